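"""Scaled subprofile model PCA (SSM-PCA) on a cohort of brain volumes.

The model assumes each subject's image is a global multiplicative factor
times a shared profile modulated by log-linear pattern expression. Taking
logs and removing each subject's own mean (row centering) eliminates the
global factor; removing the per-voxel mean of the row-centered data (the
group mean profile, GMP) leaves residual subject profiles whose principal
components are spatial covariance patterns (GIS) with one expression score
per subject and component.

Because subjects are far fewer than voxels, the PCA is solved in subject
space: the eigendecomposition of the subjects x subjects Gram matrix of the
residuals yields the same nonzero spectrum as the voxel-space covariance.

Pipeline (see :func:`derive_ssm`): intersection mask at a relative
threshold -> natural log -> double centering -> subject-space PCA ->
retain the leading components reaching the variance cutoff -> keep those
whose scores separate disease from control by Student's t-test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .volume_io import SubjectVolume, write_volume


class DerivationError(ValueError):
    """A derivation stage produced a degenerate result (e.g. empty mask)."""


class DomainError(ValueError):
    """Input values outside the operation's domain (e.g. log of <= 0)."""


@dataclass(frozen=True)
class SSMConfig:
    """Tunable constants of the derivation.

    mask_threshold
        A voxel is kept only if every subject's intensity there is at least
        this fraction of that subject's mean over its positive voxels.
    variance_cutoff
        Keep the smallest leading set of components whose cumulative
        variance fraction reaches this value.
    alpha_select
        Two-tailed significance level for the component-selection t-test.
    """

    mask_threshold: float = 0.35
    variance_cutoff: float = 0.50
    alpha_select: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.mask_threshold < 1:
            raise ValueError(f"mask_threshold must be in (0, 1), got {self.mask_threshold}")
        if not 0 < self.variance_cutoff <= 1:
            raise ValueError(f"variance_cutoff must be in (0, 1], got {self.variance_cutoff}")
        if not 0 < self.alpha_select < 1:
            raise ValueError(f"alpha_select must be in (0, 1), got {self.alpha_select}")


@dataclass
class Mask:
    """Retained voxels as strictly increasing linear indices into a grid."""

    indices: np.ndarray
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)
        if self.indices.size and (
            np.any(np.diff(self.indices) <= 0)
            or self.indices[0] < 0
            or self.indices[-1] >= int(np.prod(self.shape))
        ):
            raise ValueError("mask indices must be strictly increasing and within the grid")

    def __len__(self) -> int:
        return int(self.indices.size)

    def extract(self, data: np.ndarray) -> np.ndarray:
        return data.reshape(-1)[self.indices]

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(int(np.prod(self.shape)), fill, dtype=np.float64)
        out[self.indices] = values
        return out.reshape(self.shape)


@dataclass
class VolumeMatrix:
    """Subjects x masked-voxels matrix of natural-log intensities."""

    values: np.ndarray
    mask: Mask
    subject_ids: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise DomainError("log matrix contains non-finite entries")
        if self.values.shape != (len(self.subject_ids), len(self.mask)):
            raise ValueError("matrix shape does not match subjects x mask voxels")


@dataclass
class SSMModel:
    """Everything the derivation produced, sufficient for prospective scoring."""

    mask: Mask
    gmp: np.ndarray                    # per-voxel column mean of row-centered logs
    gis: np.ndarray                    # components x voxels, rows unit-norm
    eigenvalues: np.ndarray            # descending
    variance_fraction: np.ndarray      # eigenvalue / total
    scores: np.ndarray                 # subjects x components
    subject_ids: list[str]
    groups: list[str]
    selected_variance: list[int] = field(default_factory=list)
    selected_ttest: list[int] = field(default_factory=list)
    component_tests: list[dict] = field(default_factory=list)
    config: SSMConfig = field(default_factory=SSMConfig)
    disease_label: str = "PD"
    control_label: str = "C"


def compute_mask(cohort: Sequence[SubjectVolume], threshold: float = 0.35) -> Mask:
    """Intersection mask at a per-subject relative intensity threshold.

    A voxel is retained iff, for *every* subject, its intensity is at least
    ``threshold`` times that subject's mean over its strictly positive
    voxels. This discards low-signal tissue (white matter, CSF, background)
    and guarantees all retained voxels are strictly positive for every
    subject, so the subsequent log transform is well defined.
    """
    if not cohort:
        raise DerivationError("cohort is empty")
    shape = cohort[0].shape
    keep = np.ones(int(np.prod(shape)), dtype=bool)
    for v in cohort:
        if v.shape != shape:
            raise DerivationError(f"subject {v.subject_id!r} grid {v.shape} != {shape}")
        flat = v.data.reshape(-1)
        positive = flat > 0
        if not positive.any():
            raise DerivationError(f"subject {v.subject_id!r} has no positive voxels")
        cut = threshold * flat[positive].mean()
        keep &= flat >= cut
        keep &= positive
    indices = np.flatnonzero(keep)
    if indices.size == 0:
        raise DerivationError("mask is empty after thresholding")
    return Mask(indices=indices, shape=shape)


def build_log_matrix(cohort: Sequence[SubjectVolume], mask: Mask) -> VolumeMatrix:
    """Natural log of every subject's masked intensities."""
    rows = []
    for v in cohort:
        vals = mask.extract(v.data)
        bad = np.flatnonzero(vals <= 0)
        if bad.size:
            raise DomainError(
                f"subject {v.subject_id!r}: non-positive intensity at masked voxel "
                f"index {int(mask.indices[bad[0]])}"
            )
        rows.append(np.log(vals))
    return VolumeMatrix(
        values=np.vstack(rows),
        mask=mask,
        subject_ids=[v.subject_id for v in cohort],
        groups=[v.group for v in cohort],
    )


def double_center(m: VolumeMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove row means, then column means (the GMP), from the log matrix.

    Returns ``(residuals, row_means, gmp)``. Row centering comes first and
    the GMP is defined on the row-centered data: prospective scoring reuses
    exactly this GMP, so the order is part of the model, even though the
    final residuals are order-independent.
    """
    values = m.values if isinstance(m, VolumeMatrix) else np.asarray(m, dtype=np.float64)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise DerivationError(f"need >= 2 subjects and >= 2 voxels, got {values.shape}")
    row_means = values.mean(axis=1)
    row_centered = values - row_means[:, None]
    gmp = row_centered.mean(axis=0)
    residuals = row_centered - gmp[None, :]
    return residuals, row_means, gmp


def pca_decompose(residuals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the residual profiles, solved in subject space.

    Eigendecomposition of ``R @ R.T`` (subjects x subjects) gives the
    nonzero spectrum of the voxel-space covariance at a fraction of the
    cost. Returns ``(gis, scores, eigenvalues)`` where ``gis`` rows are
    unit-norm voxel patterns, ``scores[i, j] = residuals[i] @ gis[j]``, and
    eigenvalues are descending. Components with eigenvalue below
    ``1e-12 x largest`` are dropped.
    """
    residuals = np.asarray(residuals, dtype=np.float64)
    gram = residuals @ residuals.T
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals.size == 0 or eigvals[0] <= 0:
        raise DerivationError("residual matrix is all zero; nothing to decompose")
    keep = eigvals > 1e-12 * eigvals[0]
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    # gis_j = R.T u_j / ||R.T u_j||; then R @ gis_j = sqrt(lambda_j) u_j
    gis = (residuals.T @ eigvecs) / np.sqrt(eigvals)[None, :]
    scores = residuals @ gis
    return gis.T, scores, eigvals


def select_by_variance(eigenvalues: np.ndarray, cutoff: float = 0.50) -> list[int]:
    """Smallest leading prefix whose cumulative variance fraction reaches ``cutoff``.

    The component that crosses the boundary is included; an exact tie at the
    cutoff also includes the boundary component.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=np.float64)
    frac = eigenvalues / eigenvalues.sum()
    cum = np.cumsum(frac)
    n = int(np.searchsorted(cum, cutoff - 1e-12)) + 1
    return list(range(min(n, len(eigenvalues))))


def select_by_ttest(
    scores: np.ndarray,
    groups: Sequence[str],
    disease_label: str,
    control_label: str,
    alpha: float = 0.05,
    candidates: Sequence[int] | None = None,
) -> tuple[list[int], list[dict], np.ndarray]:
    """Student's t-test on each candidate component's subject scores.

    Pooled-variance two-tailed two-sample t-test, disease vs control; a
    component is retained iff ``p < alpha``. Before testing, each
    candidate's sign is oriented so the disease-group mean score exceeds
    the control-group mean (higher expression = more disease-like).

    Returns ``(retained indices, per-component test dicts, sign flips)``
    where ``flips`` is +-1 per column of ``scores`` (non-candidates keep +1).
    """
    groups = np.asarray(groups)
    d = np.flatnonzero(groups == disease_label)
    c = np.flatnonzero(groups == control_label)
    if d.size < 2 or c.size < 2:
        raise DerivationError(
            f"need >= 2 subjects per group, got {d.size} {disease_label!r} / {c.size} {control_label!r}"
        )
    if candidates is None:
        candidates = range(scores.shape[1])
    flips = np.ones(scores.shape[1])
    retained: list[int] = []
    tests: list[dict] = []
    for j in candidates:
        col = scores[:, j]
        if col[d].mean() < col[c].mean():
            flips[j] = -1.0
            col = -col
        t, p = sps.ttest_ind(col[d], col[c], equal_var=True)
        tests.append({"component": int(j), "t": float(t), "p": float(p),
                      "df": int(d.size + c.size - 2), "flipped": bool(flips[j] < 0)})
        if p < alpha:
            retained.append(int(j))
    return retained, tests, flips


def derive_ssm(
    cohort: Sequence[SubjectVolume],
    disease_label: str,
    control_label: str,
    config: SSMConfig | None = None,
) -> SSMModel:
    """Run the full SSM-PCA derivation on a cohort of disease + control subjects.

    Chains mask computation, log transform, double centering, subject-space
    PCA, variance-based pre-selection and t-test selection, recording every
    intermediate in the returned :class:`SSMModel`. Subjects whose group is
    neither ``disease_label`` nor ``control_label`` are excluded from the
    derivation.
    """
    config = config or SSMConfig()
    deriv = [v for v in cohort if v.group in (disease_label, control_label)]
    mask = compute_mask(deriv, config.mask_threshold)
    logm = build_log_matrix(deriv, mask)
    residuals, _, gmp = double_center(logm)
    gis, scores, eigvals = pca_decompose(residuals)
    total = eigvals.sum()
    sel_var = select_by_variance(eigvals, config.variance_cutoff)
    sel_t, tests, flips = select_by_ttest(
        scores, logm.groups, disease_label, control_label,
        alpha=config.alpha_select, candidates=sel_var,
    )
    # fold the disease-positive orientation into the stored model
    gis = gis * flips[:, None]
    scores = scores * flips[None, :]
    return SSMModel(
        mask=mask,
        gmp=gmp,
        gis=gis,
        eigenvalues=eigvals,
        variance_fraction=eigvals / total,
        scores=scores,
        subject_ids=logm.subject_ids,
        groups=logm.groups,
        selected_variance=sel_var,
        selected_ttest=sel_t,
        component_tests=tests,
        config=config,
        disease_label=disease_label,
        control_label=control_label,
    )


def save_model(model: SSMModel, directory: str | Path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Persist a model as NIfTI maps (mask, gmp, each gis) + a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume(model.mask.to_volume(np.ones(len(model.mask))), directory / "mask.nii.gz",
                 voxel_size=voxel_size)
    write_volume(model.mask.to_volume(model.gmp), directory / "gmp.nii.gz", voxel_size=voxel_size)
    for j in range(model.gis.shape[0]):
        write_volume(model.mask.to_volume(model.gis[j]), directory / f"gis_{j:02d}.nii.gz",
                     voxel_size=voxel_size)
    sidecar = {
        "shape": list(model.mask.shape),
        "mask_indices": model.mask.indices.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "variance_fraction": model.variance_fraction.tolist(),
        "selected_variance": model.selected_variance,
        "selected_ttest": model.selected_ttest,
        "component_tests": model.component_tests,
        "scores": model.scores.tolist(),
        "subject_ids": model.subject_ids,
        "groups": model.groups,
        "disease_label": model.disease_label,
        "control_label": model.control_label,
        "config": {
            "mask_threshold": model.config.mask_threshold,
            "variance_cutoff": model.config.variance_cutoff,
            "alpha_select": model.config.alpha_select,
        },
    }
    (directory / "model.json").write_text(json.dumps(sidecar, indent=1))


def load_model(directory: str | Path) -> SSMModel:
    """Load a model saved by :func:`save_model`."""
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text())
    mask = Mask(indices=np.asarray(sidecar["mask_indices"]), shape=tuple(sidecar["shape"]))
    n_comp = len(sidecar["eigenvalues"])
    gmp = _read_masked(directory / "gmp.nii.gz", mask)
    gis = np.vstack([_read_masked(directory / f"gis_{j:02d}.nii.gz", mask) for j in range(n_comp)])
    return SSMModel(
        mask=mask,
        gmp=gmp,
        gis=gis,
        eigenvalues=np.asarray(sidecar["eigenvalues"]),
        variance_fraction=np.asarray(sidecar["variance_fraction"]),
        scores=np.asarray(sidecar["scores"]),
        subject_ids=list(sidecar["subject_ids"]),
        groups=list(sidecar["groups"]),
        selected_variance=list(sidecar["selected_variance"]),
        selected_ttest=list(sidecar["selected_ttest"]),
        component_tests=list(sidecar["component_tests"]),
        config=SSMConfig(**sidecar["config"]),
        disease_label=sidecar["disease_label"],
        control_label=sidecar["control_label"],
    )


def _read_masked(path: Path, mask: Mask) -> np.ndarray:
    import nibabel as nib

    data = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
    return mask.extract(data)
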