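"""Prospective pattern scoring and the composite disease pattern.

A stored model (mask + GMP + component patterns) can score any new subject
by the topographic profile rating (TPR): restrict the image to the mask,
take natural logs, remove the subject's own mean over the mask, remove the
stored GMP, and project the residual profile onto a pattern's voxel
weights. For the derivation subjects this reproduces their PCA scores
exactly, which is the central correctness property of the scoring path.

Components that survive pairwise cross-validation on held-out cohorts are
combined into one composite pattern with weights from a logistic regression
of disease status on the component scores. Composite scores are reported as
Z-scores standardized by the derivation control group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .ssm import DerivationError, DomainError, Mask, SSMModel
from .volume_io import SubjectVolume, write_volume

#: Ridge strength applied to the slopes when the logistic fit separates
#: perfectly (small groups often do); the result carries a flag.
SEPARATION_RIDGE = 1e-4


@dataclass
class CompositePattern:
    """A weighted combination of component patterns, ready for scoring."""

    mask: Mask
    gmp: np.ndarray
    voxel_weights: np.ndarray          # sum_j c_j * gis_j over the mask
    coefficients: np.ndarray           # logistic slopes c_j
    component_indices: list[int]
    intercept: float                   # stored, not used in scoring
    z_ref_mean: float                  # composite-score normalization from
    z_ref_sd: float                    # the derivation control group
    z_voxel: np.ndarray = field(default=None)  # type: ignore[assignment]
    separation_flag: bool = False

    def __post_init__(self) -> None:
        if self.z_ref_sd <= 0:
            raise DerivationError("z_ref_sd must be positive")
        if self.z_voxel is None:
            w = self.voxel_weights
            self.z_voxel = (w - w.mean()) / w.std(ddof=1)


def tpr_score(v: SubjectVolume, pattern: CompositePattern | SSMModel,
              component: int | None = None) -> float:
    """Prospective raw expression score of one subject against a pattern.

    With an :class:`SSMModel`, ``component`` selects which GIS to project
    onto; with a :class:`CompositePattern` the composite voxel weights are
    used. Invariant to global rescaling of the input volume.
    """
    if isinstance(pattern, SSMModel):
        if component is None:
            raise ValueError("component index required when scoring against a model")
        weights = pattern.gis[component]
    else:
        weights = pattern.voxel_weights
    srp = subject_residual_profile(v, pattern.mask, pattern.gmp)
    return float(srp @ weights)


def subject_residual_profile(v: SubjectVolume, mask: Mask, gmp: np.ndarray) -> np.ndarray:
    """Masked log profile minus the subject's own mean and the stored GMP."""
    vals = mask.extract(v.data)
    if np.any(vals <= 0):
        bad = int(mask.indices[np.flatnonzero(vals <= 0)[0]])
        raise DomainError(f"subject {v.subject_id!r}: non-positive intensity at masked voxel {bad}")
    logv = np.log(vals)
    return logv - logv.mean() - gmp


def cross_validate_components(
    model: SSMModel,
    validation_cohorts: Sequence[tuple[str, str, Sequence[SubjectVolume]]] = (),
    alpha: float = 0.05,
) -> tuple[list[int], list[dict]]:
    """Keep components that separate disease from control in *every* pair.

    ``validation_cohorts`` are ``(name, role, volumes)`` triples with role
    ``"disease"`` or ``"control"``. Every disease cohort (derivation +
    validation) is paired with every control cohort and each candidate
    component from ``model.selected_ttest`` is tested with the pooled
    t-test on TPR scores; a component survives iff ``p < alpha`` in all
    pairs. With no validation cohorts the candidate list passes unchanged.
    """
    groups = np.asarray(model.groups)
    disease_pools: list[tuple[str, np.ndarray]] = []
    control_pools: list[tuple[str, np.ndarray]] = []

    candidates = model.selected_ttest
    if not validation_cohorts:
        return list(candidates), []

    # derivation scores come straight from the model; validation via TPR
    d_idx = np.flatnonzero(groups == model.disease_label)
    c_idx = np.flatnonzero(groups == model.control_label)
    disease_pools.append((model.disease_label, model.scores[d_idx][:, candidates]))
    control_pools.append((model.control_label, model.scores[c_idx][:, candidates]))
    for name, role, vols in validation_cohorts:
        scores = np.array([[tpr_score(v, model, component=j) for j in candidates] for v in vols])
        if role == "disease":
            disease_pools.append((name, scores))
        elif role == "control":
            control_pools.append((name, scores))
        else:
            raise ValueError(f"cohort {name!r}: role must be 'disease' or 'control', got {role!r}")

    tests: list[dict] = []
    surviving: list[int] = []
    for k, j in enumerate(candidates):
        ok = True
        for dname, dscores in disease_pools:
            for cname, cscores in control_pools:
                if dscores.shape[0] < 2 or cscores.shape[0] < 2:
                    raise DerivationError(
                        f"pair {dname} vs {cname}: need >= 2 subjects on each side"
                    )
                t, p = sps.ttest_ind(dscores[:, k], cscores[:, k], equal_var=True)
                tests.append({"component": int(j), "pair": f"{dname} vs {cname}",
                              "t": float(t), "p": float(p)})
                ok &= p < alpha
        if ok:
            surviving.append(int(j))
    return surviving, tests


def fit_logistic_combination(
    scores: np.ndarray, labels: Sequence[int] | np.ndarray
) -> tuple[np.ndarray, float, bool]:
    """Binary logistic regression of disease status on component scores.

    ``labels`` is 1 for disease, 0 for control. Returns ``(coefficients,
    intercept, separated)``. If the classes are linearly separable the
    unpenalized likelihood has no maximum; the fit is then redone with a
    fixed small ridge penalty (:data:`SEPARATION_RIDGE`) on the slopes and
    flagged.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=np.float64)
    uniq = np.unique(y)
    if uniq.size < 2:
        raise DerivationError("logistic fit needs both classes present")
    if np.bincount(y.astype(int)).min() < 2:
        raise DerivationError("logistic fit needs >= 2 subjects per class")

    beta, converged = _logit_mle(X, y, ridge=0.0)
    # under separation the MLE diverges: the optimizer either fails or stops
    # on a flat likelihood with every subject classified almost perfectly
    mu = 1.0 / (1.0 + np.exp(-(np.column_stack([np.ones(len(y)), X]) @ beta)))
    separated = (not converged) or np.abs(beta).max() > 1e3 or np.abs(mu - y).max() < 1e-3
    if separated:
        beta, _ = _logit_mle(X, y, ridge=SEPARATION_RIDGE)
    return beta[1:], float(beta[0]), bool(separated)


def _logit_mle(X: np.ndarray, y: np.ndarray, ridge: float) -> tuple[np.ndarray, bool]:
    """Newton/BFGS logistic fit; ridge penalizes slopes only, never the intercept."""
    Xd = np.column_stack([np.ones(len(y)), X])
    pen = np.zeros(Xd.shape[1])
    pen[1:] = ridge

    def negloglik(beta):
        eta = Xd @ beta
        # log(1 + exp(eta)) - y*eta, numerically stable
        nll = np.sum(np.logaddexp(0.0, eta) - y * eta)
        return nll + 0.5 * np.sum(pen * beta**2)

    def grad(beta):
        mu = 1.0 / (1.0 + np.exp(-(Xd @ beta)))
        return Xd.T @ (mu - y) + pen * beta

    res = optimize.minimize(negloglik, np.zeros(Xd.shape[1]), jac=grad, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    return res.x, bool(res.success)


def compose_pattern(
    model: SSMModel,
    indices: Sequence[int],
    coefficients: Sequence[float],
    intercept: float = 0.0,
    separation_flag: bool = False,
) -> CompositePattern:
    """Linearly combine selected components into the composite pattern.

    ``voxel_weights = sum_j c_j * gis_j``. The Z reference (mean and sample
    sd, n-1 denominator) comes from the derivation control subjects'
    composite raw scores, so derivation controls have Z mean 0 and sd 1 by
    construction.
    """
    indices = list(indices)
    coefficients = np.asarray(coefficients, dtype=np.float64)
    if len(indices) != coefficients.size:
        raise ValueError("indices and coefficients must have equal length")
    if not indices or np.allclose(coefficients, 0):
        raise DerivationError("composite pattern requires a nonzero coefficient vector")
    voxel_weights = coefficients @ model.gis[indices]
    composite_scores = model.scores[:, indices] @ coefficients
    controls = np.asarray(model.groups) == model.control_label
    ref = composite_scores[controls]
    sd = float(ref.std(ddof=1))
    if sd == 0:
        raise DerivationError("derivation control scores are constant; cannot standardize")
    return CompositePattern(
        mask=model.mask,
        gmp=model.gmp,
        voxel_weights=voxel_weights,
        coefficients=coefficients,
        component_indices=indices,
        intercept=float(intercept),
        z_ref_mean=float(ref.mean()),
        z_ref_sd=sd,
        separation_flag=separation_flag,
    )


def score_cohort(cohort: Sequence[SubjectVolume], pattern: CompositePattern) -> pd.DataFrame:
    """Score every subject, returning ``subject_id,group,raw_score,z_score`` rows."""
    rows = []
    for v in cohort:
        raw = tpr_score(v, pattern)
        rows.append({
            "subject_id": v.subject_id,
            "group": v.group,
            "raw_score": raw,
            "z_score": (raw - pattern.z_ref_mean) / pattern.z_ref_sd,
        })
    return pd.DataFrame(rows, columns=["subject_id", "group", "raw_score", "z_score"])


def save_pattern(pattern: CompositePattern, directory: str | Path,
                 voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Persist as NIfTI maps (weights, z map, mask, gmp) + a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume(pattern.mask.to_volume(pattern.voxel_weights), directory / "voxel_weights.nii.gz",
                 voxel_size=voxel_size)
    write_volume(pattern.mask.to_volume(pattern.z_voxel), directory / "z_voxel.nii.gz",
                 voxel_size=voxel_size)
    write_volume(pattern.mask.to_volume(np.ones(len(pattern.mask))), directory / "mask.nii.gz",
                 voxel_size=voxel_size)
    write_volume(pattern.mask.to_volume(pattern.gmp), directory / "gmp.nii.gz",
                 voxel_size=voxel_size)
    sidecar = {
        "shape": list(pattern.mask.shape),
        "mask_indices": pattern.mask.indices.tolist(),
        "voxel_weights": pattern.voxel_weights.tolist(),
        "gmp": pattern.gmp.tolist(),
        "coefficients": pattern.coefficients.tolist(),
        "component_indices": pattern.component_indices,
        "intercept": pattern.intercept,
        "z_ref_mean": pattern.z_ref_mean,
        "z_ref_sd": pattern.z_ref_sd,
        "separation_flag": pattern.separation_flag,
    }
    (directory / "pattern.json").write_text(json.dumps(sidecar, indent=1))


def load_pattern(directory: str | Path) -> CompositePattern:
    """Load a pattern saved by :func:`save_pattern` (full precision from JSON)."""
    sidecar = json.loads((Path(directory) / "pattern.json").read_text())
    return CompositePattern(
        mask=Mask(indices=np.asarray(sidecar["mask_indices"]), shape=tuple(sidecar["shape"])),
        gmp=np.asarray(sidecar["gmp"]),
        voxel_weights=np.asarray(sidecar["voxel_weights"]),
        coefficients=np.asarray(sidecar["coefficients"]),
        component_indices=list(sidecar["component_indices"]),
        intercept=float(sidecar["intercept"]),
        z_ref_mean=float(sidecar["z_ref_mean"]),
        z_ref_sd=float(sidecar["z_ref_sd"]),
        separation_flag=bool(sidecar["separation_flag"]),
    )
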