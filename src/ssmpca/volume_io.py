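"""Reading, writing and smoothing of brain volumes, plus cohort manifests.

Volumes are assumed to be spatially pre-normalized: every subject in a
cohort must share one voxel grid (shape and voxel size). Registration and
template management are out of scope; orientation metadata (the affine) is
carried through opaquely and never resampled.

Supported formats: NIfTI-1 (``.nii``, ``.nii.gz``) read/write and Analyze
7.5 (``.hdr``/``.img``) read-only. Manifests are CSV files with header
``subject_id,group,path``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage


class VolumeFormatError(ValueError):
    """File is unreadable or not a single-frame 3-D volume."""


class VolumeValidationError(ValueError):
    """Array contents violate an invariant (non-finite values, bad shape)."""


class ManifestError(ValueError):
    """Manifest rows violate an invariant (duplicates, missing files)."""


class CohortConsistencyError(ValueError):
    """Cohort volumes do not share one grid."""


# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class SubjectVolume:
    """One subject's 3-D intensity image on a fixed grid.

    Parameters
    ----------
    subject_id
        Unique identifier within a cohort.
    group
        Categorical group label (e.g. ``C``, ``PD``, ``PDv``, ``DIP``).
    data
        3-D array of non-negative, finite intensities.
    voxel_size
        Voxel edge lengths ``(dx, dy, dz)`` in millimetres.
    affine
        Voxel-to-world matrix carried from the file header (opaque).
    """

    subject_id: str
    group: str
    data: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeValidationError(
                f"volume for {self.subject_id!r} must be 3-D, got shape {self.data.shape}"
            )
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise VolumeValidationError(f"voxel sizes must be positive, got {vs}")
        self.voxel_size = vs
        if not np.all(np.isfinite(self.data)):
            raise VolumeValidationError(
                f"volume for {self.subject_id!r} contains non-finite values"
            )
        # positivity is not enforced here: pattern/GMP maps round-trip through
        # the same reader; the derivation mask rejects signal-free subjects
        if self.affine is None:
            self.affine = np.diag((*self.voxel_size, 1.0))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def read_volume(path: str | Path, subject_id: str = "", group: str = "") -> SubjectVolume:
    """Read a single-frame 3-D volume (NIfTI-1 or Analyze 7.5).

    4-D files with exactly one frame are squeezed to 3-D; files with more
    than one frame raise :class:`VolumeFormatError` naming the frame count.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # nibabel raises a zoo of types for bad files
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise VolumeFormatError(
                f"{path} has {data.shape[3]} frames; expected a single-frame volume"
            )
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path} is {data.ndim}-D; expected 3-D")
    zooms = img.header.get_zooms()[:3]
    return SubjectVolume(
        subject_id=subject_id or path.stem.replace(".nii", ""),
        group=group,
        data=data,
        voxel_size=tuple(float(z) for z in zooms),
        affine=np.array(img.affine, dtype=np.float64),
    )


def write_volume(
    v: SubjectVolume | np.ndarray,
    path: str | Path,
    *,
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
    affine: np.ndarray | None = None,
) -> None:
    """Write a volume (or a bare voxel map) as a float32 NIfTI-1 file.

    Round-tripping through :func:`read_volume` preserves values to float32
    precision. Non-finite values are rejected.
    """
    if isinstance(v, SubjectVolume):
        data, aff = v.data, v.affine
    else:
        data = np.asarray(v, dtype=np.float64)
        aff = affine if affine is not None else np.diag((*[float(s) for s in voxel_size], 1.0))
    if not np.all(np.isfinite(data)):
        raise VolumeValidationError("cannot write non-finite values")
    img = nib.Nifti1Image(data.astype(np.float32), aff)
    nib.save(img, str(path))


def gaussian_smooth(v: SubjectVolume, fwhm_mm: float) -> SubjectVolume:
    """Separable Gaussian smoothing with a kernel given as FWHM in mm.

    Per-axis sigma in voxels is ``fwhm_mm * FWHM_TO_SIGMA / voxel_size``.
    The boundary is zero-padded: intensity outside the field of view is
    treated as zero signal. ``fwhm_mm = 0`` returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise VolumeValidationError(f"fwhm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return v
    sigmas = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in v.voxel_size]
    smoothed = ndimage.gaussian_filter(v.data, sigma=sigmas, mode="constant", cval=0.0)
    return replace(v, data=smoothed)


def read_manifest(path: str | Path, group_vocabulary: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a ``subject_id,group,path`` CSV manifest and validate it.

    Relative volume paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = ["subject_id", "group", "path"]
    if list(df.columns[:3]) != required:
        raise ManifestError(f"manifest must have columns {required}, got {list(df.columns)}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ManifestError(f"duplicate subject_id(s): {dupes}")
    base = path.parent
    df["path"] = [str(p) if Path(p).is_absolute() else str(base / p) for p in df["path"]]
    missing = [p for p in df["path"] if not Path(p).exists()]
    if missing:
        raise ManifestError(f"manifest paths not found: {missing}")
    if group_vocabulary is not None:
        unknown = sorted(set(df["group"]) - set(group_vocabulary))
        if unknown:
            raise ManifestError(f"groups {unknown} not in declared vocabulary {list(group_vocabulary)}")
    return df


def load_cohort(manifest: pd.DataFrame | str | Path) -> list[SubjectVolume]:
    """Load every manifest row into a :class:`SubjectVolume`, in order.

    All volumes must share grid shape and voxel size; a mismatch raises
    :class:`CohortConsistencyError` naming the offending subject.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    if len(manifest) == 0:
        raise ManifestError("manifest is empty")
    if manifest["subject_id"].duplicated().any():
        dupes = manifest.loc[manifest["subject_id"].duplicated(), "subject_id"].tolist()
        raise ManifestError(f"duplicate subject_id(s): {dupes}")
    cohort: list[SubjectVolume] = []
    for row in manifest.itertuples(index=False):
        vol = read_volume(row.path, subject_id=str(row.subject_id), group=str(row.group))
        if cohort and (vol.shape != cohort[0].shape or not np.allclose(vol.voxel_size, cohort[0].voxel_size)):
            raise CohortConsistencyError(
                f"subject {vol.subject_id!r}: grid {vol.shape} @ {vol.voxel_size} does not match "
                f"cohort grid {cohort[0].shape} @ {cohort[0].voxel_size}"
            )
        cohort.append(vol)
    return cohort


def write_manifest(rows: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    """Write ``(subject_id, group, path)`` rows as a manifest CSV."""
    pd.DataFrame(rows, columns=["subject_id", "group", "path"]).to_csv(path, index=False)
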