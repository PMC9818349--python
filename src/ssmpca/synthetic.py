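"""Synthetic FDG-PET-like cohorts with known ground truth.

The generator produces exactly the structure the scaled-subprofile model
assumes: on an ellipsoidal "brain" mask each subject's image is

    raw_i(v) = g_i * B(v) * exp(a_i * P(v) + eps_i(v)),   0 outside,

with a per-subject global factor ``log g_i ~ N(0, global_sd^2)``, a smooth
base profile ``B``, a smooth zero-mean unit-norm embedded pattern ``P``
whose loading ``a_i ~ N(loading_mean[group], loading_sd^2)`` differs by
group, and a smooth log-domain noise field ``eps_i`` with per-voxel sd
``noise_sd``. In the log domain the model is therefore exactly linear, so
recovery of ``P`` and of the loadings is a well-posed correctness check
for the whole pipeline. A raw-domain additive-noise switch exists to test
robustness when the log-linear assumption is deliberately violated.

Defaults are sized to a realistic derivation study: 19 disease + 19
control derivation subjects, 15 + 18 held-out validation subjects, and
two 14-subject prospectively scored groups, on a 24^3 grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .volume_io import SubjectVolume, gaussian_smooth, write_manifest, write_volume


class SynthConfigError(ValueError):
    pass


DEFAULT_GROUPS: dict[str, int] = {"C": 19, "PD": 19, "AIMN": 18, "PDv": 15,
                                  "nonDIP": 14, "DIP": 14}
DEFAULT_LOADINGS: dict[str, tuple[float, float]] = {
    "C": (0.0, 1.0), "AIMN": (0.0, 1.0),
    "PD": (2.5, 1.0), "PDv": (2.5, 1.0),
    "nonDIP": (1.0, 1.0), "DIP": (2.0, 1.0),
}


@dataclass(frozen=True)
class SynthConfig:
    """Generative settings for one synthetic cohort.

    ``loading_params`` maps each group label to ``(mean, sd)`` of the
    per-subject pattern loading; higher mean = stronger expression of the
    embedded pattern (disease-like). ``global_sd`` is the sd of the log of
    the multiplicative global factor, ``noise_sd`` the per-voxel sd of the
    smooth log-domain noise field. FWHM values are in voxels.
    """

    grid: int = 24
    semi_axes: tuple[float, float, float] = (9.0, 10.0, 8.0)
    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    loading_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LOADINGS))
    global_sd: float = 0.2
    noise_sd: float = 0.05
    pattern_fwhm: float = 6.0
    noise_fwhm: float = 4.0
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    raw_noise_sd: float = 0.0  # misspecification switch: additive raw-domain noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SynthConfigError("seed is required")
        if min(self.global_sd, self.noise_sd, self.pattern_fwhm,
               self.noise_fwhm, self.raw_noise_sd) < 0:
            raise SynthConfigError("sds and fwhms must be non-negative")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise SynthConfigError(f"group {g!r} needs >= 2 subjects, got {n}")
            if g not in self.loading_params:
                raise SynthConfigError(f"group {g!r} has no loading parameters")


@dataclass
class SynthCohort:
    """Generated volumes plus the ground truth that produced them."""

    volumes: list[SubjectVolume]
    truth: pd.DataFrame            # subject_id, group, loading, global_factor
    embedded_pattern: np.ndarray   # 3-D map, zero-mean unit-norm on the mask
    base_profile: np.ndarray       # 3-D map B, positive on the mask
    brain_mask: np.ndarray         # 3-D boolean
    config: SynthConfig

    def subset(self, groups: list[str]) -> list[SubjectVolume]:
        return [v for v in self.volumes if v.group in groups]


def make_brain(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoidal brain mask and smooth positive base profile.

    The base profile is a radial parabola, ``B = b0 * (1 - 0.5 * r^2)``
    with ``r`` the normalized ellipsoidal radius and ``b0 = 100``: highest
    in the "gray matter" core, falling to half at the rim, smooth and
    strictly positive everywhere inside the mask.
    """
    n = config.grid
    center = (n - 1) / 2.0
    if max(config.semi_axes) > center + 0.5:
        raise SynthConfigError(
            f"ellipsoid semi-axes {config.semi_axes} exceed grid {n}")
    coords = np.indices((n, n, n), dtype=np.float64) - center
    r2 = sum((coords[k] / config.semi_axes[k]) ** 2 for k in range(3))
    mask = r2 < 1.0
    if not mask.any():
        raise SynthConfigError("brain mask is empty")
    base = np.where(mask, 100.0 * (1.0 - 0.5 * r2), 0.0)
    return mask, base


def _smooth_noise(rng: np.random.Generator, mask: np.ndarray, fwhm_vox: float,
                  target_sd: float, voxel_size) -> np.ndarray:
    """White noise smoothed to FWHM then rescaled to the target sd on the mask.

    Reuses the cohort smoothing kernel so the package has one smoothing
    implementation; the voxel-to-mm FWHM conversion assumes isotropic grids.
    """
    white = rng.standard_normal(mask.shape)
    if fwhm_vox > 0:
        wrapped = SubjectVolume("_noise", "", white, voxel_size)
        fieldv = gaussian_smooth(wrapped, fwhm_vox * voxel_size[0]).data
    else:
        fieldv = white
    sd = fieldv[mask].std()
    if sd == 0:
        return np.zeros_like(fieldv)
    return fieldv * (target_sd / sd)


def make_pattern(mask: np.ndarray, fwhm_vox: float, seed: int,
                 voxel_size=(2.0, 2.0, 2.0)) -> np.ndarray:
    """Seeded smooth random field, mean-removed and norm-scaled on the mask."""
    if not mask.any():
        raise SynthConfigError("mask is empty")
    rng = np.random.default_rng(seed)
    fieldv = _smooth_noise(rng, mask, fwhm_vox, 1.0, voxel_size)
    vals = fieldv[mask]
    vals = vals - vals.mean()
    norm = np.linalg.norm(vals)
    out = np.zeros(mask.shape)
    out[mask] = vals / norm
    return out


def simulate_cohort(config: SynthConfig) -> SynthCohort:
    """Generate a full cohort; bit-reproducible for a given config + seed."""
    rng = np.random.default_rng(config.seed)
    mask, base = make_brain(config)
    pattern = make_pattern(mask, config.pattern_fwhm,
                           seed=int(rng.integers(2**31)), voxel_size=config.voxel_size)
    volumes: list[SubjectVolume] = []
    truth_rows = []
    for group, n_sub in config.group_sizes.items():
        mean, sd = config.loading_params[group]
        for k in range(n_sub):
            sid = f"{group}_{k:03d}"
            loading = float(rng.normal(mean, sd))
            g = float(np.exp(rng.normal(0.0, config.global_sd)))
            eps = _smooth_noise(rng, mask, config.noise_fwhm, config.noise_sd,
                                config.voxel_size)
            data = np.where(mask, g * base * np.exp(loading * pattern + eps), 0.0)
            if config.raw_noise_sd > 0:
                raw_eps = _smooth_noise(rng, mask, config.noise_fwhm,
                                        config.raw_noise_sd, config.voxel_size)
                data = np.where(mask, np.maximum(data + raw_eps, 1e-6), 0.0)
            volumes.append(SubjectVolume(sid, group, data, config.voxel_size))
            truth_rows.append({"subject_id": sid, "group": group,
                               "loading": loading, "global_factor": g})
    return SynthCohort(
        volumes=volumes,
        truth=pd.DataFrame(truth_rows),
        embedded_pattern=pattern,
        base_profile=base,
        brain_mask=mask,
        config=config,
    )


def write_cohort(cohort: SynthCohort, directory: str | Path) -> None:
    """Write volumes + manifest + truth CSV + the embedded pattern as NIfTI."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for v in cohort.volumes:
        fname = f"{v.subject_id}.nii.gz"
        write_volume(v, directory / fname)
        rows.append((v.subject_id, v.group, fname))
    write_manifest(rows, directory / "manifest.csv")
    cohort.truth.to_csv(directory / "truth.csv", index=False)
    write_volume(cohort.embedded_pattern, directory / "embedded_pattern.nii.gz",
                 voxel_size=cohort.config.voxel_size)
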