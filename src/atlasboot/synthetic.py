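"""Synthetic phantoms and cohort tables for end-to-end testing.

Two generators make the whole pipeline runnable without any imaging data:

* :func:`make_phantom_scene` builds a target image whose ground truth is a
  voxelized ellipsoid ROI, plus a pool of atlases that are misaligned
  copies of the truth (rigid random translation + boundary label noise).
  The translation magnitude ``shift_sd`` plays the role of registration
  uncertainty: larger misalignment makes the fused volume more variable
  across bootstrap atlas collections.

* :func:`make_cohort` draws subject tables from the linear model
  ``Y_i = beta . (1, age_i - age_ref, icv_i) + group_effect * 1[group=1] + eps_i``
  with independent, subject-specific error variances
  ``sigma_i = base_sd * LogNormal(0, lognormal_sd)``, optionally inflated
  (in both mean and variance) for outlier-flagged subjects, concentrated by
  group.  Hidden-truth columns (``true_sigma2``, ``is_outlier``) allow
  oracle-weighted analyses and parameter-recovery checks.

Default cohort calibration follows typical elderly hippocampal volumetry:
volumes near 7400 mm^3 at the reference age, ages 55-95 years, ICV around
1.4e6 mm^3.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import Atlas, IntensityImage, LabelImage

__all__ = ["SceneConfig", "CohortConfig", "make_phantom_scene", "make_cohort"]


@dataclass(frozen=True)
class SceneConfig:
    """Phantom scene settings (grid in voxels, physical sizes in mm)."""

    grid_shape: tuple[int, int, int] = (24, 24, 16)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    roi_semi_axes: tuple[float, float, float] = (7.0, 6.0, 4.5)
    n_atlases: int = 35
    shift_sd: float = 1.0  # mm, per-axis sd of the rigid atlas translation
    label_flip_rate: float = 0.05  # flip probability for ROI-boundary voxels
    intensity_noise_sd: float = 0.1
    smoothing_sigma: float = 1.0  # voxels, for intensity synthesis
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift_sd < 0:
            raise ValueError("shift_sd must be >= 0")
        if not 0 <= self.label_flip_rate <= 1:
            raise ValueError("label_flip_rate must lie in [0, 1]")
        if self.n_atlases < 1:
            raise ValueError("n_atlases must be >= 1")


def _ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    semi_axes: tuple[float, float, float],
) -> np.ndarray:
    center = [(s - 1) / 2 * v for s, v in zip(grid_shape, voxel_size)]
    coords = np.meshgrid(
        *[np.arange(s) * v for s, v in zip(grid_shape, voxel_size)], indexing="ij"
    )
    q = sum(((c - c0) / a) ** 2 for c, c0, a in zip(coords, center, semi_axes))
    return q <= 1.0


def _integer_shift(grid: np.ndarray, shift: tuple[int, int, int], fill: int | float = 0) -> np.ndarray:
    out = np.full_like(grid, fill)
    src = []
    dst = []
    for s, size in zip(shift, grid.shape):
        if abs(s) >= size:
            return out
        if s >= 0:
            src.append(slice(0, size - s))
            dst.append(slice(s, size))
        else:
            src.append(slice(-s, size))
            dst.append(slice(0, size + s))
    out[tuple(dst)] = grid[tuple(src)]
    return out


def _intensity_from_labels(
    labels: np.ndarray, cfg: SceneConfig, rng: np.random.Generator
) -> np.ndarray:
    smooth = ndimage.gaussian_filter(labels.astype(float), sigma=cfg.smoothing_sigma)
    if cfg.intensity_noise_sd > 0:
        smooth = smooth + cfg.intensity_noise_sd * rng.standard_normal(labels.shape)
    return smooth


def make_phantom_scene(
    config: SceneConfig,
) -> tuple[IntensityImage, LabelImage, list[Atlas]]:
    """Build (target, ground-truth labels, atlas pool) for one phantom subject.

    Each atlas is the truth translated by a per-axis Normal(0, shift_sd) mm
    displacement (nearest-voxel resampling) with boundary labels flipped
    independently at ``label_flip_rate``; its intensity is synthesized from
    its own (misaligned) labels, so intensity-based fusion weights see the
    misalignment.
    """
    cfg = config
    extent = [(s - 1) / 2 * v for s, v in zip(cfg.grid_shape, cfg.voxel_size)]
    if any(a >= e for a, e in zip(cfg.roi_semi_axes, extent)):
        raise ValueError(
            f"ROI semi-axes {cfg.roi_semi_axes} do not fit inside the grid "
            f"(half-extents {tuple(extent)})"
        )
    rng = np.random.default_rng(cfg.seed)
    truth_grid = _ellipsoid_mask(cfg.grid_shape, cfg.voxel_size, cfg.roi_semi_axes).astype(
        np.int32
    )
    truth = LabelImage(truth_grid, cfg.voxel_size)
    target = IntensityImage(_intensity_from_labels(truth_grid, cfg, rng), cfg.voxel_size)

    # ROI boundary: voxels whose 6-neighbourhood is not label-constant
    footprint = ndimage.generate_binary_structure(3, 1)
    boundary = ndimage.maximum_filter(truth_grid, footprint=footprint) != ndimage.minimum_filter(
        truth_grid, footprint=footprint
    )

    atlases = []
    for i in range(cfg.n_atlases):
        shift_mm = rng.normal(0.0, cfg.shift_sd, size=3)
        shift_vox = tuple(int(np.rint(s / v)) for s, v in zip(shift_mm, cfg.voxel_size))
        labels = _integer_shift(truth_grid, shift_vox)
        if cfg.label_flip_rate > 0:
            flip = boundary & (rng.random(cfg.grid_shape) < cfg.label_flip_rate)
            labels = labels.copy()
            labels[flip] = 1 - labels[flip]
        intensity = _intensity_from_labels(labels, cfg, rng)
        atlases.append(
            Atlas(
                id=f"atlas{i:03d}",
                intensity=IntensityImage(intensity, cfg.voxel_size),
                labels=LabelImage(labels, cfg.voxel_size),
            )
        )
    return target, truth, atlases


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-table settings.  Volumes in mm^3, ages in years, ICV in mm^3.

    ``beta`` applies to (1, age - age_ref, icv); the intercept is thus the
    expected volume at the reference age for icv = 0.  Outlier structure is
    per group: ``outlier_rate[g]`` of group ``g``'s subjects get their
    volume shifted by ``outlier_volume_shift`` and their error sd inflated
    by ``outlier_variance_factor`` (emulating poorly segmented scans that
    yield high outlying volume estimates of low precision).
    """

    n_per_group: int = 80
    beta: tuple[float, float, float] = (7400.0, 10.0, 0.001)
    age_ref: float = 75.0
    group_effect: float = 0.0
    base_sd: float = 100.0
    lognormal_sd: float = 0.5
    outlier_rate: tuple[float, float] = (0.0, 0.0)
    outlier_volume_shift: float = 1000.0
    outlier_variance_factor: float = 5.0
    age_range: tuple[float, float] = (55.0, 95.0)
    icv_mean: float = 1.4e6
    icv_sd: float = 1.2e5
    noisy_weights: bool = False
    n_boot: int = 300  # replicate count emulated by the noisy-weight option
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if self.base_sd < 0 or self.lognormal_sd < 0 or self.icv_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if any(not 0 <= r <= 1 for r in self.outlier_rate):
            raise ValueError("outlier rates must lie in [0, 1]")
        if self.outlier_variance_factor <= 0:
            raise ValueError("outlier_variance_factor must be > 0")


def make_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw one cohort table from the heteroskedastic linear model.

    Returns a DataFrame with columns subject_id, group, age, icv,
    volume_mm3, precision_weight, cv, cv_weight plus the hidden-truth
    columns true_sigma2 and is_outlier.  ``precision_weight`` is the oracle
    weight 1/sigma_i^2 unless ``noisy_weights`` is set, in which case
    sigma_i^2 is replaced by a scaled chi-square draw with ``n_boot - 1``
    degrees of freedom, emulating bootstrap estimation error.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_per_group
    group = np.repeat([0, 1], cfg.n_per_group)

    age = rng.uniform(*cfg.age_range, size=n)
    icv = rng.normal(cfg.icv_mean, cfg.icv_sd, size=n)

    sigma = cfg.base_sd * rng.lognormal(0.0, cfg.lognormal_sd, size=n)
    is_outlier = np.zeros(n, dtype=bool)
    for g in (0, 1):
        mask = group == g
        is_outlier[mask] = rng.random(mask.sum()) < cfg.outlier_rate[g]
    sigma = np.where(is_outlier, sigma * cfg.outlier_variance_factor, sigma)

    b0, b_age, b_icv = cfg.beta
    mean_volume = (
        b0
        + b_age * (age - cfg.age_ref)
        + b_icv * icv
        + cfg.group_effect * group
        + cfg.outlier_volume_shift * is_outlier
    )
    volume = mean_volume + sigma * rng.standard_normal(n)

    sigma2 = sigma**2
    if cfg.noisy_weights:
        df = cfg.n_boot - 1
        sigma2_hat = sigma2 * rng.chisquare(df, size=n) / df
    else:
        sigma2_hat = sigma2
    precision = 1.0 / sigma2_hat
    # CV defined against the subject's expected volume, mirroring sd/mean
    # of bootstrap replicates
    cv = np.sqrt(sigma2_hat) / np.maximum(mean_volume, 1e-12)
    cv_w = 1.0 / np.maximum(cv, 1e-6)

    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "group": group,
            "age": age,
            "icv": icv,
            "volume_mm3": volume,
            "precision_weight": precision,
            "cv": cv,
            "cv_weight": cv_w,
            "true_sigma2": sigma2,
            "is_outlier": is_outlier,
        }
    )
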