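"""Bootstrap resampling of atlas collections and the precision weights.

For a fixed target image, the conditional variance of its fused ROI volume
estimate (the variance induced by the choice of atlases) is estimated by
resampling same-size atlas collections with replacement, re-fusing each
collection, and taking the sample variance of the replicate volumes.  The
reciprocal of that variance is the subject's precision weight — the
Aitken-optimal weight in weighted least squares under uncorrelated,
subject-specific error variances.  The reciprocal coefficient of variation
(sd/mean of the replicate volumes) is retained as a comparison weighting
scheme.

Per-subject random streams are derived from (global seed, subject id), so
subjects can be processed in any order, or in parallel, with identical
results.
"""
from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .fusion import FusionEngine, roi_volume, tally_votes
from .images import Atlas, IntensityImage, LabelImage

__all__ = [
    "BootstrapConfig",
    "VolumeSamples",
    "WeightRecord",
    "subject_rng",
    "resample_collection",
    "bootstrap_volumes",
    "bootstrap_variance",
    "precision_weight",
    "cv_weight",
    "running_variance_curve",
    "weight_record",
]

#: Variance floor in mm^6 guarding against infinite weights on degenerate
#: (zero-variance) inputs; never binding on realistically noisy data.
DEFAULT_VARIANCE_FLOOR = 1e-9
#: Analogous floor for the coefficient of variation (dimensionless).
DEFAULT_CV_FLOOR = 1e-6


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for the atlas bootstrap.

    ``collection_size=None`` means "same size as the atlas pool", the
    standard bootstrap convention.
    """

    n_replicates: int = 300
    collection_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.collection_size is not None and self.collection_size < 1:
            raise ValueError("collection_size must be >= 1")


@dataclass(frozen=True)
class VolumeSamples:
    """Replicate ROI volume estimates (mm^3) for one target image.

    ``volumes`` is kept in generation order; the running-variance
    diagnostic depends on it.
    """

    subject_id: str
    volumes: np.ndarray
    config: BootstrapConfig

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float)
        if v.ndim != 1 or v.size != self.config.n_replicates:
            raise ValueError(
                f"expected {self.config.n_replicates} replicate volumes, got {v.shape}"
            )
        if v.size and v.min() < 0:
            raise ValueError("volumes must be >= 0")
        object.__setattr__(self, "volumes", v)


@dataclass(frozen=True)
class WeightRecord:
    """Per-subject weight summary derived from the bootstrap replicates."""

    subject_id: str
    boot_variance: float  # mm^6
    precision_weight: float  # 1/mm^6
    cv: float
    cv_weight: float
    n_replicates: int
    flags: tuple[str, ...] = field(default_factory=tuple)


def subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Random stream for one subject, reproducibly derived from (seed, id)."""
    key = zlib.crc32(str(subject_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def resample_collection(
    atlases: list[Atlas],
    collection_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Atlas]:
    """Draw a bootstrap atlas collection uniformly with replacement."""
    if len(atlases) == 0:
        raise ValueError("atlas pool is empty")
    if collection_size is None:
        collection_size = len(atlases)
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.integers(0, len(atlases), size=collection_size)
    return [atlases[i] for i in idx]


def bootstrap_volumes(
    target: IntensityImage,
    atlases: list[Atlas],
    engine: FusionEngine,
    roi_label: int,
    config: BootstrapConfig,
    subject_id: str = "subject",
) -> VolumeSamples:
    """Replicate ROI volumes from bootstrap-resampled atlas collections.

    Each replicate draws ``collection_size`` atlases with replacement,
    fuses them with ``engine``, and records the ROI volume.  Degenerate
    collections (all slots the same atlas) are kept: excluding them would
    bias the variance.  Because vote weights do not depend on the drawn
    collection, they are computed once and each replicate reduces to a
    multiplicity-weighted tally.
    """
    if len(atlases) == 0:
        raise ValueError("atlas pool is empty")
    m = len(atlases)
    size = config.collection_size if config.collection_size is not None else m
    rng = subject_rng(config.seed, subject_id)

    stack = np.stack([a.labels.labels for a in atlases])
    weights = engine.vote_weights(target, atlases)
    voxel_volume = atlases[0].labels.voxel_volume

    volumes = np.empty(config.n_replicates)
    for b in range(config.n_replicates):
        idx = rng.integers(0, m, size=size)
        mult = np.bincount(idx, minlength=m)
        fused = tally_votes(stack, weights, mult)
        volumes[b] = np.count_nonzero(fused == roi_label) * voxel_volume
    return VolumeSamples(subject_id=subject_id, volumes=volumes, config=config)


def bootstrap_variance(samples: VolumeSamples) -> float:
    """Unbiased sample variance (divisor n-1) of the replicate volumes, mm^6."""
    if samples.volumes.size < 2:
        raise ValueError("need at least 2 replicates to estimate a variance")
    return float(np.var(samples.volumes, ddof=1))


def precision_weight(
    boot_variance: float, variance_floor: float = DEFAULT_VARIANCE_FLOOR
) -> float:
    """Inverse bootstrap variance, floored to avoid infinite weights."""
    if boot_variance < 0:
        raise ValueError("variance must be >= 0")
    if variance_floor <= 0:
        raise ValueError("variance_floor must be > 0")
    return 1.0 / max(boot_variance, variance_floor)


def cv_weight(
    samples: VolumeSamples, cv_floor: float = DEFAULT_CV_FLOOR
) -> tuple[float, float]:
    """Coefficient of variation (sd/mean) of the replicates and its reciprocal."""
    mean = float(np.mean(samples.volumes))
    if mean <= 0:
        raise ValueError("mean replicate volume must be > 0 to form a CV")
    sd = float(np.std(samples.volumes, ddof=1))
    cv = sd / mean
    return cv, 1.0 / max(cv, cv_floor)


def running_variance_curve(
    samples: VolumeSamples, grid: list[int]
) -> list[tuple[int, float]]:
    """Sample variance of the first n replicates for each n in ``grid``.

    The diagnostic used to choose the number of bootstrap replicates: the
    curve flattens once enough replicates have accumulated.
    """
    n_avail = samples.volumes.size
    grid = list(grid)
    if any(n < 2 or n > n_avail for n in grid):
        raise ValueError(f"grid values must lie in [2, {n_avail}]")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    return [(n, float(np.var(samples.volumes[:n], ddof=1))) for n in grid]


def weight_record(
    samples: VolumeSamples,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    cv_floor: float = DEFAULT_CV_FLOOR,
) -> WeightRecord:
    """Summarize one subject's replicates into variance, precision and CV weights."""
    var = bootstrap_variance(samples)
    flags: list[str] = []
    if var <= variance_floor:
        flags.append("zero_variance")
        warnings.warn(
            f"subject {samples.subject_id!r}: bootstrap variance {var:g} at or below "
            f"floor {variance_floor:g}; precision weight capped",
            stacklevel=2,
        )
    if np.mean(samples.volumes) > 0:
        cv, cvw = cv_weight(samples, cv_floor=cv_floor)
    else:
        # empty ROI in every replicate: CV undefined, flagged downstream
        cv, cvw = float("nan"), float("nan")
        flags.append("empty_roi")
    return WeightRecord(
        subject_id=samples.subject_id,
        boot_variance=var,
        precision_weight=precision_weight(var, variance_floor),
        cv=cv,
        cv_weight=cvw,
        n_replicates=samples.volumes.size,
        flags=tuple(flags),
    )
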