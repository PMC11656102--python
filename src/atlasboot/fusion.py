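"""Multi-atlas label-fusion engines and ROI volume extraction.

Two desk-scale fusion engines are provided: plain majority voting and
locally weighted voting, in which each atlas's vote at a voxel is weighted
by the similarity between the atlas and target intensities over the patch
centred at that voxel.  Both are deterministic: identical inputs always
produce the identical fused label image (ties broken by smallest label id).

Engines expose per-atlas vote weights separately from the vote tally so
that the bootstrap layer can resample atlas collections without recomputing
the (collection-independent) weights; a collection drawn with replacement
is equivalent to integer multiplicities over the atlas pool.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import Atlas, IntensityImage, LabelImage

__all__ = [
    "FusionEngine",
    "MajorityVote",
    "LocalWeightedVote",
    "majority_vote",
    "local_weighted_vote",
    "roi_volume",
    "tally_votes",
]


def _check_atlases(atlases: list[Atlas], target: IntensityImage | None = None) -> None:
    if len(atlases) == 0:
        raise ValueError("at least one atlas is required")
    ref_shape = atlases[0].shape
    ref_vs = atlases[0].voxel_size
    for a in atlases:
        if a.shape != ref_shape:
            raise ValueError(f"atlas {a.id!r} shape {a.shape} != {ref_shape}")
        if a.voxel_size != ref_vs:
            raise ValueError(f"atlas {a.id!r} voxel_size {a.voxel_size} != {ref_vs}")
    if target is not None:
        if target.shape != ref_shape:
            raise ValueError(f"target shape {target.shape} != atlas shape {ref_shape}")
        if target.voxel_size != ref_vs:
            raise ValueError("target voxel_size differs from atlas voxel_size")


def tally_votes(
    label_stack: np.ndarray,
    weights: np.ndarray,
    multiplicities: np.ndarray | None = None,
) -> np.ndarray:
    """Accumulate weighted votes and return the winning label per voxel.

    Parameters
    ----------
    label_stack
        Integer array of shape ``(m, *grid)`` — one label grid per atlas.
    weights
        Per-atlas vote weights, shape ``(m,)`` or ``(m, *grid)``.
    multiplicities
        Optional integer multiplicity per atlas (how many times it occurs
        in the fused collection); defaults to 1 each.

    Ties are broken in favour of the smallest label id.
    """
    m = label_stack.shape[0]
    grid_shape = label_stack.shape[1:]
    w = np.asarray(weights, dtype=float)
    if w.ndim == 1:
        w = w.reshape((m,) + (1,) * len(grid_shape))
    if multiplicities is not None:
        mult = np.asarray(multiplicities, dtype=float).reshape((m,) + (1,) * len(grid_shape))
        w = w * mult
    labels = np.unique(label_stack)
    # score[l] = sum over atlases endorsing label l of their (weighted) votes
    scores = np.empty((labels.size,) + grid_shape, dtype=float)
    for k, lab in enumerate(labels):
        scores[k] = np.sum(w * (label_stack == lab), axis=0)
    # argmax returns the first maximum; labels are sorted ascending, so ties
    # resolve to the smallest label id
    winner = np.argmax(scores, axis=0)
    return labels[winner]


@dataclass(frozen=True)
class FusionEngine:
    """Base class for deterministic label-fusion engines."""

    name: str = "base"

    def vote_weights(self, target: IntensityImage, atlases: list[Atlas]) -> np.ndarray:
        """Per-atlas vote weights, shape ``(m,)`` or ``(m, *grid)``."""
        raise NotImplementedError

    def fuse(
        self,
        target: IntensityImage,
        atlases: list[Atlas],
        multiplicities: np.ndarray | None = None,
    ) -> LabelImage:
        _check_atlases(atlases, target)
        stack = np.stack([a.labels.labels for a in atlases])
        weights = self.vote_weights(target, atlases)
        fused = tally_votes(stack, weights, multiplicities)
        return LabelImage(fused.astype(np.int32), atlases[0].voxel_size)


@dataclass(frozen=True)
class MajorityVote(FusionEngine):
    """Each voxel takes the label endorsed by the most atlases."""

    name: str = "majority_vote"

    def vote_weights(self, target: IntensityImage, atlases: list[Atlas]) -> np.ndarray:
        return np.ones(len(atlases))


@dataclass(frozen=True)
class LocalWeightedVote(FusionEngine):
    """Votes weighted by local patch similarity between atlas and target.

    Atlas ``a`` at voxel ``v`` receives weight ``exp(-SSD_a(v) / (h * |patch|))``
    where ``SSD_a(v)`` is the sum of squared intensity differences over the
    cubic patch of radius ``patch_radius`` centred at ``v``, clipped at the
    image borders, and ``|patch|`` is the clipped patch voxel count.  The
    bandwidth ``h`` defaults to the sample variance of the target
    intensities, making the weighting adaptive to the intensity scale.
    """

    name: str = "local_weighted_vote"
    patch_radius: int = 1
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        if self.patch_radius < 0:
            raise ValueError("patch_radius must be >= 0")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")

    def vote_weights(self, target: IntensityImage, atlases: list[Atlas]) -> np.ndarray:
        h = self.bandwidth
        if h is None:
            h = float(np.var(target.values, ddof=1)) if target.values.size > 1 else 1.0
            if h <= 0:
                h = 1.0  # constant target: all patches equally (dis)similar
        k = 2 * self.patch_radius + 1
        kernel = np.ones((k, k, k))
        # clipped patch voxel count at each voxel (borders have smaller patches)
        counts = ndimage.correlate(
            np.ones(target.shape), kernel, mode="constant", cval=0.0
        )
        weights = np.empty((len(atlases),) + target.shape, dtype=float)
        for i, a in enumerate(atlases):
            sq_diff = (target.values - a.intensity.values) ** 2
            ssd = ndimage.correlate(sq_diff, kernel, mode="constant", cval=0.0)
            weights[i] = np.exp(-ssd / (h * counts))
        return weights


def majority_vote(atlases: list[Atlas]) -> LabelImage:
    """Fuse atlases by per-voxel majority vote (ties -> smallest label id)."""
    _check_atlases(atlases)
    dummy = IntensityImage(np.zeros(atlases[0].shape), atlases[0].voxel_size)
    return MajorityVote().fuse(dummy, atlases)


def local_weighted_vote(
    target: IntensityImage,
    atlases: list[Atlas],
    patch_radius: int = 1,
    bandwidth: float | None = None,
) -> LabelImage:
    """Fuse atlases by locally weighted voting against the target image."""
    return LocalWeightedVote(patch_radius=patch_radius, bandwidth=bandwidth).fuse(
        target, atlases
    )


def roi_volume(labels: LabelImage, roi_label: int) -> float:
    """Physical volume (mm^3) of the region carrying ``roi_label``.

    An absent label yields 0.
    """
    if roi_label < 0:
        raise ValueError("roi_label must be >= 0")
    count = int(np.count_nonzero(labels.labels == roi_label))
    return count * labels.voxel_volume
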