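"""Fusion engines: majority vote, locally weighted vote, ROI volume."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atlasboot import (
    IntensityImage,
    LabelImage,
    LocalWeightedVote,
    MajorityVote,
    local_weighted_vote,
    majority_vote,
    roi_volume,
)
from conftest import make_atlas


def grid(*vals):
    return np.array(vals).reshape(1, 1, -1)


class TestMajorityVote:
    def test_unanimity_returns_shared_labels(self):
        labels = np.arange(8).reshape(2, 2, 2) % 3
        atlases = [make_atlas(f"a{i}", labels) for i in range(5)]
        fused = majority_vote(atlases)
        np.testing.assert_array_equal(fused.labels, labels)

    def test_mode_and_smallest_id_tie_break(self):
        # voxel 0: labels {1,1,2} -> 1; voxel 1: {1,2,2} -> 2; voxel 2: tie {1,2} with a 0 -> ...
        a1 = make_atlas("a1", grid(1, 1, 1))
        a2 = make_atlas("a2", grid(1, 2, 2))
        a3 = make_atlas("a3", grid(2, 2, 1))
        fused = majority_vote([a1, a2, a3])
        np.testing.assert_array_equal(fused.labels, grid(1, 2, 1))

    def test_two_way_tie_takes_smallest_label(self):
        a1 = make_atlas("a1", grid(1))
        a2 = make_atlas("a2", grid(2))
        assert majority_vote([a1, a2]).labels[0, 0, 0] == 1

    def test_empty_atlas_list_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])

    def test_shape_mismatch_rejected(self):
        a1 = make_atlas("a1", np.zeros((2, 2, 2), dtype=int))
        a2 = make_atlas("a2", np.zeros((2, 2, 3), dtype=int))
        with pytest.raises(ValueError):
            majority_vote([a1, a2])

    def test_voxel_size_mismatch_rejected(self):
        a1 = make_atlas("a1", np.zeros((2, 2, 2), dtype=int))
        a2 = make_atlas("a2", np.zeros((2, 2, 2), dtype=int), voxel_size=(1, 1, 2))
        with pytest.raises(ValueError):
            majority_vote([a1, a2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.data())
    def test_matches_per_voxel_counting_oracle(self, data):
        """Fused label equals the smallest label among per-voxel count maxima."""
        m = data.draw(st.integers(1, 5))
        stacks = data.draw(
            st.lists(
                st.lists(st.integers(0, 2), min_size=4, max_size=4),
                min_size=m,
                max_size=m,
            )
        )
        atlases = [
            make_atlas(f"a{i}", np.array(lab).reshape(2, 2, 1)) for i, lab in enumerate(stacks)
        ]
        fused = majority_vote(atlases).labels
        arr = np.stack([a.labels.labels for a in atlases])
        for idx in np.ndindex(2, 2, 1):
            votes = arr[(slice(None),) + idx]
            counts = {lab: int(np.sum(votes == lab)) for lab in np.unique(votes)}
            best = max(counts.values())
            expected = min(lab for lab, c in counts.items() if c == best)
            assert fused[idx] == expected


def _lwv_oracle(target, atlases, patch_radius, bandwidth):
    """Naive loop implementation of locally weighted voting."""
    shape = target.shape
    out = np.zeros(shape, dtype=int)
    r = patch_radius
    for idx in np.ndindex(*shape):
        sl = tuple(
            slice(max(i - r, 0), min(i + r + 1, s)) for i, s in zip(idx, shape)
        )
        npatch = np.prod([s.stop - s.start for s in sl])
        scores = {}
        for a in atlases:
            ssd = float(np.sum((target.values[sl] - a.intensity.values[sl]) ** 2))
            w = np.exp(-ssd / (bandwidth * npatch))
            lab = int(a.labels.labels[idx])
            scores[lab] = scores.get(lab, 0.0) + w
        best = max(scores.values())
        out[idx] = min(lab for lab, s in scores.items() if s - best >= -1e-12 * best)
    return out


class TestLocalWeightedVote:
    def test_identical_intensities_reduce_to_majority_vote(self, rng):
        labels = [rng.integers(0, 3, size=(3, 3, 2)) for _ in range(4)]
        target_vals = rng.normal(size=(3, 3, 2))
        atlases = [make_atlas(f"a{i}", lab, intensity=target_vals) for i, lab in enumerate(labels)]
        target = IntensityImage(target_vals)
        fused = local_weighted_vote(target, atlases, patch_radius=1, bandwidth=1.0)
        np.testing.assert_array_equal(fused.labels, majority_vote(atlases).labels)

    def test_single_atlas_returns_its_labels(self, rng):
        lab = rng.integers(0, 2, size=(3, 3, 3))
        atlas = make_atlas("a0", lab, intensity=rng.normal(size=(3, 3, 3)))
        target = IntensityImage(rng.normal(size=(3, 3, 3)))
        fused = local_weighted_vote(target, [atlas])
        np.testing.assert_array_equal(fused.labels, lab)

    def test_lower_ssd_atlas_wins_hand_computed(self):
        # 3x3x1 scene; atlas a matches the target exactly, atlas b is off by 1
        # everywhere, so at every voxel w_a = 1 > w_b and a's label wins.
        target_vals = np.arange(9, dtype=float).reshape(3, 3, 1)
        a = make_atlas("a", np.full((3, 3, 1), 1), intensity=target_vals)
        b = make_atlas("b", np.full((3, 3, 1), 2), intensity=target_vals + 1.0)
        target = IntensityImage(target_vals)
        fused = local_weighted_vote(target, [a, b], patch_radius=1, bandwidth=1.0)
        # hand check of the center voxel: SSD_a=0 -> w=1; SSD_b=9*1 -> w=exp(-1)
        assert np.exp(-9 / (1.0 * 9)) < 1.0
        np.testing.assert_array_equal(fused.labels, np.full((3, 3, 1), 1))

    def test_matches_naive_loop_oracle(self, rng):
        target = IntensityImage(rng.normal(size=(4, 3, 2)))
        atlases = [
            make_atlas(
                f"a{i}",
                rng.integers(0, 3, size=(4, 3, 2)),
                intensity=rng.normal(size=(4, 3, 2)),
            )
            for i in range(3)
        ]
        fused = local_weighted_vote(target, atlases, patch_radius=1, bandwidth=0.7)
        oracle = _lwv_oracle(target, atlases, patch_radius=1, bandwidth=0.7)
        np.testing.assert_array_equal(fused.labels, oracle)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            LocalWeightedVote(patch_radius=-1)
        with pytest.raises(ValueError):
            LocalWeightedVote(bandwidth=0.0)


class TestEngineProperties:
    @pytest.mark.parametrize("engine", [MajorityVote(), LocalWeightedVote(bandwidth=1.0)])
    def test_unanimity_idempotence(self, engine, rng):
        lab = rng.integers(0, 4, size=(3, 3, 3))
        intens = rng.normal(size=(3, 3, 3))
        atlases = [make_atlas(f"a{i}", lab, intensity=intens) for i in range(4)]
        target = IntensityImage(rng.normal(size=(3, 3, 3)))
        fused = engine.fuse(target, atlases)
        np.testing.assert_array_equal(fused.labels, lab)

    @pytest.mark.parametrize("engine", [MajorityVote(), LocalWeightedVote(bandwidth=1.0)])
    def test_determinism_and_label_closure(self, engine, rng):
        atlases = [
            make_atlas(
                f"a{i}",
                rng.integers(0, 3, size=(3, 3, 2)),
                intensity=rng.normal(size=(3, 3, 2)),
            )
            for i in range(3)
        ]
        target = IntensityImage(rng.normal(size=(3, 3, 2)))
        f1 = engine.fuse(target, atlases)
        f2 = engine.fuse(target, atlases)
        np.testing.assert_array_equal(f1.labels, f2.labels)
        stack = np.stack([a.labels.labels for a in atlases])
        # every output label is endorsed by at least one atlas at that voxel
        assert np.all(np.any(stack == f1.labels[None], axis=0))


class TestRoiVolume:
    def test_absent_label_is_zero(self):
        img = LabelImage(np.zeros((2, 2, 2), dtype=np.int32))
        assert roi_volume(img, 5) == 0.0

    def test_count_times_voxel_volume(self):
        lab = np.zeros((2, 2, 2), dtype=np.int32)
        lab[0, 0, 0] = lab[0, 1, 0] = lab[1, 1, 1] = 3
        img = LabelImage(lab, voxel_size=(1.0, 1.0, 2.0))
        assert roi_volume(img, 3) == pytest.approx(6.0)

    def test_negative_label_rejected(self):
        img = LabelImage(np.zeros((2, 2, 2), dtype=np.int32))
        with pytest.raises(ValueError):
            roi_volume(img, -1)

    def test_voxelized_ellipsoid_matches_analytic_volume(self):
        from atlasboot.synthetic import _ellipsoid_mask

        a, b, c = 10.0, 8.0, 6.0
        mask = _ellipsoid_mask((50, 50, 50), (0.5, 0.5, 0.5), (a, b, c))
        img = LabelImage(mask.astype(np.int32), voxel_size=(0.5, 0.5, 0.5))
        analytic = 4.0 / 3.0 * np.pi * a * b * c
        assert roi_volume(img, 1) == pytest.approx(analytic, rel=0.05)

    def test_additive_over_disjoint_labels_and_scales_with_voxel_volume(self, rng):
        lab = rng.integers(0, 4, size=(4, 4, 4)).astype(np.int32)
        img1 = LabelImage(lab, voxel_size=(1, 1, 1))
        img2 = LabelImage(lab, voxel_size=(2, 1, 3))
        total1 = sum(roi_volume(img1, k) for k in range(4))
        assert total1 == pytest.approx(lab.size * 1.0)
        for k in range(4):
            assert roi_volume(img2, k) == pytest.approx(6.0 * roi_volume(img1, k))
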