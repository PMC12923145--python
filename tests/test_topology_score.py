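import numpy as np
import pytest

from conftest import oracle_cluster_stats
from ithkit.errors import DegenerateInputError, StageError
from ithkit.image_io import NoduleImage
from ithkit.subregion_clustering import ClusterMap
from ithkit.topology_score import (
    IthResult,
    TopologySummary,
    compute_ith,
    ith_score,
    label_components,
)


def _cmap(labels, K=None, mode=None):
    labels = np.asarray(labels, dtype=np.int32)
    if K is None:
        K = int(labels.max())
    if mode is None:
        mode = "2d" if labels.ndim == 2 else "3d"
    return ClusterMap(labels=labels, K=K, seed=0, mode=mode)


class TestLabelComponents:
    def test_solid_square_single_component(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[1:4, 1:4] = 1
        s = label_components(_cmap(labels))
        assert s.component_counts == (1,)
        assert s.largest_sizes == (9,)
        assert s.total == 9

    def test_diagonal_touch_is_connected_under_8(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[0, 0] = labels[1, 1] = 1
        s = label_components(_cmap(labels))
        assert s.component_counts == (1,)
        assert s.largest_sizes == (2,)

    def test_empty_cluster_recorded_as_zero(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[0, 0] = 1
        s = label_components(_cmap(labels, K=3))
        assert s.cluster_sizes == (1, 0, 0)
        assert s.component_counts == (1, 0, 0)
        assert s.largest_sizes == (1, 0, 0)

    def test_connectivity_mode_guard(self):
        labels = np.ones((3, 3), dtype=int)
        with pytest.raises(ValueError):
            label_components(_cmap(labels), connectivity=26)

    @pytest.mark.parametrize("ndim", [2, 3])
    def test_matches_flood_fill_oracle(self, rng, ndim):
        connectivity = 8 if ndim == 2 else 26
        for _ in range(60):
            shape = tuple(int(rng.integers(2, 13)) for _ in range(ndim))
            K = int(rng.integers(1, 5))
            labels = rng.integers(0, K + 1, size=shape)
            if not (labels > 0).any():
                labels.flat[0] = 1
            s = label_components(_cmap(labels, K=K), connectivity)
            expected = oracle_cluster_stats(labels, K, connectivity)
            got = list(zip(s.cluster_sizes, s.component_counts, s.largest_sizes))
            assert got == expected


class TestIthScore:
    def test_single_component_clusters_score_zero(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[:3, :] = 1
        labels[3:, :] = 2
        res = ith_score(label_components(_cmap(labels)))
        assert res.score == 0.0

    def test_hand_constructed_example(self):
        # 4x4 full mask: cluster B at opposite corners, cluster A elsewhere
        labels = np.full((4, 4), 1, dtype=int)
        labels[0, 3] = 2
        labels[3, 0] = 2
        s = label_components(_cmap(labels))
        assert s.component_counts == (1, 2)
        assert s.largest_sizes == (14, 1)
        res = ith_score(s)
        assert res.score == 1.0 - (14 + 0.5) / 16.0 == 0.09375

    def test_score_below_one(self, rng):
        for _ in range(25):
            labels = rng.integers(0, 4, size=(7, 7))
            if not (labels > 0).any():
                labels[0, 0] = 1
            res = ith_score(label_components(_cmap(labels, K=3)))
            assert 0.0 <= res.score < 1.0

    def test_zero_iff_all_single_components(self, rng):
        for _ in range(40):
            labels = rng.integers(0, 4, size=(6, 6))
            if not (labels > 0).any():
                labels[0, 0] = 1
            s = label_components(_cmap(labels, K=3))
            res = ith_score(s)
            all_single = all(c in (0, 1) for c in s.component_counts)
            assert (res.score == 0.0) == all_single

    def test_label_permutation_invariance(self, rng):
        labels = rng.integers(0, 5, size=(8, 8))
        labels[0, 0] = 1
        base = ith_score(label_components(_cmap(labels, K=4))).score
        perm = np.array([0, 3, 1, 4, 2])  # permutes labels 1..4
        permuted = perm[labels]
        assert ith_score(label_components(_cmap(permuted, K=4))).score == base

    def test_empty_everything_rejected(self):
        s = TopologySummary(cluster_sizes=(0,), component_counts=(0,),
                            largest_sizes=(0,), total=0, connectivity=8)
        with pytest.raises(DegenerateInputError):
            ith_score(s)

    def test_fragmentation_monotonicity_constructed(self, rng):
        # isolated cells on a step-3 lattice: splitting one component strictly
        # increases the score (the +1 companion pixel cannot touch other cells)
        for _ in range(30):
            grid = np.zeros((17, 17), dtype=int)
            cells = [(r, c) for r in range(0, 17, 3) for c in range(0, 17, 3)]
            rng.shuffle(cells)
            # cluster 1: one multi-pixel component + isolated singles
            big = cells.pop()
            grid[big] = 1
            grid[big[0] + 1, big[1]] = 1  # size-2 component
            for _ in range(int(rng.integers(0, 3))):
                grid[cells.pop()] = 1
            # cluster 2 background blob to vary totals
            grid[cells.pop()] = 2
            before = ith_score(label_components(_cmap(grid, K=2))).score
            # split the size-2 component: move one pixel to a fresh cell
            grid[big[0] + 1, big[1]] = 0
            grid[cells.pop()] = 1
            after = ith_score(label_components(_cmap(grid, K=2))).score
            assert after > before


class TestComputeIth:
    def test_determinism(self, ball_image):
        r1 = compute_ith(ball_image, "3d", K=3, seed=4)
        r2 = compute_ith(ball_image, "3d", K=3, seed=4)
        assert r1.score == r2.score
        assert r1.summary == r2.summary

    def test_result_provenance(self, ball_image):
        res = compute_ith(ball_image, "2d", K=3, seed=1)
        assert res.mode == "2d" and res.connectivity == 8
        assert res.K == 3 and res.N == 104 and res.seed == 1
        assert res.slice_index is not None
        assert 0.0 <= res.score < 1.0
        d = res.to_dict()
        assert {"mode", "score", "K", "N", "seed", "connectivity",
                "per_cluster"} <= set(d)

    def test_single_slice_mask_26_restricts_to_8(self, rng):
        # a one-slice-thick mask: 26-connectivity labeling restricted to the
        # plane must reproduce the 8-connectivity planar labeling
        labels2d = rng.integers(0, 4, size=(9, 9))
        labels2d[0, 0] = 1
        labels3d = labels2d[None, :, :]
        s2 = label_components(_cmap(labels2d, K=3, mode="2d"), 8)
        s3 = label_components(_cmap(labels3d, K=3, mode="3d"), 26)
        assert s2.cluster_sizes == s3.cluster_sizes
        assert s2.component_counts == s3.component_counts
        assert s2.largest_sizes == s3.largest_sizes

    def test_one_slice_mask_3d_pipeline_runs(self, rng):
        shape = (3, 14, 14)
        mask = np.zeros(shape, dtype=np.uint8)
        mask[1, 3:11, 3:11] = 1
        img = NoduleImage(intensities=rng.normal(-300, 40, shape), mask=mask)
        res = compute_ith(img, "3d", K=3, seed=0)
        assert 0.0 <= res.score < 1.0

    def test_stage_error_names_stage(self):
        mask = np.zeros((4, 6, 6), dtype=np.uint8)
        mask[1, 2, 2:5] = 1  # three voxels: fewer rows than K=6
        img = NoduleImage(intensities=np.zeros((4, 6, 6)), mask=mask)
        with pytest.raises(StageError) as err:
            compute_ith(img, "3d", K=6, seed=0)
        assert err.value.stage == "subregion_clustering"

    def test_mode_spec_mismatch(self, ball_image):
        from ithkit.local_features import FeatureBankSpec

        with pytest.raises(ValueError):
            compute_ith(ball_image, "3d", FeatureBankSpec(mode="2d"))

    def test_spacing_metadata_does_not_change_score(self, ball_image):
        res1 = compute_ith(ball_image, "3d", K=3, seed=2)
        img2 = NoduleImage(intensities=ball_image.intensities,
                           mask=ball_image.mask, spacing=(2.5, 0.33, 0.33))
        res2 = compute_ith(img2, "3d", K=3, seed=2)
        assert res1.score == res2.score
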