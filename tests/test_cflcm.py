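import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucleoprog.cflcm import (
    CFLCM_STAT_NAMES,
    ROI_STAT_NAMES,
    SkipROIError,
    aggregate_roi,
    aggregate_table,
    build_cflcm,
    build_neighbor_graph,
    cflcm_statistics,
    quantize_feature,
    roi_feature_names,
)

from oracles import bruteforce_cflcm, bruteforce_knn_edges, straightline_roi_vector


def _stat(vec, name):
    return vec[CFLCM_STAT_NAMES.index(name)]


class TestQuantize:
    def test_median_split(self):
        levels, _ = quantize_feature(np.array([1.0, 2.0, 3.0, 4.0]), 2)
        np.testing.assert_array_equal(levels, [1, 1, 2, 2])

    def test_constant_input_all_level_one(self):
        levels, _ = quantize_feature(np.full(7, 3.3), 4)
        np.testing.assert_array_equal(levels, 1)

    def test_equal_frequency_binning(self):
        rng = np.random.default_rng(0)
        levels, _ = quantize_feature(rng.standard_normal(1000), 8)
        counts = np.bincount(levels, minlength=9)[1:]
        assert np.all(np.abs(counts - 125) <= 1)

    def test_empty_input_raises(self):
        with pytest.raises(SkipROIError):
            quantize_feature(np.array([]), 2)


class TestNeighborGraph:
    def test_two_nuclei_one_edge(self):
        g = build_neighbor_graph(np.array([[0, 0], [3, 4]]), k=1)
        assert g.edges.tolist() == [[0, 1]]

    def test_three_collinear_equally_spaced(self):
        g = build_neighbor_graph(np.array([[0, 0], [0, 10], [0, 20]]), k=1)
        assert g.edges.tolist() == [[0, 1], [1, 2]]

    def test_single_nucleus_empty_edge_set(self):
        g = build_neighbor_graph(np.array([[5, 5]]), k=5)
        assert g.edges.shape == (0, 2)

    @pytest.mark.parametrize("seed,n,k", [(0, 10, 2), (1, 30, 5), (2, 50, 5), (3, 50, 1)])
    def test_matches_bruteforce_all_pairs(self, seed, n, k):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, size=(n, 2))
        g = build_neighbor_graph(pts, k=k)
        assert [tuple(e) for e in g.edges] == bruteforce_knn_edges(pts, k)

    def test_duplicate_centroids_deterministic(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0], [9.0, 9.0]])
        g1 = build_neighbor_graph(pts, k=1)
        g2 = build_neighbor_graph(pts, k=1)
        assert g1.edges.tolist() == g2.edges.tolist()

    def test_delaunay_triangle(self):
        pts = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 0.0]])
        g = build_neighbor_graph(pts, method="delaunay")
        assert [tuple(e) for e in g.edges] == [(0, 1), (0, 2), (1, 2)]


class TestBuildCFLCM:
    def test_uniform_levels_single_cell(self):
        g = build_neighbor_graph(np.array([[0, 0], [1, 0], [2, 0]]), k=1)
        m = build_cflcm(np.array([2, 2, 2]), g, n_levels=4)
        assert m.matrix[1, 1] == pytest.approx(1.0)
        assert m.matrix.sum() == pytest.approx(1.0)

    def test_two_nuclei_hand_count(self):
        g = build_neighbor_graph(np.array([[0, 0], [1, 0]]), k=1)
        m = build_cflcm(np.array([1, 2]), g, n_levels=2)
        np.testing.assert_allclose(m.matrix, [[0, 0.5], [0.5, 0]])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))  # all instances <= 20 nuclei
        pts = rng.uniform(0, 50, size=(n, 2))
        levels = rng.integers(1, 9, size=n)
        g = build_neighbor_graph(pts, k=3)
        ours = build_cflcm(levels, g, n_levels=8).matrix
        oracle = bruteforce_cflcm(levels, [tuple(e) for e in g.edges], 8)
        np.testing.assert_allclose(ours, oracle)

    def test_no_edges_degenerate(self):
        g = build_neighbor_graph(np.array([[0.0, 0.0]]), k=5)
        m = build_cflcm(np.array([1]), g, n_levels=4)
        assert m.degenerate
        np.testing.assert_array_equal(m.matrix, 0.0)


class TestCFLCMStatistics:
    def test_single_cell_mass(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        stats = cflcm_statistics(P)
        assert _stat(stats, "asm") == pytest.approx(1.0)
        assert _stat(stats, "entropy") == pytest.approx(0.0)
        assert _stat(stats, "contrast") == pytest.approx(0.0)

    def test_antidiagonal_closed_form(self):
        stats = cflcm_statistics(np.array([[0, 0.5], [0.5, 0]]))
        assert _stat(stats, "contrast") == pytest.approx(1.0)
        assert _stat(stats, "asm") == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_definitional_bounds_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.random((8, 8))
        M = M + M.T
        P = M / M.sum()
        stats = cflcm_statistics(P)
        assert _stat(stats, "entropy") >= 0
        assert _stat(stats, "asm") <= 1
        assert _stat(stats, "max_probability") == pytest.approx(P.max())
        assert _stat(stats, "homogeneity") <= 1 + 1e-12

    def test_degenerate_zero_matrix_all_zero(self):
        np.testing.assert_array_equal(cflcm_statistics(np.zeros((8, 8))), 0.0)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="not normalized"):
            cflcm_statistics(np.full((2, 2), 0.4))


class TestAggregateROI:
    def _toy(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 6))
        C = rng.uniform(0, 100, size=(n, 2))
        return X, C

    def test_output_length_is_twelve_per_feature(self):
        X, C = self._toy()
        vec = aggregate_roi(X, C)
        assert vec.shape == (12 * 6,)
        assert len(ROI_STAT_NAMES) == 12

    def test_identical_nuclei_zero_spread(self):
        X = np.ones((8, 3)) * 4.2
        C = np.random.default_rng(1).uniform(0, 50, size=(8, 2))
        vec = aggregate_roi(X, C).reshape(3, 12)
        names = ROI_STAT_NAMES
        assert np.allclose(vec[:, names.index("mean")], 4.2)
        assert np.allclose(vec[:, names.index("sd")], 0.0)
        assert np.allclose(vec[:, names.index("cflcm_contrast")], 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_straightline_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((5, 4))
        C = rng.uniform(0, 30, size=(5, 2))
        ours = aggregate_roi(X, C, min_nuclei=5)
        oracle = straightline_roi_vector(X, C)
        np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_permutation_invariance(self):
        X, C = self._toy(n=15, seed=3)
        perm = np.random.default_rng(4).permutation(15)
        np.testing.assert_allclose(
            aggregate_roi(X, C), aggregate_roi(X[perm], C[perm]), atol=1e-12
        )

    def test_spatial_mixing_changes_contrast_not_marginals(self):
        # same per-nucleus values, clustered vs interleaved layouts
        values = np.array([0.0] * 10 + [10.0] * 10)
        grid = np.array([[0.0, 10.0 * i] for i in range(20)])
        clustered = aggregate_roi(values[:, None], grid, k=2).reshape(1, 12)
        inter_vals = np.empty(20)
        inter_vals[0::2] = 0.0
        inter_vals[1::2] = 10.0
        interleaved = aggregate_roi(inter_vals[:, None], grid, k=2).reshape(1, 12)
        names = ROI_STAT_NAMES
        assert clustered[0, names.index("mean")] == interleaved[0, names.index("mean")]
        assert clustered[0, names.index("sd")] == interleaved[0, names.index("sd")]
        assert (
            interleaved[0, names.index("cflcm_contrast")]
            > clustered[0, names.index("cflcm_contrast")] + 1.0
        )

    def test_below_minimum_nucleus_count_skips(self):
        X, C = self._toy(n=3)
        with pytest.raises(SkipROIError):
            aggregate_roi(X, C, min_nuclei=5)

    def test_aggregate_table_groups_and_names(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        frames = []
        for roi in ("r1", "r2"):
            df = pd.DataFrame(rng.standard_normal((8, 3)), columns=["f1", "f2", "f3"])
            df.insert(0, "centroid_col", rng.uniform(0, 10, 8))
            df.insert(0, "centroid_row", rng.uniform(0, 10, 8))
            df.insert(0, "nucleus_id", np.arange(1, 9))
            df.insert(0, "roi_id", roi)
            df.insert(0, "case_id", "c1")
            frames.append(df)
        out = aggregate_table(pd.concat(frames, ignore_index=True))
        assert len(out) == 2
        assert list(out.columns[2:]) == roi_feature_names(["f1", "f2", "f3"])


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40),
    st.integers(2, 8),
)
def test_quantize_levels_within_range(values, n_levels):
    levels, edges = quantize_feature(np.array(values), n_levels)
    assert levels.min() >= 1
    assert levels.max() <= n_levels
    assert len(edges) == n_levels + 1
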