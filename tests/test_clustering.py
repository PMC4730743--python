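import itertools

import numpy as np
import pandas as pd
import pytest

from clonofit.clustering import (
    DistanceMatrix,
    agglomerate,
    best_cut,
    cut_tree,
    euclidean_distances,
    feature_variants,
    silhouette,
    to_newick,
)
from clonofit.errors import ValidationError

from conftest import make_dataset


def dm_from_points(pts, labels=None):
    pts = np.asarray(pts, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    return euclidean_distances(pts, labels=labels)


FOUR_POINTS = dm_from_points([0.0, 1.0, 10.0, 11.0], labels=list("abcd"))


class TestEuclideanDistances:
    def test_identical_rows_have_zero_distance(self):
        D = dm_from_points([[1.0, 2.0], [1.0, 2.0]])
        assert D.d[0, 1] == 0.0

    def test_three_four_five_triangle(self):
        D = dm_from_points([[0.0, 0.0], [3.0, 4.0]])
        assert D.d[0, 1] == pytest.approx(5.0)

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 3))
        D = euclidean_distances(X)
        for i in range(4):
            for j in range(4):
                expected = np.sqrt(np.sum((X[i] - X[j]) ** 2))
                assert D.d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))


def brute_force_ward(X):
    """Exhaustive Ward oracle: at each step merge the pair of clusters
    whose fusion adds the least within-cluster error sum of squares.
    Returns the merge sequence as frozensets of leaf indices."""
    X = np.asarray(X, dtype=float)

    def ess(idx):
        sub = X[list(idx)]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d_ess = ess(a | b) - ess(a) - ess(b)
            if best is None or d_ess < best[0] - 1e-12:
                best = (d_ess, a, b)
        _, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        merges.append(a | b)
    return merges


def scipy_merge_sets(dend):
    """Leaf-index sets created by each merge of a linkage matrix."""
    n = dend.n_leaves
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for row_idx, (a, b, _, _) in enumerate(dend.merges):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        out.append(merged)
    return out


class TestAgglomerate:
    def test_two_well_separated_pairs(self):
        dend = agglomerate(FOUR_POINTS, "ward")
        sol = cut_tree(dend, 2)
        assert sol.labels["a"] == sol.labels["b"]
        assert sol.labels["c"] == sol.labels["d"]
        assert sol.labels["a"] != sol.labels["c"]

    def test_two_leaves_merge_at_their_distance(self):
        D = dm_from_points([[0.0], [3.0]])
        dend = agglomerate(D, "ward")
        assert dend.merges.shape == (1, 4)
        assert dend.heights[0] == pytest.approx(3.0)

    def test_duplicated_points_merge_first_at_zero(self):
        D = dm_from_points([0.0, 5.0, 0.0])
        dend = agglomerate(D, "ward")
        assert dend.heights[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_brute_force_ess_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        for rep in range(20):
            X = rng.normal(size=(n, 3))
            dend = agglomerate(euclidean_distances(X), "ward")
            assert scipy_merge_sets(dend) == brute_force_ward(X)

    def test_ward_heights_non_decreasing(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            X = rng.normal(size=(8, 4))
            dend = agglomerate(euclidean_distances(X), "ward")
            assert np.all(np.diff(dend.heights) >= -1e-12)

    def test_ward_d_variant_differs_only_in_heights_here(self):
        dend2 = agglomerate(FOUR_POINTS, "ward_d")
        dend = agglomerate(FOUR_POINTS, "ward")
        assert scipy_merge_sets(dend2) == scipy_merge_sets(dend)
        assert np.all(np.diff(dend2.heights) >= -1e-12)

    def test_unknown_linkage_rejected(self):
        with pytest.raises(ValidationError):
            agglomerate(FOUR_POINTS, "median")


class TestCuts:
    def test_extreme_cuts(self):
        dend = agglomerate(FOUR_POINTS, "ward")
        assert len(set(cut_tree(dend, 4).labels.values())) == 4
        assert len(set(cut_tree(dend, 1).labels.values())) == 1
        with pytest.raises(ValidationError):
            cut_tree(dend, 5)

    def test_best_cut_finds_the_two_pairs(self):
        sol = best_cut(agglomerate(FOUR_POINTS, "ward"))
        assert sol.k == 2
        assert sol.labels["a"] == sol.labels["b"]
        assert sol.labels["c"] == sol.labels["d"]

    def test_best_cut_gap_matches_hand_computation(self):
        dend = agglomerate(FOUR_POINTS, "ward")
        h = dend.heights  # [1, 1, 10]: the k=2 gap (10 - 1) dominates
        gaps = {k: h[4 - k] - h[4 - k - 1] for k in (2, 3)}
        assert max(gaps, key=gaps.get) == 2


class TestSilhouette:
    def test_hand_computed_widths(self):
        sol = cut_tree(agglomerate(FOUR_POINTS, "ward"), 2)
        res = silhouette(FOUR_POINTS, sol)
        assert res.s["a"] == pytest.approx((10.5 - 1) / 10.5, abs=1e-4)
        assert res.s["b"] == pytest.approx((9.5 - 1) / 9.5, abs=1e-4)
        assert res.average == pytest.approx(0.8997, abs=1e-4)

    def test_identical_point_clusters_score_one(self):
        D = dm_from_points([0.0, 0.0, 9.0, 9.0])
        sol = cut_tree(agglomerate(D, "ward"), 2)
        assert all(v == pytest.approx(1.0) for v in silhouette(D, sol).s.values())

    def test_singleton_cluster_scores_zero(self):
        D = dm_from_points([0.0, 1.0, 9.0], labels=list("abc"))
        sol = cut_tree(agglomerate(D, "ward"), 2)
        assert silhouette(D, sol).s["c"] == 0.0

    def test_single_cluster_is_undefined(self):
        sol = cut_tree(agglomerate(FOUR_POINTS, "ward"), 1)
        with pytest.raises(ValidationError):
            silhouette(FOUR_POINTS, sol)

    def test_widths_bounded_on_random_panels(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            X = rng.normal(size=(7, 4))
            D = euclidean_distances(X)
            sol = cut_tree(agglomerate(D, "ward"), int(rng.integers(2, 6)))
            res = silhouette(D, sol)
            vals = np.array(list(res.s.values()))
            assert np.all((vals >= -1) & (vals <= 1))
            assert res.average == pytest.approx(vals.mean())


class TestFeatureVariants:
    def test_shapes(self, panel):
        assert feature_variants(panel, "raw_percent").shape == (9, 6)
        assert feature_variants(panel, "sf2_only").shape == (9, 1)

    def test_log_mode_of_equal_rows_gives_zero_distances(self):
        ds = make_dataset([("A", "R1", 0.0, 1.0), ("A", "R1", 2.0, 0.5),
                           ("B", "R1", 0.0, 1.0), ("B", "R1", 2.0, 0.5)])
        D = euclidean_distances(feature_variants(ds, "log"))
        assert np.allclose(D.d, 0.0)

    def test_sf2_requires_dose_two(self):
        ds = make_dataset([("A", "R1", 0.0, 1.0), ("A", "R1", 4.0, 0.5),
                           ("B", "R1", 0.0, 1.0), ("B", "R1", 4.0, 0.4)])
        with pytest.raises(ValidationError):
            feature_variants(ds, "sf2_only")


def test_newick_export_parses_and_preserves_leaves():
    dendropy = pytest.importorskip("dendropy")
    dend = agglomerate(FOUR_POINTS, "ward")
    tree = dendropy.Tree.get(data=to_newick(dend), schema="newick")
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    assert leaves == {"a", "b", "c", "d"}
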