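"""Filters, uncentered-correlation/centroid clustering (against a
brute-force oracle) and the survival-guided C1 call."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirhub.containers import ExpressionMatrix
from mirhub.preprocess import (
    assign_c1,
    cut_k_branches,
    filter_detected,
    filter_top_variance,
    hierarchical_cluster,
    uncentered_correlation_distance,
)


def _expr(arr, features=None, samples=None, scale="raw"):
    arr = np.asarray(arr)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=features, columns=samples), scale=scale)


def _labels(sample_ids, c1_ids):
    return pd.Series([s in set(c1_ids) for s in sample_ids], index=sample_ids)


class TestDetectionFilter:
    def test_or_semantics_keeps_group_specific_feature(self):
        expr = _expr([[5, 5, 5, 0, 0, 0]])
        is_c1 = _labels(expr.sample_ids, expr.sample_ids[:3])
        out = filter_detected(expr, is_c1=is_c1)
        assert out.feature_ids == ["f0"]

    def test_all_zero_feature_dropped_and_subthreshold_dropped(self):
        expr = _expr([[0, 0, 0, 0, 0, 0], [3, 0, 0, 2, 0, 0], [1, 2, 3, 4, 5, 6]])
        is_c1 = _labels(expr.sample_ids, expr.sample_ids[:3])
        out = filter_detected(expr, is_c1=is_c1)
        # f1 detected in 1/3 of each group: below 0.5 in both
        assert out.feature_ids == ["f2"]

    def test_idempotent(self, small_cohort):
        mirna, _gene, _clin, truth, _cfg = small_cohort
        is_c1 = truth.subtype_of == "C1"
        once = filter_detected(mirna, is_c1=is_c1)
        twice = filter_detected(once, is_c1=is_c1)
        assert once.feature_ids == twice.feature_ids


class TestVarianceFilter:
    def test_top_quartile_of_100_features(self, rng):
        sds = np.arange(1.0, 101.0)
        arr = rng.normal(size=(100, 60)) * sds[:, None]
        out = filter_top_variance(_expr(arr, scale="log2"), 0.75)
        assert out.n_features == 25

    def test_sds_1_to_8_keeps_top_two_with_linear_interpolation(self, rng):
        # SD quantile(0.75) of 1..8 = 6.25 by linear interpolation -> keep {7, 8}
        z = rng.normal(size=60)
        z = (z - z.mean()) / z.std(ddof=1)
        arr = np.vstack([z * s for s in range(1, 9)])
        out = filter_top_variance(_expr(arr, scale="log2"), 0.75)
        assert out.feature_ids == ["f6", "f7"]

    def test_degenerate_all_equal_warns_and_keeps_all(self):
        arr = np.tile([1.0, 2.0, 3.0, 4.0], (5, 1))
        with pytest.warns(UserWarning):
            out = filter_top_variance(_expr(arr, scale="log2"), 0.75)
        assert out.n_features == 5

    def test_deterministic_and_monotone_in_quantile(self, rng):
        # the retained set is reproducible, and a stricter quantile retains
        # a subset of a looser one
        arr = rng.normal(size=(40, 30))
        expr = _expr(arr, scale="log2")
        once = filter_top_variance(expr, 0.75)
        again = filter_top_variance(expr, 0.75)
        assert once.feature_ids == again.feature_ids
        loose = filter_top_variance(expr, 0.5)
        assert set(once.feature_ids) <= set(loose.feature_ids)


class TestUncenteredCorrelationDistance:
    def test_identity_orthogonal_antiparallel(self):
        assert uncentered_correlation_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0)
        assert uncentered_correlation_distance([1, 0], [0, 1]) == pytest.approx(1)
        assert uncentered_correlation_distance([1, 1], [-1, -1]) == pytest.approx(2)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            uncentered_correlation_distance([0, 0], [1, 2])

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        st.floats(0.01, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_scale_invariant(self, xs, ys, c):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        if np.linalg.norm(x) < 1e-6 or np.linalg.norm(y) < 1e-6:
            return
        d_xy = uncentered_correlation_distance(x, y)
        assert d_xy == pytest.approx(uncentered_correlation_distance(y, x))
        assert d_xy == pytest.approx(uncentered_correlation_distance(c * x, y), abs=1e-8)


def brute_force_centroid_linkage(M):
    """Independent re-derivation: exhaustive scan, centroids recomputed from
    scratch from original member vectors at every step."""
    clusters = {i: [i] for i in range(M.shape[0])}
    ids = {i: i for i in range(M.shape[0])}
    merges = []
    next_id = M.shape[0]
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a_pos in range(len(keys)):
            for b_pos in range(a_pos + 1, len(keys)):
                a, b = keys[a_pos], keys[b_pos]
                ca = M[clusters[a]].mean(axis=0)
                cb = M[clusters[b]].mean(axis=0)
                d = 1 - (ca @ cb) / (np.linalg.norm(ca) * np.linalg.norm(cb))
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((min(ids[a], ids[b]), max(ids[a], ids[b]), d))
        clusters[a] = clusters[a] + clusters[b]
        ids[a] = next_id
        del clusters[b], ids[b]
        next_id += 1
    return merges


class TestHierarchicalClustering:
    def test_identical_pair_merges_first_at_height_zero(self):
        arr = np.array([[1.0, 5.0, 1.0], [2.0, 5.0, 2.0]])  # samples 0 and 2 identical
        d = hierarchical_cluster(_expr(arr, scale="log2"), center=None)
        a, b, h = d.merges[0]
        assert {a, b} == {0, 2}
        assert h == pytest.approx(0, abs=1e-12)

    @pytest.mark.parametrize("n_items,seed", [(5, 0), (7, 1), (8, 2)])
    def test_merge_sequence_matches_brute_force_oracle(self, n_items, seed):
        rng = np.random.default_rng(seed)
        arr = rng.uniform(0.5, 4.0, size=(4, n_items))
        d = hierarchical_cluster(_expr(arr, scale="log2"), center=None)
        oracle = brute_force_centroid_linkage(arr.T)
        assert len(d.merges) == len(oracle)
        for (a, b, h), (oa, ob, oh) in zip(d.merges, oracle):
            assert (a, b) == (oa, ob)
            assert h == pytest.approx(oh, abs=1e-10)

    def test_duplicating_samples_preserves_distinct_point_structure(self):
        # duplicating every sample first pairs off the duplicates at height
        # ~0, after which the between-centroid merge heights reproduce the
        # distinct-point dendrogram (centroids and relative sizes unchanged)
        rng = np.random.default_rng(3)
        arr = rng.uniform(0.5, 4.0, size=(4, 4))
        base = hierarchical_cluster(_expr(arr, scale="log2"), center=None)
        dup = np.hstack([arr, arr])
        d = hierarchical_cluster(_expr(dup, scale="log2"), center=None)
        assert all(h == pytest.approx(0, abs=1e-10) for _, _, h in d.merges[:4])
        dup_heights = sorted(h for _, _, h in d.merges[4:])
        base_heights = sorted(h for _, _, h in base.merges)
        assert dup_heights == pytest.approx(base_heights, abs=1e-10)


class TestCutBranches:
    def test_extreme_k(self, rng):
        arr = rng.normal(size=(3, 6)) + 5
        d = hierarchical_cluster(_expr(arr, scale="log2"), center=None)
        assert cut_k_branches(d, 6).nunique() == 6
        assert cut_k_branches(d, 1).nunique() == 1

    def test_six_leaf_cut_matches_manual_partition(self):
        # three tight pairs along distinct directions: cutting at k=3 must
        # recover the pairs; k=4 splits the loosest pair
        base = np.array(
            [[1, 0.02, 0], [1, 0, 0.02], [0, 1, 0.1], [0.1, 1, 0], [0.3, 0, 1], [0, 0.3, 1]]
        ).T
        d = hierarchical_cluster(_expr(base, scale="log2"), center=None)
        three = cut_k_branches(d, 3)
        groups = {frozenset(three.index[three == c]) for c in three.unique()}
        assert groups == {frozenset({"s0", "s1"}), frozenset({"s2", "s3"}), frozenset({"s4", "s5"})}


class TestAssignC1:
    def test_all_early_death_cluster_is_c1(self):
        clusters = pd.Series([1, 1, 2, 2, 3, 3], index=[f"s{i}" for i in range(6)])
        clinical = pd.DataFrame(
            {
                "age": 60,
                "sex": "M",
                "smoking": "never",
                "stage": "I",
                "time": [0.2, 0.4, 5.0, 5.0, 5.0, 5.0],
                "event": [1, 1, 0, 0, 0, 0],
            },
            index=clusters.index,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lab = assign_c1(clusters, clinical)
        assert lab.c1_cluster_id == 1
        assert set(lab.c1_samples) == {"s0", "s1"}
        assert set(lab.pooling_pvalues) == {(2, 3)}

    def test_identical_survival_breaks_tie_deterministically_with_warning(self):
        clusters = pd.Series([1, 1, 2, 2], index=["a", "b", "c", "d"])
        clinical = pd.DataFrame(
            {
                "age": 60,
                "sex": "F",
                "smoking": "never",
                "stage": "I",
                "time": [1.0, 2.0, 1.0, 2.0],
                "event": [1, 0, 1, 0],
            },
            index=clusters.index,
        )
        with pytest.warns(UserWarning, match="tied survival"):
            lab = assign_c1(clusters, clinical)
        assert lab.c1_cluster_id == 1

    def test_planted_worst_prognosis_cluster_recovered(self, small_cohort):
        mirna, gene, clinical, truth, _cfg = small_cohort
        # use the true branches as the cluster assignment; C1 must win
        clusters = truth.branch_of.map({"C1": 1, "C2": 2, "C3": 3, "C4": 4})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lab = assign_c1(clusters, clinical)
        assert (lab.is_c1 == (truth.subtype_of == "C1")).all()
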