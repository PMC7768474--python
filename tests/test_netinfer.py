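"""MI estimation, DPI pruning, bootstrap consensus and the rewiring cascade."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from mirhub.containers import ExpressionMatrix
from mirhub.netinfer import (
    AracneConfig,
    InteractionNetwork,
    RewiringResult,
    aracne_single,
    bootstrap_consensus,
    dpi_prune,
    mutual_information,
    rewire_c1,
    select_hubs,
)


def plugin_mi(x, y, bins):
    """Brute-force plug-in MI of rank-binned data, in nats."""
    rx, ry = rankdata(x), rankdata(y)
    H, _, _ = np.histogram2d(rx, ry, bins=bins)
    P = H / H.sum()
    px, py = P.sum(axis=1), P.sum(axis=0)
    nz = P > 0
    return float((P[nz] * np.log(P[nz] / np.outer(px, py)[nz])).sum())


class TestMutualInformation:
    def test_independent_vectors_score_null(self, rng):
        x, y = rng.normal(size=500), rng.normal(size=500)
        mi, p = mutual_information(x, y, n_null_perm=200, seed=1)
        assert p > 0.05
        null_mis = [
            mutual_information(x, rng.permutation(y), n_null_perm=50, seed=2)[0]
            for _ in range(20)
        ]
        assert abs(mi - np.mean(null_mis)) < 2 * (np.std(null_mis) + 1e-9) + 0.05

    def test_identity_matches_plugin_oracle_within_5_percent(self, rng):
        x = rng.normal(size=500)
        mi, p = mutual_information(x, x, n_null_perm=200, seed=1)
        # the chi-square stop rule terminates at ~4 points per cell, i.e. a
        # dyadic grid of ~n/4 bins per margin
        bins = 2 ** int(round(np.log2(len(x) / 4)))
        oracle = plugin_mi(x, x, bins)
        assert mi == pytest.approx(oracle, rel=0.05)
        assert p <= 1 / (200 + 1) + 1e-12

    def test_decreasing_relation_scores_like_increasing(self, rng):
        x = rng.normal(size=400)
        mi_up, _ = mutual_information(x, x, n_null_perm=100, seed=1)
        mi_dn, _ = mutual_information(x, -x, n_null_perm=100, seed=1)
        assert mi_dn == pytest.approx(mi_up, rel=1e-9)

    def test_symmetry_and_monotone_invariance(self, rng):
        x = rng.normal(size=300)
        y = x + rng.normal(size=300)
        for estimator in ("adaptive_partitioning", "rank_gaussian"):
            mi_xy, _ = mutual_information(x, y, estimator, n_null_perm=100, seed=0)
            mi_yx, _ = mutual_information(y, x, estimator, n_null_perm=100, seed=0)
            mi_tr, _ = mutual_information(np.exp(x), y**3, estimator, n_null_perm=100, seed=0)
            assert mi_xy == pytest.approx(mi_yx, rel=1e-6)
            assert mi_tr == pytest.approx(mi_xy, rel=1e-6)

    def test_constant_vector_returns_zero(self):
        mi, p = mutual_information(np.ones(50), np.arange(50.0), n_null_perm=100)
        assert (mi, p) == (0.0, 1.0)


class TestDpi:
    def test_tolerance_one_disables_pruning(self):
        edges = {("r1", "t"): 0.1, ("r2", "t"): 1.0}
        kept = dpi_prune(edges, lambda a, b: 1.0, tolerance=1.0)
        assert kept == edges

    def test_equal_mi_triangle_retained(self):
        edges = {("r1", "t"): 0.5, ("r2", "t"): 0.5}
        kept = dpi_prune(edges, lambda a, b: 0.5, tolerance=0.0)
        assert kept == edges

    def test_weakest_edge_of_chain_removed(self):
        edges = {("r1", "t"): 0.2, ("r2", "t"): 0.9}
        kept = dpi_prune(edges, lambda a, b: 0.8, tolerance=0.0)
        assert set(kept) == {("r2", "t")}

    def test_never_grows_and_idempotent(self, rng):
        regs = [f"r{i}" for i in range(6)]
        mi_rr = {(a, b): rng.uniform(0, 1) for a in regs for b in regs if a < b}
        reg_mi = lambda a, b: mi_rr[(min(a, b), max(a, b))]  # noqa: E731
        edges = {(r, f"t{j}"): rng.uniform(0, 1) for r in regs for j in range(4)}
        once = dpi_prune(edges, reg_mi, tolerance=0.1)
        assert set(once) <= set(edges)
        twice = dpi_prune(once, reg_mi, tolerance=0.1)
        assert once == twice

    def test_simulated_chain_removes_indirect_edge(self, rng):
        # r -> m -> t chain: MI(r, t) is smallest; the r-t edge must go
        removed = 0
        n_sim = 40
        for _ in range(n_sim):
            r = rng.normal(size=500)
            m = r + rng.normal(scale=0.7, size=500)
            t = m + rng.normal(scale=0.7, size=500)
            mis = {}
            for name, (a, b) in {"rm": (r, m), "mt": (m, t), "rt": (r, t)}.items():
                mis[name], _ = mutual_information(a, b, "rank_gaussian", n_null_perm=100, seed=0)
            edges = {("r", "t"): mis["rt"], ("m", "t"): mis["mt"]}
            kept = dpi_prune(edges, lambda a, b: mis["rm"], tolerance=0.0)
            if ("r", "t") not in kept and ("m", "t") in kept:
                removed += 1
        assert removed / n_sim >= 0.95


def _paired_matrices(rng, n=200, n_reg=6, n_tar=30, coupled=0):
    reg = rng.normal(size=(n_reg, n))
    tar = rng.normal(size=(n_tar, n))
    for j in range(coupled):
        tar[j] = -reg[0] + rng.normal(scale=0.5, size=n)
    mir = pd.DataFrame(reg, index=[f"r{i}" for i in range(n_reg)], columns=[f"s{j}" for j in range(n)])
    gen = pd.DataFrame(tar, index=[f"t{i}" for i in range(n_tar)], columns=[f"s{j}" for j in range(n)])
    return mir, gen


class TestAracne:
    def test_null_edge_rate_bounded(self, rng):
        mir, gen = _paired_matrices(rng)
        cfg = AracneConfig(mi_estimator="rank_gaussian", mi_pvalue_threshold=1e-3, seed=4)
        net = aracne_single(mir, gen, list(mir.index), cfg)
        n_pairs = mir.shape[0] * gen.shape[0]
        # expected false edges ~ threshold * pairs; allow generous slack
        assert net.n_edges <= max(5, 5 * 1e-3 * n_pairs)

    def test_planted_hub_fully_recovered(self, rng):
        mir, gen = _paired_matrices(rng, coupled=10)
        cfg = AracneConfig(mi_estimator="rank_gaussian", seed=4)
        net = aracne_single(mir, gen, list(mir.index), cfg)
        recovered = {t for r, t in net.edge_set if r == "r0"}
        assert {f"t{j}" for j in range(10)} <= recovered

    def test_single_pair_dpi_noop(self, rng):
        mir, gen = _paired_matrices(rng, n_reg=1, n_tar=1, coupled=1)
        cfg = AracneConfig(mi_estimator="rank_gaussian", seed=0)
        net = aracne_single(mir, gen, ["r0"], cfg)
        assert net.edge_set == {("r0", "t0")}

    def test_empty_regulators_rejected(self, rng):
        mir, gen = _paired_matrices(rng, n=50)
        with pytest.raises(ValueError):
            aracne_single(mir, gen, [], AracneConfig())


class TestBootstrapConsensus:
    def test_planted_edges_high_support_null_near_empty(self, rng):
        mir, gen = _paired_matrices(rng, coupled=8)
        cfg = AracneConfig(mi_estimator="rank_gaussian", n_bootstraps=60, seed=9)
        net = bootstrap_consensus(mir, gen, list(mir.index), cfg)
        true_edges = {("r0", f"t{j}") for j in range(8)}
        support = net.edges.set_index(["regulator", "target"])["support"]
        planted = [support.get(e, 0.0) for e in sorted(true_edges)]
        assert np.median(planted) >= 0.8
        false_edges = net.edge_set - true_edges
        assert len(false_edges) <= 0.05 * mir.shape[0] * gen.shape[0]

    def test_fully_independent_data_nearly_empty(self, rng):
        mir, gen = _paired_matrices(rng)
        cfg = AracneConfig(mi_estimator="rank_gaussian", n_bootstraps=40, seed=2)
        net = bootstrap_consensus(mir, gen, list(mir.index), cfg)
        assert net.n_edges <= 0.05 * mir.shape[0] * gen.shape[0]


def _net(edges, stratum):
    df = pd.DataFrame(
        [(r, t, 1.0, 1.0) for r, t in sorted(edges)],
        columns=["regulator", "target", "mi", "support"],
    )
    return InteractionNetwork(edges=df, stratum=stratum)


def _de_table(rows):
    return pd.DataFrame(
        {k: [v[i] for v in rows.values()] for i, k in enumerate(("log2_fc", "p"))},
        index=list(rows),
    )


class TestRewiring:
    def _networks(self, c1_edges, non_c1_edges):
        return {
            "C1:all": _net(c1_edges, "C1:all"),
            "C1:stageI": _net(c1_edges, "C1:stageI"),
            "nonC1:all": _net(non_c1_edges, "nonC1:all"),
        }

    def test_empty_predictions_empty_rules_2_to_4(self):
        nets = self._networks({("m1", "g1")}, set())
        de_m = _de_table({"m1": (1.0, 1e-4)})
        de_g = _de_table({"g1": (-1.0, 1e-4)})
        res = rewire_c1(nets, set(), de_m, de_g)
        assert res.rule1 == {("m1", "g1")}
        assert res.rule2 == res.rule3 == res.rule4 == set()

    def test_edge_shared_with_non_c1_eliminated_at_rule1(self):
        nets = self._networks({("m1", "g1"), ("m1", "g2")}, {("m1", "g1")})
        de_m = _de_table({"m1": (1.0, 1e-4)})
        de_g = _de_table({"g1": (-1.0, 1e-4), "g2": (-1.0, 1e-4)})
        res = rewire_c1(nets, {("m1", "g1"), ("m1", "g2")}, de_m, de_g, min_degree=1)
        assert res.rule1 == {("m1", "g2")}

    def test_trend_rule_requires_opposite_signs_and_gene_significance(self):
        edges = {("m1", "g1"), ("m1", "g2"), ("m1", "g3")}
        nets = self._networks(edges, set())
        de_m = _de_table({"m1": (1.0, 1e-4)})
        de_g = _de_table({"g1": (-1.0, 1e-4), "g2": (1.0, 1e-4), "g3": (-1.0, 0.5)})
        res = rewire_c1(nets, edges, de_m, de_g, min_degree=1)
        assert res.rule3 == {("m1", "g1")}  # g2 same trend, g3 not significant

    def test_cardinalities_nested(self, small_cohort):
        from mirhub.config import PipelineConfig
        from mirhub.pipeline import infer_hub_candidates
        from mirhub.syndata import generate_target_predictions

        mirna, gene, clinical, truth, _cfg = small_cohort
        preds = generate_target_predictions(truth, 10 * len(truth.regulatory_edges), seed=5)
        cfg = PipelineConfig(seed=3, n_bootstraps=30)
        bundle = infer_hub_candidates(
            mirna, gene, clinical, truth.subtype_of == "C1", preds, cfg
        )
        c = bundle["rewiring"].cardinalities
        assert c["rule1"] >= c["rule2"] >= c["rule3"] >= c["rule4"]

    def test_missing_required_stratum_rejected(self):
        nets = {"C1:all": _net(set(), "C1:all")}
        with pytest.raises(KeyError):
            rewire_c1(nets, set(), _de_table({}), _de_table({}))


# Seven hub miRNAs with their published signature memberships, plus the
# remaining members of the two candidate signatures.
SEVEN = {
    "miR-193b-5p": "19- and 7-miRNA",
    "miR-31-3p": "19- and 7-miRNA",
    "miR-31-5p": "19- and 7-miRNA",
    "miR-550a-5p": "19- and 7-miRNA",
    "miR-196b-5p": "19-, 14-miRNA and 7-miRNA",
    "miR-584-5p": "19-, 14-miRNA and 7-miRNA",
    "miR-193b-3p": "14- and 7-miRNA",
}
OTHERS = {
    "miR-30d-5p": "19- and 14-miRNA",
    "miR-582-3p": "19- and 14-miRNA",
    "miR-9-5p": "19- and 14-miRNA",
    "miR-138-5p": "19-miRNA",
    "miR-215-5p": "19-miRNA",
    "miR-192-5p": "14-miRNA",
    "miR-210-3p": "14-miRNA",
}


class TestSelectHubs:
    @staticmethod
    def _membership_fixture():
        members = {**SEVEN, **OTHERS}
        sig19 = {m for m, s in members.items() if "19-" in s}
        sig14 = {m for m, s in members.items() if "14-" in s or "14-miRNA" in s}
        return members, sig19, sig14

    def test_published_membership_fixture_selects_exactly_the_seven(self):
        members, sig19, sig14 = self._membership_fixture()
        hub_candidates = {m for m, s in members.items() if "7-miRNA" in s}
        rew = RewiringResult(
            rule1=set(), rule2=set(), rule3=set(),
            rule4={(m, f"g{i}") for m in hub_candidates for i in range(3)},
            hub_candidates=hub_candidates,
        )
        hubs = select_hubs(rew, [sig19, sig14])
        assert hubs.hubs == set(SEVEN)
        for h in hubs.hubs:
            assert len(hubs.neighborhoods[h]) == 3
            assert hubs.provenance[h]  # each hub traces to >= 1 signature

    def test_all_mirnas_as_candidates_returns_hub_candidates(self):
        rew = RewiringResult(set(), set(), set(), set(), {"a", "b"})
        hubs = select_hubs(rew, [{"a", "b", "c", "d"}])
        assert hubs.hubs == {"a", "b"}

    def test_disjoint_signature_yields_empty_with_warning(self):
        rew = RewiringResult(set(), set(), set(), set(), {"a"})
        with pytest.warns(UserWarning):
            hubs = select_hubs(rew, [{"z"}])
        assert hubs.hubs == set()
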