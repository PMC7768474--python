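"""Mutual-information network inference and the C1-specific rewiring cascade.

The inference follows the ARACNe recipe on a bipartite regulon (miRNAs as
regulators, mRNAs as targets): pairwise mutual information, a permutation
null to discard insignificant pairs, Data Processing Inequality pruning of
triangles, and bootstrap consensus over sample resamples.  Two MI estimators
are available:

* ``adaptive_partitioning`` -- recursive partition of the rank-rank plane
  with a chi-square uniformity stop rule (the classic ARACNe estimator);
* ``rank_gaussian`` -- Gaussian-copula MI, ``-0.5 * log(1 - rho^2)`` on
  normal scores, which vectorizes over all pairs and is the practical
  choice for bootstrap consensus at desk scale.

Both are rank-based, so MI is invariant under strictly monotone transforms
of either argument and the permutation null depends only on the sample size
and tie pattern, letting one pooled null serve every pair of a run.

The rewiring cascade then intersects stratified consensus networks to keep
C1-only, stage-I-supported interactions (rule 1), restricts to predicted
miRNA->gene targeting (rule 2), to anti-regulation consistent with the
differential-expression trends (rule 3), and finally extracts hub miRNAs
with at least ``min_degree`` surviving targets (rule 4).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom, norm, rankdata

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

_CHI2_CRIT = 7.814727903251179  # chi-square 0.95 quantile, 3 df
_MIN_CELL = 8  # do not split cells with fewer points


# ---------------------------------------------------------------------------
# mutual information estimators
# ---------------------------------------------------------------------------

def _ordinal_ranks(x: np.ndarray) -> np.ndarray:
    return rankdata(x, method="ordinal").astype(np.intp) - 1


def _adaptive_mi_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    """Adaptive-partitioning MI (nats) on 0..n-1 ranks.

    The y ranks are reflected when the rank correlation is negative: MI is
    invariant under monotone reparameterization, and orienting every pair
    along the main diagonal keeps the dyadic range-midpoint splits aligned
    with the dependence, so increasing and decreasing relationships score
    identically.
    """
    n = rx.size
    if np.corrcoef(rx, ry)[0, 1] < 0:
        ry = (n - 1) - ry
    inv_n = 1.0 / n
    total = 0.0
    # stack of (x1, x2, y1, y2, point index array), rank bounds inclusive
    stack = [(0, n - 1, 0, n - 1, np.arange(n))]
    while stack:
        x1, x2, y1, y2, idx = stack.pop()
        npts = idx.size
        if npts == 0:
            continue
        splittable = npts >= _MIN_CELL and x2 > x1 and y2 > y1
        if splittable:
            xm = (x1 + x2) // 2
            ym = (y1 + y2) // 2
            left = rx[idx] <= xm
            low = ry[idx] <= ym
            q = [idx[left & low], idx[left & ~low], idx[~left & low], idx[~left & ~low]]
            e = npts / 4.0
            chi2 = sum((qi.size - e) ** 2 for qi in q) / e
            if chi2 > _CHI2_CRIT:
                stack.append((x1, xm, y1, ym, q[0]))
                stack.append((x1, xm, ym + 1, y2, q[1]))
                stack.append((xm + 1, x2, y1, ym, q[2]))
                stack.append((xm + 1, x2, ym + 1, y2, q[3]))
                continue
        px = (x2 - x1 + 1) * inv_n
        py = (y2 - y1 + 1) * inv_n
        f = npts * inv_n
        total += f * np.log(f / (px * py))
    return max(total, 0.0)


def _normal_scores(x: np.ndarray) -> np.ndarray:
    r = rankdata(x, method="average")
    z = norm.ppf(r / (x.size + 1.0))
    z = z - z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def _rank_gaussian_mi(x: np.ndarray, y: np.ndarray) -> float:
    zx, zy = _normal_scores(x), _normal_scores(y)
    rho = float(np.clip((zx @ zy) / x.size, -0.999999, 0.999999))
    return -0.5 * np.log1p(-rho * rho)


def _mi_single(x: np.ndarray, y: np.ndarray, estimator: str) -> float:
    if estimator == "adaptive_partitioning":
        return _adaptive_mi_from_ranks(_ordinal_ranks(x), _ordinal_ranks(y))
    if estimator == "rank_gaussian":
        return _rank_gaussian_mi(x, y)
    raise ValueError(f"unknown MI estimator {estimator!r}")


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    estimator: str = "adaptive_partitioning",
    n_null_perm: int = 300,
    seed: int = 0,
) -> tuple[float, float]:
    """MI (nats) between two vectors and its permutation p-value.

    Constant input yields ``(0.0, 1.0)``.  The p-value is
    ``(1 + #{null >= mi}) / (n_null_perm + 1)`` over shuffles of ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 8:
        raise ValueError("vectors must share a 1-D shape with >= 8 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    mi = _mi_single(x, y, estimator)
    rng = np.random.default_rng(seed)
    null = np.empty(n_null_perm)
    for b in range(n_null_perm):
        null[b] = _mi_single(x, rng.permutation(y), estimator)
    p = (1.0 + np.count_nonzero(null >= mi)) / (n_null_perm + 1.0)
    return mi, p


# ---------------------------------------------------------------------------
# single-run ARACNe
# ---------------------------------------------------------------------------

@dataclass
class AracneConfig:
    n_bootstraps: int = 100
    mi_estimator: str = "adaptive_partitioning"
    mi_pvalue_threshold: float = 1e-3
    dpi_tolerance: float = 0.15
    consensus_alpha: float = 0.05
    n_null_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mi_estimator not in ("adaptive_partitioning", "rank_gaussian"):
            raise ValueError(f"unknown MI estimator {self.mi_estimator!r}")
        if not 0 < self.mi_pvalue_threshold <= 1:
            raise ValueError("mi_pvalue_threshold must be in (0, 1]")
        if not 0 <= self.dpi_tolerance <= 1:
            raise ValueError("dpi_tolerance must be in [0, 1]")
        if (self.n_null_perm + 1) * self.mi_pvalue_threshold < 1.0:
            raise ValueError("n_null_perm too small for mi_pvalue_threshold")


@dataclass
class InteractionNetwork:
    """Regulator -> target edges with MI and bootstrap support."""

    edges: pd.DataFrame  # columns: regulator, target, mi, support
    stratum: str = "all"

    def __post_init__(self) -> None:
        if list(self.edges.columns) != ["regulator", "target", "mi", "support"]:
            self.edges = self.edges.reindex(
                columns=["regulator", "target", "mi", "support"]
            )
        if (self.edges["regulator"] == self.edges["target"]).any():
            raise ValueError("self-edges are not allowed")

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator"], self.edges["target"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _all_pair_mi(Z_reg: np.ndarray, Z_tar: np.ndarray) -> np.ndarray:
    """rank_gaussian MI for every regulator x target pair (rows are scores)."""
    n = Z_reg.shape[1]
    rho = np.clip(Z_reg @ Z_tar.T / n, -0.999999, 0.999999)
    return -0.5 * np.log1p(-rho * rho)


def _pooled_null_mi(
    mats: tuple[np.ndarray, np.ndarray],
    estimator: str,
    n_null: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pooled null MI values from sample-shuffled regulator rows."""
    Z_reg, Z_tar = mats
    m_r, n = Z_reg.shape
    m_t = Z_tar.shape[0]
    if estimator == "rank_gaussian":
        n_shuffles = max(1, -(-n_null // (m_r * m_t)))
        vals = []
        for _ in range(n_shuffles):
            perm = rng.permutation(n)
            vals.append(_all_pair_mi(Z_reg[:, perm], Z_tar).ravel())
        return np.concatenate(vals)
    # adaptive partitioning: shuffle per draw over a rotating pair
    vals = np.empty(n_null)
    for b in range(n_null):
        i = b % m_r
        j = (b // m_r) % m_t
        vals[b] = _adaptive_mi_from_ranks(
            Z_reg[i].astype(np.intp), rng.permutation(Z_tar[j]).astype(np.intp)
        )
    return vals


def aracne_single(
    expr_mirna: ExpressionMatrix | pd.DataFrame,
    expr_gene: ExpressionMatrix | pd.DataFrame,
    regulators: list[str],
    config: AracneConfig | None = None,
    rng: np.random.Generator | None = None,
    stratum: str = "all",
) -> InteractionNetwork:
    """One ARACNe pass: MI for every regulator x target pair, permutation
    thresholding, then bipartite DPI.  Edges run regulator -> target only.
    """
    config = config or AracneConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mir = expr_mirna.values if isinstance(expr_mirna, ExpressionMatrix) else expr_mirna
    gen = expr_gene.values if isinstance(expr_gene, ExpressionMatrix) else expr_gene
    if not regulators:
        raise ValueError("empty regulator set")
    missing = [r for r in regulators if r not in mir.index]
    if missing:
        raise KeyError(f"regulators absent from miRNA matrix: {missing}")
    if list(mir.columns) != list(gen.columns):
        raise ValueError("miRNA and gene matrices must share the sample order")

    R = mir.loc[regulators].to_numpy(dtype=float)
    T = gen.to_numpy(dtype=float)
    targets = list(gen.index)
    n = R.shape[1]
    if n < 8:
        raise ValueError("need at least 8 samples for MI estimation")

    const_reg = np.ptp(R, axis=1) == 0
    const_tar = np.ptp(T, axis=1) == 0

    if config.mi_estimator == "rank_gaussian":
        Z_reg = np.vstack([_normal_scores(r) for r in R])
        Z_tar = np.vstack([_normal_scores(t) for t in T])
        mi_mat = _all_pair_mi(Z_reg, Z_tar)
        null = _pooled_null_mi((Z_reg, Z_tar), "rank_gaussian", config.n_null_perm, rng)
    else:
        RK = np.vstack([_ordinal_ranks(r) for r in R])
        TK = np.vstack([_ordinal_ranks(t) for t in T])
        mi_mat = np.empty((len(regulators), len(targets)))
        for i in range(len(regulators)):
            for j in range(len(targets)):
                mi_mat[i, j] = _adaptive_mi_from_ranks(RK[i], TK[j])
        null = _pooled_null_mi((RK, TK), "adaptive_partitioning", config.n_null_perm, rng)

    mi_mat[const_reg, :] = 0.0
    mi_mat[:, const_tar] = 0.0
    null_sorted = np.sort(null)
    # p = (1 + #{null >= mi}) / (N + 1); keep pairs with p <= threshold
    counts_ge = null_sorted.size - np.searchsorted(null_sorted, mi_mat, side="left")
    pvals = (1.0 + counts_ge) / (null_sorted.size + 1.0)
    keep = pvals <= config.mi_pvalue_threshold
    keep[const_reg, :] = False
    keep[:, const_tar] = False

    edges = {
        (regulators[i], targets[j]): float(mi_mat[i, j])
        for i, j in zip(*np.nonzero(keep))
    }

    # regulator-regulator MI on demand for DPI triangles
    if config.mi_estimator == "rank_gaussian":
        reg_mi_all = _all_pair_mi(Z_reg, Z_reg)
        reg_mi = lambda i, j: float(reg_mi_all[i, j])  # noqa: E731
    else:
        _cache: dict[tuple[int, int], float] = {}

        def reg_mi(i: int, j: int) -> float:
            key = (min(i, j), max(i, j))
            if key not in _cache:
                _cache[key] = _adaptive_mi_from_ranks(RK[key[0]], RK[key[1]])
            return _cache[key]

    reg_index = {r: i for i, r in enumerate(regulators)}
    surviving = dpi_prune(edges, lambda a, b: reg_mi(reg_index[a], reg_index[b]), config.dpi_tolerance)

    rows = sorted(surviving.items())
    df = pd.DataFrame(
        [(r, t, m, 1.0) for (r, t), m in rows],
        columns=["regulator", "target", "mi", "support"],
    )
    return InteractionNetwork(edges=df, stratum=stratum)


def dpi_prune(
    edges: dict[tuple[str, str], float],
    reg_reg_mi,
    tolerance: float = 0.15,
) -> dict[tuple[str, str], float]:
    """Data Processing Inequality on regulator-regulator-target triangles.

    For every pair of regulators sharing a target, the triangle's weakest MI
    is presumed indirect; a regulator->target edge is removed when its MI is
    strictly below ``(1 - tolerance) *`` the smaller of the other two MIs.
    Removals are marked first and applied together, so the result does not
    depend on traversal order and the operation is idempotent.
    """
    by_target: dict[str, list[str]] = {}
    for (r, t) in edges:
        by_target.setdefault(t, []).append(r)
    removed: set[tuple[str, str]] = set()
    bound = 1.0 - tolerance
    for t, regs in by_target.items():
        regs = sorted(regs)
        for a in range(len(regs)):
            for b in range(a + 1, len(regs)):
                r1, r2 = regs[a], regs[b]
                m1 = edges[(r1, t)]
                m2 = edges[(r2, t)]
                m3 = reg_reg_mi(r1, r2)
                if m1 < min(m2, m3) * bound:
                    removed.add((r1, t))
                elif m2 < min(m1, m3) * bound:
                    removed.add((r2, t))
    return {e: m for e, m in edges.items() if e not in removed}


# ---------------------------------------------------------------------------
# bootstrap consensus
# ---------------------------------------------------------------------------

def bootstrap_consensus(
    expr_mirna: ExpressionMatrix | pd.DataFrame,
    expr_gene: ExpressionMatrix | pd.DataFrame,
    regulators: list[str],
    config: AracneConfig | None = None,
    stratum: str = "all",
) -> InteractionNetwork:
    """ARACNe over bootstrap resamples; keep edges beyond a binomial null.

    Each resample draws samples with replacement; resamples with fewer than
    8 distinct samples are redrawn (logged).  An edge survives if its
    appearance count is improbable (``consensus_alpha``) under a binomial
    null whose per-edge rate is the mean number of edges per bootstrap over
    the number of scored pairs.  ``support`` is the appearance fraction.
    """
    config = config or AracneConfig()
    if config.n_bootstraps < 2:
        raise ValueError("need at least 2 bootstraps")
    mir = expr_mirna.values if isinstance(expr_mirna, ExpressionMatrix) else expr_mirna
    gen = expr_gene.values if isinstance(expr_gene, ExpressionMatrix) else expr_gene
    n = mir.shape[1]
    rng = np.random.default_rng(config.seed)

    counts: dict[tuple[str, str], int] = {}
    mi_sums: dict[tuple[str, str], float] = {}
    total_edges = 0
    for _b in range(config.n_bootstraps):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            if np.unique(idx).size >= 8:
                break
            logger.info("degenerate bootstrap resample redrawn")
        net = aracne_single(
            mir.iloc[:, idx], gen.iloc[:, idx], regulators, config, rng=rng, stratum=stratum
        )
        total_edges += net.n_edges
        for row in net.edges.itertuples(index=False):
            key = (row.regulator, row.target)
            counts[key] = counts.get(key, 0) + 1
            mi_sums[key] = mi_sums.get(key, 0.0) + row.mi

    n_pairs = len(regulators) * gen.shape[0]
    p0 = min(1.0, (total_edges / config.n_bootstraps) / max(n_pairs, 1))
    # consensus_alpha is familywise: Bonferroni over the scored pairs, as in
    # standard bootstrap-ARACNe edge significance
    alpha_pair = config.consensus_alpha / max(n_pairs, 1)
    rows = []
    for (r, t), k in sorted(counts.items()):
        # P(Bin(B, p0) >= k)
        if binom.sf(k - 1, config.n_bootstraps, p0) <= alpha_pair:
            rows.append((r, t, mi_sums[(r, t)] / k, k / config.n_bootstraps))
    df = pd.DataFrame(rows, columns=["regulator", "target", "mi", "support"])
    logger.info(
        "consensus network (%s): %d edges from %d bootstraps (null rate %.2e)",
        stratum,
        len(df),
        config.n_bootstraps,
        p0,
    )
    return InteractionNetwork(edges=df, stratum=stratum)


# ---------------------------------------------------------------------------
# rewiring cascade and hubs
# ---------------------------------------------------------------------------

@dataclass
class RewiringResult:
    rule1: set[tuple[str, str]]
    rule2: set[tuple[str, str]]
    rule3: set[tuple[str, str]]
    rule4: set[tuple[str, str]]
    hub_candidates: set[str]

    @property
    def cardinalities(self) -> dict[str, int]:
        return {
            "rule1": len(self.rule1),
            "rule2": len(self.rule2),
            "rule3": len(self.rule3),
            "rule4": len(self.rule4),
        }


@dataclass
class HubSet:
    hubs: set[str]
    neighborhoods: dict[str, set[str]]
    provenance: dict[str, list[str]] = field(default_factory=dict)


REQUIRED_STRATA = ("C1:all", "C1:stageI")


def rewire_c1(
    networks: dict[str, InteractionNetwork],
    predictions: set[tuple[str, str]],
    de_mirna: pd.DataFrame,
    de_gene: pd.DataFrame,
    min_degree: int = 3,
    gene_p_threshold: float = 0.05,
) -> RewiringResult:
    """The four-rule cascade extracting C1-specific hub miRNAs.

    1. edges present in both the C1 all-patients and C1 stage-I consensus
       networks and absent from every non-C1 network (C1-only, stage-I
       supported but not exclusive);
    2. edges with predicted miRNA -> gene targeting;
    3. edges whose miRNA and gene fold-change trends oppose, with the gene
       differentially expressed at ``gene_p_threshold`` (unadjusted p);
    4. edges of miRNAs retaining at least ``min_degree`` targets.
    """
    for key in REQUIRED_STRATA:
        if key not in networks:
            raise KeyError(f"missing required stratum network {key!r}")
    non_c1 = [net for name, net in networks.items() if name.startswith("nonC1:")]
    if not non_c1:
        raise KeyError("at least one non-C1 stratum network is required")

    c1_core = networks["C1:all"].edge_set & networks["C1:stageI"].edge_set
    non_c1_union: set[tuple[str, str]] = set()
    for net in non_c1:
        non_c1_union |= net.edge_set
    rule1 = c1_core - non_c1_union

    rule2 = rule1 & set(predictions)

    rule3 = set()
    for (r, t) in rule2:
        if r not in de_mirna.index or t not in de_gene.index:
            continue
        if de_gene.loc[t, "p"] >= gene_p_threshold:
            continue
        if de_mirna.loc[r, "log2_fc"] * de_gene.loc[t, "log2_fc"] < 0:
            rule3.add((r, t))

    degree: dict[str, int] = {}
    for (r, _t) in rule3:
        degree[r] = degree.get(r, 0) + 1
    hub_candidates = {r for r, d in degree.items() if d >= min_degree}
    rule4 = {(r, t) for (r, t) in rule3 if r in hub_candidates}

    result = RewiringResult(rule1, rule2, rule3, rule4, hub_candidates)
    logger.info("rewiring cascade cardinalities: %s", result.cardinalities)
    return result


def select_hubs(
    rewiring: RewiringResult, candidate_signatures: list[set[str]]
) -> HubSet:
    """Hubs = cascade candidates that appear in any candidate signature."""
    if not candidate_signatures:
        raise ValueError("at least one candidate signature required")
    union: set[str] = set()
    for sig in candidate_signatures:
        union |= set(sig)
    hubs = rewiring.hub_candidates & union
    if not hubs:
        warnings.warn("no hub candidate belongs to any candidate signature", stacklevel=2)
    neighborhoods = {
        h: {t for (r, t) in rewiring.rule4 if r == h} for h in hubs
    }
    provenance = {
        h: [f"signature_{i + 1}" for i, sig in enumerate(candidate_signatures) if h in sig]
        for h in hubs
    }
    return HubSet(hubs=hubs, neighborhoods=neighborhoods, provenance=provenance)
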