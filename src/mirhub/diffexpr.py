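"""Differential expression between C1 and non-C1 samples.

Two engines are provided:

* :func:`nb_wald_test` -- a negative-binomial log-linear Wald test in the
  DESeq2 mold: median-of-ratios size factors enter as offsets, a per-gene
  dispersion is estimated by gene-wise maximum likelihood (moment start, no
  empirical-Bayes shrinkage), and significance comes from the Wald statistic
  of the group coefficient with Benjamini-Hochberg adjustment.
* :func:`multivariate_permutation_ttest` -- two-sample t statistics under a
  multivariate permutation procedure (Korn-style step-down) that selects the
  largest feature set whose false-positive proportion is bounded by
  ``max_fp_proportion`` with the stated confidence.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

_LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors(expr: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors, renormalized to geometric mean 1.

    Each sample's factor is the median, over features expressed in every
    sample, of the ratio of its count to the feature's geometric mean.  If
    no feature is expressed everywhere the fallback uses geometric means of
    positive counts only, with a warning.
    """
    counts = expr.values.to_numpy(dtype=float)
    everywhere = (counts > 0).all(axis=1)
    if everywhere.any():
        sub = counts[everywhere]
        log_geo = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_geo[:, None]
        log_sf = np.median(ratios, axis=0)
    else:
        warnings.warn(
            "no feature expressed in all samples; falling back to positive-count "
            "geometric means",
            stacklevel=2,
        )
        with np.errstate(divide="ignore"):
            logs = np.where(counts > 0, np.log(np.maximum(counts, 1e-300)), np.nan)
        log_geo = np.nanmean(logs, axis=1)
        ratios = logs - log_geo[:, None]
        log_sf = np.nanmedian(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=expr.sample_ids, name="size_factor")


# ---------------------------------------------------------------------------
# negative-binomial Wald test
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; ``alpha`` broadcast per gene."""
    inv = 1.0 / alpha
    mu = np.maximum(mu, 1e-300)
    ll = (
        gammaln(y + inv)
        - gammaln(inv)
        - gammaln(y + 1.0)
        + y * np.log(alpha * mu / (1.0 + alpha * mu))
        - inv * np.log1p(alpha * mu)
    )
    return ll.sum(axis=-1)


def _newton_beta(
    y: np.ndarray, g: np.ndarray, log_sf: np.ndarray, alpha: np.ndarray, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Newton-Raphson for (intercept, group) per gene.

    Returns updated beta (G x 2) and the Fisher information entries needed
    for the Wald SE of the group coefficient.
    """
    a = alpha[:, None]
    info = None
    for _ in range(50):
        eta = log_sf[None, :] + beta[:, [0]] + beta[:, [1]] * g[None, :]
        mu = np.exp(np.clip(eta, -40, 40))
        w = mu / (1.0 + a * mu)
        r = (y - mu) / (1.0 + a * mu)
        s0 = r.sum(axis=1)
        s1 = (r * g).sum(axis=1)
        i00 = w.sum(axis=1)
        i01 = (w * g).sum(axis=1)
        det = np.maximum(i01 * (i00 - i01), 1e-12)
        # closed-form 2x2 solve; I = [[i00, i01], [i01, i01]] since g is binary
        db0 = i01 * (s0 - s1) / det
        db1 = (i00 * s1 - i01 * s0) / det
        step = np.stack([db0, db1], axis=1)
        step = np.clip(step, -3.0, 3.0)
        beta = np.clip(beta + step, -30.0, 30.0)
        info = (i00, i01, det)
        if np.abs(step).max() < 1e-10:
            break
    return beta, info


def _ml_dispersion(
    y: np.ndarray, g: np.ndarray, log_sf: np.ndarray, beta: np.ndarray, lo: float = 1e-8, hi: float = 50.0
) -> np.ndarray:
    """Per-gene ML dispersion given the current mean fit (vectorized ternary search)."""
    eta = log_sf[None, :] + beta[:, [0]] + beta[:, [1]] * g[None, :]
    mu = np.exp(np.clip(eta, -40, 40))
    # bracket on log-alpha by coarse grid, then ternary refinement
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), 25))
    lls = np.stack([_nb_loglik(y, mu, np.asarray(a_val)) for a_val in grid])
    best = lls.argmax(axis=0)
    lo_i = np.maximum(best - 1, 0)
    hi_i = np.minimum(best + 1, len(grid) - 1)
    la, lb = np.log(grid[lo_i]), np.log(grid[hi_i])
    for _ in range(30):
        m1 = la + (lb - la) / 3.0
        m2 = lb - (lb - la) / 3.0
        l1 = _nb_loglik(y, mu, np.exp(m1)[:, None])
        l2 = _nb_loglik(y, mu, np.exp(m2)[:, None])
        take = l1 < l2
        la = np.where(take, m1, la)
        lb = np.where(take, lb, m2)
    return np.exp((la + lb) / 2.0)


def nb_wald_test(
    expr: ExpressionMatrix,
    is_c1: pd.Series,
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature NB Wald test of C1 vs non-C1.

    Returns a table with ``log2_fc`` (C1 relative to non-C1), ``p``, BH ``q``
    and ``trend`` (up/down in C1).  All-zero features are flagged with
    ``p = 1`` and zero fold change.
    """
    if expr.scale != "raw":
        raise ValueError("NB Wald test operates on raw counts")
    is_c1 = is_c1.reindex(expr.sample_ids)
    if is_c1.isna().any():
        raise ValueError("labels do not cover all samples")
    g = is_c1.to_numpy(dtype=float)
    if is_c1.sum() < 2 or (~is_c1).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    if sf is None:
        sf = size_factors(expr)
    log_sf = np.log(sf.reindex(expr.sample_ids).to_numpy(dtype=float))

    y = expr.values.to_numpy(dtype=float)
    nonzero = y.sum(axis=1) > 0
    G = y.shape[0]

    norm_counts = y / np.exp(log_sf)[None, :]
    mean_c1 = norm_counts[:, g == 1].mean(axis=1)
    mean_non = norm_counts[:, g == 0].mean(axis=1)

    beta = np.zeros((G, 2))
    beta[:, 0] = np.log(np.maximum(mean_non, 1e-8))
    beta[:, 1] = np.log(np.maximum(mean_c1, 1e-8)) - beta[:, 0]

    # moment start for the dispersion, pooled within groups
    var_pool = 0.5 * (
        norm_counts[:, g == 1].var(axis=1, ddof=1) + norm_counts[:, g == 0].var(axis=1, ddof=1)
    )
    mean_pool = 0.5 * (mean_c1 + mean_non)
    alpha = np.clip(
        (var_pool - mean_pool) / np.maximum(mean_pool**2, 1e-12), 1e-8, 50.0
    )

    info = None
    for _ in range(3):
        beta, info = _newton_beta(y, g, log_sf, alpha, beta)
        alpha = _ml_dispersion(y, g, log_sf, beta)
    beta, info = _newton_beta(y, g, log_sf, alpha, beta)

    i00, _i01, det = info
    var_b1 = i00 / det
    se = np.sqrt(np.maximum(var_b1, 1e-300))
    z = beta[:, 1] / se
    p = 2.0 * norm.sf(np.abs(z))
    log2_fc = beta[:, 1] / _LN2

    p = np.clip(np.where(nonzero, p, 1.0), np.finfo(float).tiny, 1.0)
    log2_fc = np.where(nonzero, log2_fc, 0.0)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p": p,
            "q": q,
            "trend": np.where(log2_fc > 0, "up", "down"),
            "dispersion": alpha,
            "all_zero": ~nonzero,
        },
        index=pd.Index(expr.feature_ids, name="feature_id"),
    )
    return table


# ---------------------------------------------------------------------------
# multivariate permutation t-test (BRB style)
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestConfig:
    n_perm: int = 1000
    confidence: float = 0.80
    max_fp_proportion: float = 0.05
    seed: int = 0
    t_variant: str = "welch"  # or "pooled"

    def __post_init__(self) -> None:
        if not 0 < self.confidence < 1 or not 0 <= self.max_fp_proportion < 1:
            raise ValueError("confidence in (0,1), max_fp_proportion in [0,1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


def _t_pvalues(X: np.ndarray, mask1: np.ndarray, variant: str) -> np.ndarray:
    """Two-sided two-sample t p-values per row of ``X`` for the split ``mask1``."""
    a, b = X[:, mask1], X[:, ~mask1]
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if variant == "welch":
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / np.maximum(
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1), 1e-300
        )
    elif variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full(X.shape[0], n1 + n2 - 2.0)
    else:
        raise ValueError(f"unknown t variant {variant!r}")
    tstat = (m1 - m2) / np.sqrt(np.maximum(se2, 1e-300))
    return 2.0 * t_dist.sf(np.abs(tstat), df)


def _label_permutations(n: int, n1: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean masks of group-1 membership: full enumeration when feasible."""
    if math.comb(n, n1) <= n_perm:
        masks = np.zeros((math.comb(n, n1), n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n1)):
            masks[i, list(idx)] = True
        return masks
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=n1, replace=False)] = True
    return masks


def multivariate_permutation_ttest(
    log_expr: ExpressionMatrix | pd.DataFrame,
    is_c1: pd.Series,
    config: PermutationTestConfig | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Step-down permutation selection bounding the false-positive proportion.

    Orders features by their two-sample t p-value and extends the selected
    prefix while each ordered p-value stays below the permutation critical
    value for its allowed number of false positives
    (``floor(max_fp_proportion * i)``), taken at the ``1 - confidence``
    quantile of the permutation distribution of the corresponding p-value
    order statistic.  Returns the selected ids (p-ordered) and the
    per-feature table.
    """
    config = config or PermutationTestConfig()
    values = log_expr.values if isinstance(log_expr, ExpressionMatrix) else log_expr
    is_c1 = is_c1.reindex(values.columns)
    if is_c1.isna().any():
        raise ValueError("labels do not cover all samples")
    alpha = 1.0 - config.confidence
    if (config.n_perm + 1) * alpha < 1.0:
        raise ValueError("n_perm too small for the requested confidence resolution")
    mask_obs = is_c1.to_numpy(dtype=bool)
    if mask_obs.sum() < 2 or (~mask_obs).sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    X = values.to_numpy(dtype=float)
    m, n = X.shape
    p_obs = _t_pvalues(X, mask_obs, config.t_variant)
    order = np.argsort(p_obs, kind="stable")

    rng = np.random.default_rng(config.seed)
    masks = _label_permutations(n, int(mask_obs.sum()), config.n_perm, rng)
    perm_sorted = np.empty((masks.shape[0], m))
    for b in range(masks.shape[0]):
        perm_sorted[b] = np.sort(_t_pvalues(X, masks[b], config.t_variant))

    selected_idx: list[int] = []
    for rank, feat in enumerate(order, start=1):
        u = int(math.floor(config.max_fp_proportion * rank))
        if u >= rank:
            selected_idx.append(feat)
            continue
        crit = np.quantile(perm_sorted[:, u], alpha, method="lower")
        if p_obs[feat] <= crit:
            selected_idx.append(feat)
        else:
            break

    ids = list(values.index)
    selected = [ids[i] for i in selected_idx]
    table = pd.DataFrame(
        {"p": p_obs, "selected": [i in set(selected_idx) for i in range(m)]},
        index=pd.Index(ids, name="feature_id"),
    )
    logger.info(
        "multivariate permutation test selected %d/%d features", len(selected), m
    )
    return selected, table


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_overlap(set_a, set_b) -> tuple[set, set, set]:
    """(intersection, A-only, B-only) of two feature-id sets."""
    a, b = set(set_a), set(set_b)
    return a & b, a - b, b - a
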