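"""Penalized logistic signature selection and its evaluation.

The signature is an L1-penalized (lasso) logistic regression of the C1
indicator on log2 expression.  The penalty is tuned by repeated 10-fold
cross-validation: each repeat re-splits the folds, the held-out
log-likelihood is averaged over folds and repeats, and the strongest
penalty among ties wins.  Predictors are standardized internally;
coefficients are reported on the original scale and features with zero
coefficient are dropped from the signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu, rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class CvConfig:
    n_folds: int = 10
    n_repeats: int = 50
    lambda_grid: np.ndarray | None = None
    n_lambda: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.lambda_grid is not None and len(self.lambda_grid) == 0:
            raise ValueError("lambda_grid must be nonempty")


@dataclass
class LogisticSignature:
    feature_ids: list[str]
    coefficients: list[float]
    intercept: float
    lambda_: float
    cv_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.coefficients):
            raise ValueError("coefficients must align 1:1 with feature ids")

    @property
    def selected_features(self) -> list[str]:
        return [f for f, c in zip(self.feature_ids, self.coefficients) if c != 0.0]


def _default_lambda_grid(Xs: np.ndarray, y: np.ndarray, n_lambda: int) -> np.ndarray:
    """Log-spaced grid from the all-zero penalty down four decades."""
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(Xs.T @ resid).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * 1e-4, n_lambda)


def _refit_intercept(Xs: np.ndarray, y: np.ndarray, coef: np.ndarray, b0: float) -> float:
    """Unpenalized 1-D Newton refit of the intercept at fixed coefficients.

    liblinear places the intercept under the L1 penalty; refitting it given
    the coefficients removes that shrinkage (and makes the all-zero model's
    intercept the exact prevalence log-odds).
    """
    eta0 = Xs @ coef
    for _ in range(50):
        p = 1.0 / (1.0 + np.exp(-np.clip(eta0 + b0, -35, 35)))
        g = np.sum(y - p)
        h = np.sum(p * (1 - p))
        if h <= 0:
            break
        step = g / h
        b0 += np.clip(step, -5.0, 5.0)
        if abs(step) < 1e-12:
            break
    return float(b0)


def _fit_at_lambda(Xs: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # liblinear minimizes C * sum(loss) + (|w|_1 + |b|); lambda = 1 / (n C)
    C = 1.0 / (len(y) * lam)
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", tol=1e-7, max_iter=1000, random_state=0
    )
    clf.fit(Xs, y)
    clf.intercept_[0] = _refit_intercept(Xs, y, clf.coef_[0], float(clf.intercept_[0]))
    return clf


def _heldout_loglik(clf: LogisticRegression, Xs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(clf.predict_proba(Xs)[:, 1], 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lasso_logistic_cv(
    X: pd.DataFrame,
    y: pd.Series,
    cv: CvConfig | None = None,
) -> LogisticSignature:
    """Lasso logistic fit with repeat-averaged held-out log-likelihood tuning.

    ``X`` is samples x features (log2 expression); ``y`` the binary C1
    indicator.  The chosen penalty maximizes the mean held-out
    log-likelihood over ``n_repeats`` random ``n_folds`` splits (ties go to
    the largest penalty); the final model refits all data at that penalty.
    """
    cv = cv or CvConfig()
    yv = pd.Series(y).reindex(X.index).to_numpy(dtype=float)
    if np.isnan(yv).any() or X.isna().any().any():
        raise ValueError("missing values in X or y")
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present")

    mu = X.mean(axis=0).to_numpy()
    sd = X.std(axis=0, ddof=0).to_numpy()
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X.to_numpy(dtype=float) - mu) / sd

    grid = (
        np.sort(np.asarray(cv.lambda_grid, dtype=float))[::-1]
        if cv.lambda_grid is not None
        else _default_lambda_grid(Xs, yv, cv.n_lambda)
    )

    scores = np.zeros(len(grid))
    n_splits_total = 0
    for rep in range(cv.n_repeats):
        folds = StratifiedKFold(
            n_splits=cv.n_folds, shuffle=True, random_state=cv.seed + rep
        )
        for train, test in folds.split(Xs, yv):
            n_splits_total += 1
            for gi, lam in enumerate(grid):
                clf = _fit_at_lambda(Xs[train], yv[train], lam)
                scores[gi] += _heldout_loglik(clf, Xs[test], yv[test])
    scores /= n_splits_total
    best = int(np.argmax(scores))  # grid descends, so first max = largest lambda
    lam = float(grid[best])

    clf = _fit_at_lambda(Xs, yv, lam)
    coef_std = clf.coef_[0]
    coef = coef_std / sd
    intercept = float(clf.intercept_[0] - np.sum(coef_std * mu / sd))
    sig = LogisticSignature(
        feature_ids=list(X.columns),
        coefficients=coef.tolist(),
        intercept=intercept,
        lambda_=lam,
        cv_metadata={
            "n_folds": cv.n_folds,
            "n_repeats": cv.n_repeats,
            "seed": cv.seed,
            "mean_heldout_loglik": float(scores[best]),
        },
    )
    logger.info(
        "lasso CV chose lambda=%.3g with %d nonzero features",
        lam,
        len(sig.selected_features),
    )
    return sig


def predict_c1_probability(model: LogisticSignature, X: pd.DataFrame) -> pd.Series:
    """Logistic-link C1 probabilities for samples in ``X`` (samples x features)."""
    missing = [f for f in model.feature_ids if f not in X.columns]
    if missing:
        raise KeyError(f"model features absent from matrix: {missing}")
    eta = model.intercept + X[model.feature_ids].to_numpy() @ np.asarray(model.coefficients)
    eta = np.clip(eta, -700.0, 700.0)
    return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=X.index, name="p_c1")


def auc(scores, labels) -> float:
    """Area under the ROC curve = Mann-Whitney U / (n1 * n0), ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required for AUC")
    r = rankdata(s)
    u = r[y == 1].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def cross_validated_auc(
    X: pd.DataFrame,
    y: pd.Series,
    model_factory=None,
    cv: CvConfig | None = None,
) -> float:
    """AUC of pooled out-of-fold C1 probabilities, averaged over repeats.

    ``model_factory`` returns a fresh sklearn-style classifier per fold;
    the default is an unpenalized logistic regression (the evaluation model
    for a fixed signature).  Folds are stratified so both classes appear in
    every split.
    """
    cv = cv or CvConfig(n_repeats=10)
    if model_factory is None:
        model_factory = lambda: LogisticRegression(C=np.inf, max_iter=5000)  # noqa: E731
    yv = pd.Series(y).reindex(X.index).to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    aucs = []
    for rep in range(cv.n_repeats):
        folds = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed + rep)
        oof = np.empty(len(yv))
        for train, test in folds.split(Xv, yv):
            clf = model_factory()
            clf.fit(Xv[train], yv[train])
            oof[test] = clf.predict_proba(Xv[test])[:, 1]
        aucs.append(auc(oof, yv))
    return float(np.mean(aucs))


def wilcoxon_mann_whitney(values_a, values_b) -> float:
    """Two-sided rank-sum p; exact for small tie-free samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    return float(mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)


def overrepresentation_test(
    query: set[str],
    collection: dict[str, set[str]],
    universe: int | set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Returns one row per set with the overlap ``k``, set size ``K``, the
    ``k/K`` ratio, the upper-tail hypergeometric p (survival at ``k - 1``)
    and BH ``q`` across the collection, sorted by (q, p).  Sets are clipped
    to the universe with a warning when they extend beyond it.
    """
    import warnings

    query = set(query)
    if not query:
        raise ValueError("query gene set is empty")
    if isinstance(universe, set):
        uni_set, M = universe, len(universe)
        if not query <= uni_set:
            warnings.warn("query clipped to universe", stacklevel=2)
            query = query & uni_set
    else:
        uni_set, M = None, int(universe)
    rows = []
    for name, members in collection.items():
        members = set(members)
        if uni_set is not None and not members <= uni_set:
            warnings.warn(f"gene set {name!r} clipped to universe", stacklevel=2)
            members = members & uni_set
        K = len(members)
        if K > M:
            raise ValueError(f"set {name!r} larger than the universe")
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, M, K, len(query)))
        rows.append((name, k, K, k / K if K else 0.0, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["set", "k", "K", "k_over_K", "p"]).set_index("set")
    table["q"] = bh_adjust(table["p"])
    return table.sort_values(["q", "p"])
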