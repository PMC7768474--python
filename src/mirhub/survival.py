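"""Censored survival analysis: truncation, Kaplan-Meier, log-rank, Cox PH.

Follow-up is truncated at a horizon (3 years by default) before modeling, to
limit contamination of overall mortality by late non-disease deaths.  Cox
models use the Efron partial likelihood by default (lifelines); a Breslow
variant (scikit-survival) is available and coincides with Efron when event
times are distinct.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time

#: reference level used when expanding each categorical covariate
CATEGORICAL_REFERENCE = {"sex": "M", "smoking": "current/former", "stage": "I"}


def truncate_followup(data: pd.DataFrame, horizon: float = 3.0) -> pd.DataFrame:
    """Administratively censor everyone still at risk beyond ``horizon`` years."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    out = data.copy()
    late = out["time"] > horizon
    out.loc[late, "time"] = horizon
    out.loc[late, "event"] = 0
    return out


def kaplan_meier(data: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate; columns ``time`` and ``survival``."""
    if len(data) == 0:
        raise ValueError("empty survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(data["time"], data["event"])
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def survival_at(data: pd.DataFrame, t: float) -> float:
    """Kaplan-Meier survival probability at time ``t``."""
    kmf = KaplanMeierFitter()
    kmf.fit(data["time"], data["event"])
    return float(kmf.predict(t))


def restricted_mean(data: pd.DataFrame, horizon: float) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(data["time"], data["event"])
    return float(restricted_mean_survival_time(kmf, t=horizon))


def log_rank_test(data: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Log-rank chi-square and p over the pooled event times (k-1 df)."""
    groups = groups.loc[data.index]
    sizes = groups.value_counts()
    if (sizes == 0).any() or sizes.size < 2:
        raise ValueError("log-rank requires >= 2 non-empty groups")
    if sizes.size == 2:
        ids = sizes.index
        a, b = data[groups == ids[0]], data[groups == ids[1]]
        res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    else:
        res = multivariate_logrank_test(data["time"], groups, data["event"])
    return float(res.test_statistic), float(res.p_value)


def expand_covariates(data: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Design columns for Cox: numeric kept, categoricals dummy-coded.

    Each categorical drops its documented reference level
    (:data:`CATEGORICAL_REFERENCE`; first sorted level otherwise); explicit
    "missing" categories are kept as their own indicator.
    """
    cols = []
    for cov in covariates:
        s = data[cov]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.astype(float))
        else:
            levels = sorted(s.astype(str).unique())
            ref = CATEGORICAL_REFERENCE.get(cov, levels[0])
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((s.astype(str) == lev).astype(float).rename(f"{cov}[{lev}]"))
    return pd.concat(cols, axis=1)


def cox_ph(
    data: pd.DataFrame,
    covariates: list[str],
    ties: str = "efron",
) -> pd.DataFrame:
    """Cox proportional-hazards fit; one row per design column.

    Returns columns ``hr``, ``ci_low``, ``ci_high``, ``p``, ``n``,
    ``n_events``.  ``ties="efron"`` fits via the Efron partial likelihood
    (lifelines); ``ties="breslow"`` via scikit-survival's Breslow handling.
    """
    if data["event"].sum() < 1:
        raise ValueError("Cox model requires at least one event")
    X = expand_covariates(data, covariates)
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("non-finite covariate values")
    n, n_events = len(data), int(data["event"].sum())

    if ties == "efron":
        df = pd.concat([X, data[["time", "event"]]], axis=1)
        cph = CoxPHFitter()
        cph.fit(
            df,
            duration_col="time",
            event_col="event",
            fit_options={"precision": 1e-10},
        )
        summ = cph.summary
        out = pd.DataFrame(
            {
                "hr": np.exp(summ["coef"]),
                "ci_low": np.exp(summ["coef lower 95%"]),
                "ci_high": np.exp(summ["coef upper 95%"]),
                "p": summ["p"],
            },
            index=summ.index,
        )
    elif ties == "breslow":
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        y = np.array(
            list(zip(data["event"].astype(bool), data["time"].astype(float))),
            dtype=[("event", bool), ("time", float)],
        )
        est = CoxPHSurvivalAnalysis(alpha=1e-9)
        est.fit(X.to_numpy(), y)
        coef = est.coef_
        # Wald covariance from the observed information at the estimate
        se = _breslow_se(X.to_numpy(), data["time"].to_numpy(), data["event"].to_numpy(), coef)
        from scipy.stats import norm

        z = coef / se
        out = pd.DataFrame(
            {
                "hr": np.exp(coef),
                "ci_low": np.exp(coef - 1.959963984540054 * se),
                "ci_high": np.exp(coef + 1.959963984540054 * se),
                "p": 2 * norm.sf(np.abs(z)),
            },
            index=X.columns,
        )
    else:
        raise ValueError(f"unknown tie handling {ties!r}")

    out["n"] = n
    out["n_events"] = n_events
    return out


def _breslow_se(X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Standard errors from the Breslow partial-likelihood information."""
    order = np.argsort(-time, kind="stable")
    X, time, event = X[order], time[order], event[order]
    eta = X @ beta
    w = np.exp(eta)
    n, p = X.shape
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            s0 += w[j]
            s1 += w[j] * X[j]
            s2 += w[j] * np.outer(X[j], X[j])
            j += 1
        for k in range(i, j):
            if event[k]:
                xbar = s1 / s0
                info += s2 / s0 - np.outer(xbar, xbar)
        i = j
    cov = np.linalg.inv(info)
    return np.sqrt(np.diag(cov))
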