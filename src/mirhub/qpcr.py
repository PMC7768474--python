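"""qPCR (CT value) validation arm.

CT values are amplification cycle thresholds: one cycle fewer means roughly
twice the transcript.  Normalization subtracts a per-sample scaling factor
``SF_j = CT_ref,j - constant`` (the reference miRNA's deviation from a fixed
constant, 21.87 cycles by default), so the reference maps to the constant in
every sample and within-sample CT differences are preserved exactly.  The
risk arm rescales each feature by its interquartile range (q1-q3
normalization), forms a weighted risk score and calls C1 for scores strictly
above the cohort's 66th percentile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)


@dataclass
class CtMatrix:
    """Feature x sample CT cycles; undetermined wells are missing (NaN)."""

    values: pd.DataFrame
    normalized: bool = False

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class RiskModel:
    """Weighted gene risk score with a percentile classification cut."""

    gene_ids: list[str]
    weights: list[float]
    threshold_percentile: float = 66.0
    scaling: str = "q1q3"

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.weights):
            raise ValueError("weights must align 1:1 with gene ids")


def impute_undetermined(ct: CtMatrix, ceiling: float = 40.0) -> CtMatrix:
    """Replace undetermined (missing) CTs with a detection-ceiling cycle."""
    n_missing = int(ct.values.isna().sum().sum())
    if n_missing:
        logger.info("imputing %d undetermined CT wells at ceiling %.1f", n_missing, ceiling)
    return CtMatrix(ct.values.fillna(ceiling), normalized=ct.normalized)


def normalize_ct(ct: CtMatrix, reference_id: str, constant: float = 21.87) -> CtMatrix:
    """Subtract the per-sample scaling factor SF_j = CT_ref,j - constant.

    After normalization the reference feature equals ``constant`` in every
    sample; renormalizing is a no-op.
    """
    if reference_id not in ct.values.index:
        raise KeyError(f"reference feature {reference_id!r} absent from CT matrix")
    ref = ct.values.loc[reference_id]
    missing = ref.index[ref.isna()].tolist()
    if missing:
        raise ValueError(f"reference CT missing in samples: {missing}")
    sf = ref - constant
    return CtMatrix(ct.values.sub(sf, axis=1), normalized=True)


def q1q3_rescale(values: pd.DataFrame) -> pd.DataFrame:
    """Per-feature interquartile rescaling: x' = (x - Q1) / (Q3 - Q1).

    Quartiles use linear interpolation between order statistics, computed
    per feature across samples.
    """
    if values.shape[1] < 4:
        raise ValueError("q1-q3 rescaling needs at least 4 samples")
    q1 = values.quantile(0.25, axis=1, interpolation="linear")
    q3 = values.quantile(0.75, axis=1, interpolation="linear")
    iqr = q3 - q1
    degenerate = iqr.index[iqr <= 0].tolist()
    if degenerate:
        raise ValueError(f"zero interquartile range for features: {degenerate}")
    return values.sub(q1, axis=0).div(iqr, axis=0)


def risk_classify(
    rescaled: pd.DataFrame,
    model: RiskModel,
    threshold: float | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Weighted risk scores and the strict-percentile C1 call.

    ``threshold`` overrides the cohort-recomputed percentile cut (use it to
    carry a cut from a training cohort); by default the cut is the linear-
    interpolation percentile of this cohort's scores, and C1 requires
    ``score > cut`` (strict).
    """
    missing = [g for g in model.gene_ids if g not in rescaled.index]
    if missing:
        raise KeyError(f"risk model genes absent from matrix: {missing}")
    w = pd.Series(model.weights, index=model.gene_ids, dtype=float)
    scores = rescaled.loc[model.gene_ids].mul(w, axis=0).sum(axis=0)
    cut = (
        float(np.percentile(scores, model.threshold_percentile, method="linear"))
        if threshold is None
        else threshold
    )
    return scores, scores > cut


def refit_hub_model(
    ct_norm: CtMatrix,
    hub_ids: list[str],
    is_c1: pd.Series,
    stage: pd.Series | None = None,
):
    """Unpenalized logistic refit of the C1 call on normalized hub CTs.

    Lower CT means more transcript, so coefficient signs are on the CT scale.
    Hubs missing from the card are reported and the fit proceeds on those
    detected.  Returns ``(signature, auc_all, auc_stage1)``; the stage-I AUC
    is ``None`` when no stage column is given or one class is absent there.
    """
    from .signature import LogisticSignature, auc

    detected = [h for h in hub_ids if h in ct_norm.values.index]
    absent = sorted(set(hub_ids) - set(detected))
    if absent:
        warnings.warn(f"hub miRNAs not detected on the CT card: {absent}", stacklevel=2)
    if not detected:
        raise ValueError("no hub miRNAs detected in CT matrix")

    X = ct_norm.values.loc[detected].T  # samples x hubs
    if X.isna().any().any():
        raise ValueError("CT matrix contains undetermined values; impute first")
    y = is_c1.loc[X.index].astype(int)
    if y.nunique() < 2:
        raise ValueError("both C1 and non-C1 samples required for the refit")

    clf = LogisticRegression(C=np.inf, max_iter=5000)
    clf.fit(X.to_numpy(), y.to_numpy())
    model = LogisticSignature(
        feature_ids=list(detected),
        coefficients=clf.coef_[0].tolist(),
        intercept=float(clf.intercept_[0]),
        lambda_=0.0,
    )
    probs = pd.Series(clf.predict_proba(X.to_numpy())[:, 1], index=X.index)
    auc_all = auc(probs, y)

    auc_stage1 = None
    if stage is not None:
        mask = stage.loc[X.index] == "I"
        if mask.any() and y[mask].nunique() == 2:
            auc_stage1 = auc(probs[mask], y[mask])
        else:
            warnings.warn("stage-I subset lacks both classes; stage-I AUC omitted", stacklevel=2)
    return model, auc_all, auc_stage1
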