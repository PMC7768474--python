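"""Shared in-memory containers for expression, clinical and labeling data.

Expression data travel as a thin wrapper around a feature x sample pandas
DataFrame together with the scale they are on (``raw`` integer counts or
``log2`` of counts + 1).  Clinical tables are plain DataFrames indexed by
sample id with the columns ``age``, ``sex``, ``smoking``, ``stage``,
``time`` (years) and ``event`` (0/1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLINICAL_COLUMNS = ("age", "sex", "smoking", "stage", "time", "event")
SEX_LEVELS = ("M", "F")
SMOKING_LEVELS = ("current/former", "never", "missing")
STAGE_LEVELS = ("I", "II", "III", "IV", "missing")


@dataclass
class ExpressionMatrix:
    """Feature x sample expression values on a declared scale.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features, columns are samples.
    scale : {"raw", "log2"}
        ``raw`` requires non-negative integral counts.
    """

    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.scale == "raw":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise ValueError("raw counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("raw counts must be integral")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def log2(self) -> "ExpressionMatrix":
        """Return log2(count + 1) view of a raw matrix (identity on log2)."""
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.values.astype(float) + 1.0), scale="log2")

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)], scale=self.scale)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], scale=self.scale)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.scale == other.scale and self.values.equals(other.values)


@dataclass
class SubtypeLabeling:
    """Cluster assignment plus the survival-guided C1 / non-C1 call."""

    cluster_of: pd.Series  # sample -> cluster id (int)
    c1_cluster_id: int
    pooling_pvalues: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def is_c1(self) -> pd.Series:
        return self.cluster_of == self.c1_cluster_id

    @property
    def c1_samples(self) -> list[str]:
        return list(self.cluster_of.index[self.is_c1])

    @property
    def non_c1_samples(self) -> list[str]:
        return list(self.cluster_of.index[~self.is_c1])


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table: closed categories, time >= 0, event in {0,1}."""
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if (clinical["time"] < 0).any():
        raise ValueError("follow-up time must be >= 0")
    if not clinical["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    for col, levels in (("sex", SEX_LEVELS), ("smoking", SMOKING_LEVELS), ("stage", STAGE_LEVELS)):
        bad = set(clinical[col].unique()) - set(levels)
        if bad:
            raise ValueError(f"unknown {col} levels: {sorted(bad)}")
    return clinical
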