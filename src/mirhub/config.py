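"""Structured pipeline configuration with desk/paper fidelity presets.

A single top-level seed fans out deterministically to per-stage seeds.  The
``paper`` preset restores the full-fidelity sampling effort (1000 network
bootstraps, 1000 label permutations, 50 cross-validation repeats); the
``desk`` preset scales those down (100 / 500 / 5) for interactive runs.
Only those documented parameters differ between presets.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .syndata import CohortConfig

FIDELITY_PRESETS = {
    "desk": {"n_bootstraps": 100, "n_perm": 500, "n_repeats": 5},
    "paper": {"n_bootstraps": 1000, "n_perm": 1000, "n_repeats": 50},
}


@dataclass
class PipelineConfig:
    seed: int = 0
    fidelity: str = "desk"

    # input paths; any left None is synthesized from ``cohort``
    mirna_counts_path: str | None = None
    gene_counts_path: str | None = None
    clinical_path: str | None = None
    predictions_path: str | None = None
    panel_path: str | None = None
    gmt_path: str | None = None
    risk_weights_path: str | None = None

    cohort: CohortConfig = field(default_factory=CohortConfig)
    prediction_decoy_factor: int = 10  # decoys per true edge when simulating

    # preprocessing
    min_detection_fraction: float = 0.5
    variance_quantile: float = 0.75
    k_clusters: int = 4
    clustering_center: str | None = "median"
    horizon_years: float = 3.0
    pool_alpha: float = 0.05

    # differential expression
    mirna_de_scale: str = "q"  # select miRNAs on adjusted (q) or raw (p) values
    mirna_de_threshold: float = 0.05
    gene_p_threshold: float = 0.05
    n_perm: int = 500
    perm_confidence: float = 0.80
    perm_max_fp_proportion: float = 0.05

    # network inference
    n_bootstraps: int = 100
    mi_estimator: str = "rank_gaussian"
    mi_pvalue_threshold: float = 1e-3
    dpi_tolerance: float = 0.15
    consensus_alpha: float = 0.05
    min_degree: int = 3
    min_stratum_samples: int = 10

    # signature selection / evaluation
    n_folds: int = 10
    n_repeats: int = 5
    n_lambda: int = 40
    predicted_c1_cutoff: float = 0.5

    # qPCR arm
    ct_reference_constant: float = 21.87
    ct_noise_sd: float = 0.25
    ct_sample_shift_sd: float = 1.0
    ct_ceiling: float = 40.0
    risk_threshold_percentile: float = 66.0
    run_qpcr_arm: bool = True

    def __post_init__(self) -> None:
        if self.fidelity not in FIDELITY_PRESETS:
            raise ValueError(f"unknown fidelity preset {self.fidelity!r}")

    def with_fidelity(self, fidelity: str) -> "PipelineConfig":
        """Copy of this config with the preset-controlled parameters applied."""
        preset = FIDELITY_PRESETS[fidelity]
        d = asdict(self)
        d["cohort"] = CohortConfig(**d["cohort"])
        d["fidelity"] = fidelity
        d.update(preset)
        return PipelineConfig(**d)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the single config seed."""
        h = 0
        for ch in stage:
            h = (h * 131 + ord(ch)) % 1_000_003
        return (self.seed * 10_007 + h) % (2**31)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            cohort = dict(d["cohort"])
            for key in ("baseline_mean_log_range", "stage_probs"):
                if key in cohort and isinstance(cohort[key], list):
                    cohort[key] = tuple(cohort[key])
            d["cohort"] = CohortConfig(**cohort)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
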