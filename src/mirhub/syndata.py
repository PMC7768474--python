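"""Synthetic paired mRNA/miRNA cohorts with planted regulatory structure.

The generator emulates the statistical structure the downstream analysis
assumes: two latent molecular subtypes (an aggressive ``C1`` subtype and a
pooled ``non-C1`` remainder), negative-binomial sequencing counts,
differentially expressed miRNAs and genes, a small panel of strongly
discriminative "panel" genes (the stand-in for a 10-gene prognostic
signature), hub miRNAs whose targets are repressed and anti-correlated with
the hub *only inside C1* (through a shared per-sample latent activity
scalar), censored survival with an elevated C1 hazard, and qPCR CT values
anchored to a stable reference miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_clinical
from .qpcr import CtMatrix

REFERENCE_MIRNA = "miR-ref"


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults are sized on a TCGA-LUAD-like lung adenocarcinoma cohort:
    510 tumors of which ~39% fall in the aggressive C1 subtype, stage
    distribution ~(54, 24, 16, 5)%, ~20% three-year mortality outside C1
    and a ~2.2-fold C1 death hazard.
    """

    n_samples: int = 510
    c1_fraction: float = 0.39
    n_mirna: int = 382
    n_gene: int = 2000
    n_hubs: int = 7
    targets_per_hub: int = 10
    hub_log2fc: float = 1.5
    target_log2fc: float = -1.0
    nb_dispersion: float = 0.2
    baseline_mean_log_range: tuple[float, float] = (3.0, 9.0)
    stage_probs: tuple[float, float, float, float] = (0.542, 0.241, 0.163, 0.054)
    hazard_ratio_c1: float = 2.2
    censor_rate: float = 0.25
    seed: int = 0
    # latent hub activity scalar weight; couples hubs to targets within C1
    coupling: float = 1.0
    # extra (non-hub) differential features and the clustering panel
    n_de_mirna_extra: int = 20
    n_de_gene_extra: int = 60
    # non-hub differential features shift by this fraction of the hub effect
    # (the hub miRNAs are the strongest differential miRNAs of the cohort)
    de_extra_scale: float = 0.6
    n_panel_genes: int = 10
    panel_log2fc: float | None = None  # default: 1.5 * |hub_log2fc|
    baseline_hazard: float = 0.08  # deaths per year in non-C1
    admin_censor_years: float = 6.0
    # non-C1 substructure: three prognostically equivalent sub-branches
    # (C2-C4) distinguished by panel-gene offsets, so a 4-branch dendrogram
    # cut yields four sizable clusters
    n_non_c1_branches: int = 3
    branch_panel_shift: float = 1.5

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_mirna": self.n_mirna,
            "n_gene": self.n_gene,
            "n_hubs": self.n_hubs,
            "targets_per_hub": self.targets_per_hub,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1 (got {v})")
        if not 0.0 < self.c1_fraction < 1.0:
            raise ValueError("c1_fraction must be in (0, 1)")
        if self.n_hubs * self.targets_per_hub + self.n_panel_genes > self.n_gene:
            raise ValueError("n_hubs * targets_per_hub + n_panel_genes exceeds n_gene")
        if self.n_hubs + self.n_de_mirna_extra + 1 > self.n_mirna:
            raise ValueError("hub + extra DE miRNAs + reference exceed n_mirna")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if abs(sum(self.stage_probs) - 1.0) > 1e-8:
            raise ValueError("stage_probs must sum to 1")

    @property
    def resolved_panel_log2fc(self) -> float:
        if self.panel_log2fc is not None:
            return self.panel_log2fc
        return 1.5 * abs(self.hub_log2fc)


@dataclass
class GroundTruth:
    """What was planted: hubs, C1-only regulatory edges, DE features, subtypes."""

    hub_ids: set[str]
    regulatory_edges: set[tuple[str, str]]
    de_mirna_ids: set[str]
    de_gene_ids: set[str]
    subtype_of: pd.Series  # sample -> "C1" | "nonC1"
    branch_of: pd.Series | None = None  # sample -> "C1" | "C2" | "C3" | "C4"
    mirna_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    panel_gene_ids: list[str] = field(default_factory=list)
    reference_mirna_id: str = REFERENCE_MIRNA

    def __post_init__(self) -> None:
        if not self.hub_ids <= self.de_mirna_ids:
            raise ValueError("hub_ids must be a subset of de_mirna_ids")
        edge_genes = {g for _, g in self.regulatory_edges}
        if not edge_genes <= self.de_gene_ids:
            raise ValueError("every regulatory edge's gene must be in de_gene_ids")


def desk_cohort(seed: int = 0, n_samples: int = 180) -> CohortConfig:
    """The packaged desk-scale fixture: 7 hubs x 10 targets among mostly
    null features, sized so the planted structure is a minority of the
    matrix (as in real cohorts) while the whole pipeline runs in seconds.
    """
    return CohortConfig(
        n_samples=n_samples,
        n_mirna=40,
        n_gene=500,
        n_de_mirna_extra=10,
        n_de_gene_extra=20,
        coupling=1.2,
        seed=seed,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Draw a paired miRNA/mRNA cohort with clinical table and ground truth.

    Returns ``(mirna_counts, gene_counts, clinical, truth)``; reproducible
    bit-for-bit given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    # subtype assignment
    n_c1 = max(1, min(n - 1, int(round(n * config.c1_fraction))))
    is_c1 = np.zeros(n, dtype=bool)
    is_c1[rng.choice(n, size=n_c1, replace=False)] = True
    # prognostically equivalent non-C1 sub-branches (C2..): differ only in
    # panel-gene offsets so the dendrogram shows four main branches
    branch = np.where(
        is_c1, 0, rng.integers(1, max(config.n_non_c1_branches, 1) + 1, size=n)
    )

    # feature naming encodes the planted role (readable ground truth)
    hub_ids = [f"miR-hub-{k + 1:02d}" for k in range(config.n_hubs)]
    de_mirna_extra = [f"miR-de-{k + 1:03d}" for k in range(config.n_de_mirna_extra)]
    n_null_mir = config.n_mirna - config.n_hubs - config.n_de_mirna_extra - 1
    null_mirna = [f"miR-null-{k + 1:04d}" for k in range(n_null_mir)]
    mirna_ids = hub_ids + de_mirna_extra + [REFERENCE_MIRNA] + null_mirna

    target_ids = [
        f"GENE-T{h + 1:02d}-{j + 1:02d}"
        for h in range(config.n_hubs)
        for j in range(config.targets_per_hub)
    ]
    panel_ids = [f"GENE-panel-{j + 1:02d}" for j in range(config.n_panel_genes)]
    n_extra_g = min(config.n_de_gene_extra, config.n_gene - len(target_ids) - len(panel_ids))
    de_gene_extra = [f"GENE-de-{k + 1:04d}" for k in range(n_extra_g)]
    n_null_g = config.n_gene - len(target_ids) - len(panel_ids) - n_extra_g
    null_genes = [f"GENE-null-{k + 1:04d}" for k in range(n_null_g)]
    gene_ids = target_ids + panel_ids + de_gene_extra + null_genes

    lo, hi = config.baseline_mean_log_range
    base_mir = rng.uniform(lo, hi, size=config.n_mirna)
    base_gene = rng.uniform(lo, hi, size=config.n_gene)
    # panel genes are well-expressed (a qPCR-able prognostic panel), which
    # keeps their log2 profiles stable enough for sample clustering
    panel_lo = max(lo, 0.5 * (lo + hi))
    base_gene[len(target_ids) : len(target_ids) + config.n_panel_genes] = rng.uniform(
        panel_lo, hi, size=config.n_panel_genes
    )

    # per-sample latent activity, one independent scalar per hub, active only
    # in C1; a hub and its own targets share it with opposite sign, which
    # couples them without making the hubs collinear with one another
    latent = (
        np.where(is_c1[None, :], rng.normal(0.0, 1.0, size=(config.n_hubs, n)), 0.0)
        * config.coupling
    )

    delta_mir = np.zeros((config.n_mirna, n))
    delta_gene = np.zeros((config.n_gene, n))
    c1 = is_c1.astype(float)

    for i in range(config.n_hubs):
        delta_mir[i] = c1 * config.hub_log2fc + latent[i]
    for k in range(config.n_de_mirna_extra):
        sign = 1.0 if k % 2 == 0 else -1.0
        delta_mir[config.n_hubs + k] = (
            c1 * sign * config.de_extra_scale * abs(config.hub_log2fc)
        )

    for t in range(len(target_ids)):
        delta_gene[t] = c1 * config.target_log2fc - latent[t // config.targets_per_hub]
    off = len(target_ids)
    for j in range(config.n_panel_genes):
        sign = 1.0 if j % 2 == 0 else -1.0
        delta_gene[off + j] = c1 * sign * config.resolved_panel_log2fc
        # Walsh-like +/-1 patterns separate the non-C1 branches on the panel
        for k in range(1, config.n_non_c1_branches + 1):
            bit = ((j >> (k - 1)) & 1) if k <= 2 else (((j >> 0) ^ (j >> 1)) & 1)
            pattern = 1.0 if bit else -1.0
            delta_gene[off + j] += (branch == k) * pattern * config.branch_panel_shift
    off += config.n_panel_genes
    for k in range(n_extra_g):
        sign = 1.0 if k % 2 == 0 else -1.0
        delta_gene[off + k] = (
            c1 * sign * config.de_extra_scale * abs(config.target_log2fc)
        )

    mean_mir = 2.0 ** (base_mir[:, None] + delta_mir)
    mean_gene = 2.0 ** (base_gene[:, None] + delta_gene)
    counts_mir = _nb_draw(rng, mean_mir, config.nb_dispersion)
    counts_gene = _nb_draw(rng, mean_gene, config.nb_dispersion)

    mirna = ExpressionMatrix(
        pd.DataFrame(counts_mir, index=mirna_ids, columns=sample_ids), scale="raw"
    )
    gene = ExpressionMatrix(
        pd.DataFrame(counts_gene, index=gene_ids, columns=sample_ids), scale="raw"
    )

    clinical = _generate_clinical(rng, sample_ids, is_c1, config)

    edges = {
        (hub_ids[h], f"GENE-T{h + 1:02d}-{j + 1:02d}")
        for h in range(config.n_hubs)
        for j in range(config.targets_per_hub)
    }
    truth = GroundTruth(
        hub_ids=set(hub_ids),
        regulatory_edges=edges,
        de_mirna_ids=set(hub_ids) | set(de_mirna_extra),
        de_gene_ids=set(target_ids) | set(panel_ids) | set(de_gene_extra),
        subtype_of=pd.Series(np.where(is_c1, "C1", "nonC1"), index=sample_ids),
        branch_of=pd.Series(
            np.where(is_c1, "C1", np.char.add("C", (branch + 1).astype(str))),
            index=sample_ids,
        ),
        mirna_ids=mirna_ids,
        gene_ids=gene_ids,
        panel_gene_ids=panel_ids,
        reference_mirna_id=REFERENCE_MIRNA,
    )
    return mirna, gene, clinical, truth


def _generate_clinical(
    rng: np.random.Generator, sample_ids: list[str], is_c1: np.ndarray, config: CohortConfig
) -> pd.DataFrame:
    n = len(sample_ids)
    age = np.clip(np.round(rng.normal(66, 9, size=n)), 35, 90).astype(int)
    sex = rng.choice(["M", "F"], size=n, p=[0.46, 0.54])
    smoking = rng.choice(
        ["current/former", "never", "missing"], size=n, p=[0.713, 0.122, 0.165]
    )
    # stage independent of subtype by default (keeps survival effect attributable
    # to subtype in recovery experiments)
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=list(config.stage_probs))

    hazard = config.baseline_hazard * np.where(is_c1, config.hazard_ratio_c1, 1.0)
    death = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        censor = np.full(n, np.inf)
    censor = np.minimum(censor, config.admin_censor_years)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)

    clinical = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "smoking": smoking,
            "stage": stage,
            "time": time,
            "event": event,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return validate_clinical(clinical)


def generate_target_predictions(
    truth: GroundTruth, extra_random_edges: int, seed: int
) -> set[tuple[str, str]]:
    """True regulatory edges plus decoy miRNA->gene pairs not in the truth.

    Emulates a predicted-target export: complete for the planted biology but
    diluted with spurious predictions.
    """
    rng = np.random.default_rng(seed)
    edges = set(truth.regulatory_edges)
    n_pairs = len(truth.mirna_ids) * len(truth.gene_ids)
    if len(edges) + extra_random_edges > n_pairs:
        raise ValueError("extra_random_edges exceeds available decoy pairs")
    decoys: set[tuple[str, str]] = set()
    while len(decoys) < extra_random_edges:
        m = truth.mirna_ids[rng.integers(len(truth.mirna_ids))]
        g = truth.gene_ids[rng.integers(len(truth.gene_ids))]
        if (m, g) not in edges and (m, g) not in decoys:
            decoys.add((m, g))
    return edges | decoys


def generate_ct_matrix(
    expr: ExpressionMatrix,
    reference_id: str,
    reference_ct_mean: float = 21.87,
    noise_sd: float = 0.25,
    seed: int = 0,
    sample_shift_sd: float = 0.0,
    base_ct: float = 30.0,
) -> CtMatrix:
    """qPCR CT values derived from expression: one cycle fewer per doubling.

    ``CT_ij = K_i - log2(x_ij) + shift_j + noise``; zero counts come out as
    undetermined (missing) CTs.  The reference feature's CT is drawn around
    ``reference_ct_mean`` independently of expression and subtype, emulating
    a stable endogenous reference.
    """
    if reference_id not in expr.values.index:
        raise KeyError(f"reference feature {reference_id!r} not in matrix")
    rng = np.random.default_rng(seed)
    x = expr.values.to_numpy().astype(float)
    with np.errstate(divide="ignore"):
        log2x = np.where(x > 0, np.log2(np.maximum(x, 1e-300)), np.nan)
    n_feat, n_samp = x.shape
    offsets = base_ct + rng.uniform(-2.0, 2.0, size=n_feat)
    # recenter so typical CTs sit in the usable range whatever the count scale
    offsets = offsets + np.nanmean(log2x)
    shift = rng.normal(0.0, sample_shift_sd, size=n_samp) if sample_shift_sd > 0 else np.zeros(n_samp)
    noise = rng.normal(0.0, noise_sd, size=(n_feat, n_samp)) if noise_sd > 0 else 0.0
    ct = offsets[:, None] - log2x + shift[None, :] + noise

    ref_pos = expr.values.index.get_loc(reference_id)
    ref_noise = rng.normal(0.0, noise_sd, size=n_samp) if noise_sd > 0 else np.zeros(n_samp)
    ct[ref_pos] = reference_ct_mean + shift + ref_noise

    values = pd.DataFrame(ct, index=expr.values.index, columns=expr.values.columns)
    return CtMatrix(values=values, normalized=False)
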