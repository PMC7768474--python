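# mirhub

Minimal prognostic miRNA "hub" signatures from paired mRNA/miRNA expression
of a tumor cohort.

Early-stage lung adenocarcinoma harbors an aggressive molecular subtype
("C1") with markedly worse 3-year survival. Long mRNAs degrade in the FFPE
blocks used for routine diagnostics, so an mRNA prognostic panel is hard to
deploy; short miRNAs survive fixation and are qPCR-friendly. `mirhub`
implements, as a tested pipeline package, a network-based procedure that
derives a *minimal* miRNA signature as a surrogate for an mRNA risk panel:

1. **Subtype clustering** — hierarchical clustering of samples on a small
   gene panel with *uncentered correlation* distance,
   `d(x, y) = 1 − (Σxᵢyᵢ)/(‖x‖‖y‖)`, and *centroid linkage* (size-weighted
   centroids in coordinate space); a 4-branch cut; the branch with the
   lowest Kaplan–Meier survival at 3 years becomes C1 and the rest pool as
   non-C1.
2. **Dual differential expression** — a negative-binomial Wald test
   (median-of-ratios size factors as offsets, gene-wise ML dispersion,
   Benjamini–Hochberg adjustment) and an independent two-sample *t* engine
   under multivariate-permutation false-discovery-proportion control
   (select the largest set whose FDP ≤ γ with confidence 1 − α).
3. **Penalized signatures** — lasso logistic regression of the C1 indicator
   with the penalty tuned by repeated 10-fold cross-validated held-out
   log-likelihood.
4. **Network rewiring** — ARACNe-style mutual-information networks
   (permutation-thresholded MI, Data Processing Inequality pruning,
   bootstrap consensus) inferred separately for C1/non-C1 × all/stage-I/
   stage-II–IV strata, then filtered by the four-rule cascade: (1) edges
   present only in C1 networks and supported in stage I, (2) predicted
   miRNA→gene targeting, (3) opposite miRNA/gene expression trends,
   (4) miRNAs keeping ≥ 3 targets — the **hubs**.
5. **Evaluation** — cross-validated AUC of each signature,
   Wilcoxon–Mann–Whitney contrast of predicted C1 probabilities,
   Kaplan–Meier/log-rank, and Cox proportional-hazards models (Efron
   partial likelihood; univariate and adjusted for age, sex, smoking,
   stage) on 3-year-truncated follow-up.
6. **qPCR validation arm** — CT values normalized by the per-sample scaling
   factor `SF_j = CT_ref,j − 21.87`, q1–q3 (interquartile) rescaling, a
   weighted risk score cut at the 66th percentile, and an unpenalized
   logistic refit of the hub signature on CT data.

Real patient data are not bundled; a first-class synthetic-cohort generator
(`mirhub.syndata`) plants the structure the method assumes — two latent
subtypes with three prognostically equivalent non-C1 sub-branches, hub
miRNAs anti-correlated with their targets only inside C1 via per-hub latent
activities, negative-binomial counts, censored survival with elevated C1
hazard, and CT values anchored to a stable reference miRNA — so every stage
can be tested against known ground truth.

## Worked example

```python
import dataclasses
from mirhub.config import PipelineConfig
from mirhub.syndata import desk_cohort, generate_cohort, generate_target_predictions
from mirhub.pipeline import infer_hub_candidates

pcfg = PipelineConfig(seed=1, n_bootstraps=100)
cfg = dataclasses.replace(desk_cohort(), seed=pcfg.stage_seed("simulate"))
mirna, gene, clinical, truth = generate_cohort(cfg)
preds = generate_target_predictions(truth, 10 * len(truth.regulatory_edges),
                                    seed=pcfg.stage_seed("predictions"))
bundle = infer_hub_candidates(mirna, gene, clinical,
                              truth.subtype_of == "C1", preds, pcfg)
print(bundle["rewiring"].cardinalities)
print(sorted(bundle["rewiring"].hub_candidates))
```

prints

```
{'rule1': 66, 'rule2': 57, 'rule3': 56, 'rule4': 56}
['miR-hub-01', 'miR-hub-02', 'miR-hub-03', 'miR-hub-04', 'miR-hub-05', 'miR-hub-06', 'miR-hub-07']
```

— the cascade's nested edge counts (66 C1-only stage-I-supported edges, 57
of them predicted targets, 56 with opposite trends, 56 belonging to
well-connected miRNAs) and the recovered hub set: all 7 planted hubs, no
false positives, out of 770 candidate predictions.

The full pipeline, including clustering, both signatures, survival models
and the qPCR arm, runs from one config:

```bash
mirhub run-all --seed 1 --out results/run1        # desk-scale defaults
mirhub run-all --seed 1 --fidelity paper --out results/run1p
```

Each stage writes a tab-separated table under `--out`, plus `manifest.json`
(seeds, parameters, version — sufficient to reproduce the run bit for bit)
and `summary.json`. Individual stages are exposed as CLI verbs
(`simulate`, `cluster`, `filter`, `de`, `signature`, `network`, `rewire`,
`evaluate`, `qpcr`).

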