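# Methods

This note records the models behind `mirhub`, the choices made where the
design was genuinely open, and what the synthetic cohorts do and do not
establish.

## Cohort model (the synthetic generator)

`mirhub.syndata.generate_cohort` draws a paired miRNA/mRNA cohort from an
explicit generative model:

* **Subtypes.** Each sample is C1 with probability `c1_fraction`
  (default 0.39); non-C1 samples split uniformly over three
  prognostically equivalent sub-branches (C2–C4) that differ only in
  offsets on the clustering panel genes (±`branch_panel_shift`, default
  1.5 log2 units, Walsh-pattern signs). Four sizable dendrogram branches
  is the regime the subtype-clustering step is designed for; with a single
  non-C1 population the extra cuts isolate noise outliers instead.
* **Counts.** `count ~ NB(mean, dispersion)` with a single dispersion
  shared across features (default 0.2) and per-feature baseline log2 means
  uniform on `baseline_mean_log_range` (default 3–9). Panel genes draw
  their baselines from the upper half of that range: a qPCR-able prognostic
  panel is well expressed, and low-count panel genes would make sample
  clustering hostage to shot noise.
* **Regulatory structure.** `n_hubs` hub miRNAs (default 7) are shifted by
  `hub_log2fc` (default +1.5) in C1. Each hub owns `targets_per_hub` target
  genes (default 10) shifted by `target_log2fc` (default −1.0) in C1.
  Inside C1, hub *k* and its targets share an independent per-sample latent
  activity scalar (weight `coupling`) with opposite signs — this creates
  mutual information between a hub and its own targets only within C1,
  without making the hubs collinear with one another (a single cohort-wide
  latent would, and the lasso then provably drops most hubs from the
  signatures). Additional differential features (`n_de_mirna_extra`,
  `n_de_gene_extra`) shift by `de_extra_scale` (default 0.6) times the
  hub/target effect: the hubs are the strongest differential miRNAs, as in
  the cohort this emulates. The latent's log-normal mean term attenuates
  the realized mean fold change of targets (≈ −0.5 log2 at the defaults);
  tests account for the realized, not the nominal, effect.
* **Survival.** Death times are exponential with hazard
  `baseline_hazard × hazard_ratio_c1^{1{C1}}` (defaults 0.08/yr and 2.2),
  censored by an independent exponential (0.25/yr) and a 6-year
  administrative cutoff; this yields ~20% 3-year mortality outside C1.
  Stage is drawn independently of subtype (default probabilities
  54/24/16/5%), so survival effects in recovery experiments are
  attributable to the subtype alone.
* **CT values.** `CT = K_i − log2(count) + shift_j + noise`; zero counts
  are undetermined (missing). The reference miRNA's CT is drawn around the
  normalization constant (21.87 cycles) independently of subtype.

What the generator does **not** emulate: library-size artifacts beyond
global scaling, batch effects, tag-wise dispersion trends, miRNA–mRNA
feedback, non-proportional hazards, or qPCR efficiency/plate effects.
Passing tests therefore demonstrate that the pipeline recovers structure
under its own model assumptions, not performance on real cohorts.

## Clustering

Uncentered correlation distance with centroid linkage is implemented
directly (scipy restricts centroid linkage to Euclidean distance): clusters
carry size-weighted mean vectors, merge height is the distance between
centroids, and ties break to the lowest cluster-index pair. Input is
log2(count+1), median-centered per feature by default (configurable; the
centering convention of desktop clustering tools is not universal).
Cutting removes the k−1 highest merges (ties: later merge removed first).
C1 is the cluster with the lowest Kaplan–Meier survival at the 3-year
horizon; ties fall back to the restricted mean, then the lowest label.
Pooling of the remaining clusters always proceeds; pairwise log-rank
p-values among them are reported and a warning is raised if any pair
differs at `pool_alpha`.

## Differential expression

The NB Wald engine estimates size factors by median-of-ratios
(renormalized to geometric mean 1; positive-count fallback with a warning
when no feature is expressed everywhere), then fits, per gene, a
log-linear NB model with a group indicator and log-size-factor offset.
Dispersion is gene-wise maximum likelihood (moment start, coarse log-grid
bracket, vectorized ternary refinement), alternated with Newton steps for
the coefficients; there is **no** empirical-Bayes dispersion shrinkage —
a deliberate simplification, whose cost is visible only as mildly
anti-conservative small-sample behavior; the empirical type-I error at
n = 120 is ~0.05–0.06 and is asserted to stay within [0.03, 0.08].
Size factors are always computed on the *full* count matrix: filtered
subsets are enriched for regulated features and bias median-of-ratios.

The permutation engine computes Welch t p-values (pooled variant
available) and applies a step-down rule: extend the p-ordered selection
while each ordered p stays below the `1 − confidence` quantile of the
permutation distribution of the corresponding order statistic, allowing
`floor(max_fp_proportion × rank)` false positives. Label permutations are
enumerated exhaustively when few enough, otherwise Monte-Carlo sampled
with a fixed seed.

## Network inference

Two rank-based MI estimators: adaptive partitioning (recursive quadrant
splits of the rank-rank plane, χ²(3 df, α=0.05) uniformity stop, minimum
cell of 8 points) and a Gaussian-copula estimator
(`−½ log(1 − ρ²)` on normal scores) that vectorizes over all pairs and is
the desk-scale default for bootstrap consensus. The adaptive estimator
reflects the y-ranks when the rank correlation is negative: MI is invariant
under monotone maps, and orienting pairs along the main diagonal keeps the
dyadic splits aligned with the dependence so decreasing relationships
score identically to increasing ones. Because both estimators see only
ranks, a single permutation null (pooled over shuffled pairs) serves every
pair of a run.

Significance thresholding keeps pairs with permutation p ≤ 1e-3
(n_null ≥ 1000). DPI examines regulator–regulator–target triangles on the
bipartite regulon, computing regulator–regulator MI on demand, marks the
strictly weakest edge for removal when below `(1 − tolerance) ×` the
smaller of the other two (tolerance 0.15), and removes marks in one sweep
— order-independent and idempotent. Bootstrap consensus resamples samples
with replacement (resamples with < 8 distinct samples are redrawn), counts
edge appearances, and keeps edges whose count is binomially improbable at
`consensus_alpha` applied **familywise** (Bonferroni over scored pairs),
the convention of bootstrap-ARACNe implementations; a raw per-edge α of
0.05 floods the non-C1 networks with weakly supported edges that then
falsely disqualify true C1-only pairs at rewiring rule 1.

Rewiring: rule 1 keeps edges present in both the C1 all-patients and C1
stage-I consensus networks and absent from every non-C1 network ("C1-only,
stage-I supported but not exclusive"); rule 2 intersects with predicted
targeting; rule 3 requires opposite miRNA/gene fold-change signs with the
gene differential at unadjusted p < 0.05; rule 4 keeps miRNAs with ≥ 3
surviving targets. Hub selection intersects the rule-4 candidates with the
union of the candidate signatures and records per-hub provenance.

## Signatures and evaluation

The lasso path is fit per penalty with liblinear (penalty `λ = 1/(nC)`),
predictors standardized internally and coefficients mapped back. liblinear
penalizes the intercept, so after each fit the intercept is refit
unpenalized by a one-dimensional Newton step at fixed coefficients (the
all-zero model's intercept is then exactly the prevalence log-odds). The
penalty maximizes held-out log-likelihood averaged over `n_repeats` random
10-fold splits; ties go to the stronger penalty. The default grid is
log-spaced over four decades down from the smallest all-zero penalty.
Note that prediction-optimal penalties are not selection-consistent: the
planted support is recovered essentially completely in simulations, but
decoy features enter alongside it.

AUC is the Mann–Whitney statistic with ties counted ½; cross-validated AUC
pools out-of-fold probabilities within a repeat and averages AUCs over
repeats (stratified folds). Survival evaluation truncates follow-up at 3
years (later times censored at the horizon), then fits Kaplan–Meier,
log-rank, and Cox models; Cox uses the Efron partial likelihood
(lifelines, convergence 1e-10) with a Breslow variant (scikit-survival)
that coincides when event times are distinct. Categorical covariates
expand against fixed reference levels (sex M, smoking current/former,
stage I) with "missing" kept as an explicit level.

## qPCR arm

`SF_j = CT_ref,j − 21.87` is subtracted from every CT of sample j, pinning
the reference at the constant and preserving within-sample CT differences
exactly; normalization is idempotent. Undetermined wells impute at a
40-cycle ceiling before normalization. q1–q3 rescaling is per feature
across samples with linear-interpolation quartiles (zero IQR is an error
naming the feature). Risk scores are weighted sums of rescaled values;
C1 requires `score >` the 66th percentile, recomputed on the cohort by
default or carried from a training cohort via an explicit threshold (with
the strict rule and an interpolated cohort-recomputed cut, at most
⌊0.34 (n−1)⌋ samples can be called C1 — 15 of 44 — so reproducing a 16/28
split requires the carried-cut mode). The hub model refit is unpenalized
logistic regression on normalized CTs; hubs absent from the card are
reported and excluded.

## Problem sizes

The packaged desk-scale fixture (`syndata.desk_cohort`) uses 180 samples,
40 miRNAs, 500 genes, 7 hubs × 10 targets, coupling 1.2, and 100 network
bootstraps; predictions are truth plus 10× random decoys. Calibration
experiments use 2000 null features (type-I error), 150–200 replicates
(permutation FDP, Cox recovery and coverage, null p-value uniformity),
60–100 cohorts (worst-prognosis-cluster recovery), and 6–20 cohorts (hub
recall). The `paper` fidelity preset raises bootstraps to 1000,
permutations to 1000 and cross-validation repeats to 50; it changes
nothing else.

## Known limitations

* Hub recall is reported against the planted truth of the generator; on
  real cohorts the "truth" is unknown and rule-1 specificity depends on
  stratum sample sizes (the stage-I C1 stratum is the binding constraint).
* The NB Wald test's lack of dispersion shrinkage makes it mildly liberal
  at small n; it is calibrated empirically, not exactly.
* Gaussian-copula MI under-detects non-monotone dependence; the adaptive
  estimator is available where that matters, at higher cost.
* The subtype-clustering step inherits the instability of centroid linkage
  under weak separation; with the default hazard ratio (2.2) the C1 call
  can land on a wrong branch in a few percent of simulated cohorts, which
  is a property of the survival noise, not of the cascade.
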