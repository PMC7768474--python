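"""End-to-end orchestration: cluster -> filter -> DE -> signatures ->
stratified networks -> rewiring -> hubs -> survival evaluation -> qPCR arm.

Every stage writes its table under the output directory and the run is
described by a machine-readable ``manifest.json`` (parameters, per-stage
seeds, package version) sufficient to reproduce it bit for bit; the main
numbers land in ``summary.json``.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diffexpr, io, netinfer, preprocess, qpcr, signature, survival, syndata
from .config import PipelineConfig
from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

STRATA = {
    "all": lambda clin: pd.Series(True, index=clin.index),
    "stageI": lambda clin: clin["stage"] == "I",
    "stageII_IV": lambda clin: clin["stage"].isin(["II", "III", "IV"]),
}


def _load_or_simulate(config: PipelineConfig, outdir: Path):
    """Resolve inputs: read provided paths, synthesize the rest."""
    truth = None
    if config.mirna_counts_path and config.gene_counts_path and config.clinical_path:
        mirna = io.read_count_matrix(config.mirna_counts_path)
        gene = io.read_count_matrix(config.gene_counts_path)
        clinical = io.read_clinical_table(config.clinical_path)
    else:
        cohort = syndata.CohortConfig(
            **{**config.cohort.__dict__, "seed": config.stage_seed("simulate")}
        )
        mirna, gene, clinical, truth = syndata.generate_cohort(cohort)
        io.write_count_matrix(mirna, outdir / "mirna_counts.tsv")
        io.write_count_matrix(gene, outdir / "gene_counts.tsv")
        io.write_clinical_table(clinical, outdir / "clinical.tsv")

    if config.predictions_path:
        predictions = io.read_prediction_edges(config.predictions_path)
    elif truth is not None:
        predictions = syndata.generate_target_predictions(
            truth,
            extra_random_edges=config.prediction_decoy_factor * len(truth.regulatory_edges),
            seed=config.stage_seed("predictions"),
        )
        io.write_prediction_edges(predictions, outdir / "predictions.tsv")
    else:
        raise ValueError("predictions_path required when inputs are not simulated")

    if config.panel_path:
        panel = io.read_feature_list(config.panel_path)
    elif truth is not None:
        panel = truth.panel_gene_ids
        io.write_feature_list(panel, outdir / "panel.tsv")
    else:
        raise ValueError("panel_path required when inputs are not simulated")
    return mirna, gene, clinical, predictions, panel, truth


def infer_hub_candidates(
    mirna: ExpressionMatrix,
    gene: ExpressionMatrix,
    clinical: pd.DataFrame,
    is_c1: pd.Series,
    predictions: set[tuple[str, str]],
    config: PipelineConfig,
) -> dict:
    """Filters, dual DE, stratified consensus networks and the rewiring
    cascade, starting from a given C1/non-C1 labeling.

    Returns a bundle with the filtered matrices, DE tables, selection lists,
    stratified networks and the :class:`~mirhub.netinfer.RewiringResult`.
    """
    mirna_f = preprocess.filter_detected(mirna, is_c1=is_c1, min_fraction=config.min_detection_fraction)
    gene_f = preprocess.filter_detected(gene, is_c1=is_c1, min_fraction=config.min_detection_fraction)
    gene_f = preprocess.filter_top_variance(gene_f.log2(), config.variance_quantile)

    # size factors from the full matrices; filtered subsets are biased toward
    # regulated features and would distort median-of-ratios
    mirna_de = diffexpr.nb_wald_test(mirna_f, is_c1, sf=diffexpr.size_factors(mirna))
    gene_de = diffexpr.nb_wald_test(
        gene.subset_features(gene_f.feature_ids), is_c1, sf=diffexpr.size_factors(gene)
    )
    deseq_list = list(
        mirna_de.index[mirna_de[config.mirna_de_scale] < config.mirna_de_threshold]
    )
    de_genes = list(gene_de.index[gene_de["p"] < config.gene_p_threshold])

    aracne_base = dict(
        n_bootstraps=config.n_bootstraps,
        mi_estimator=config.mi_estimator,
        mi_pvalue_threshold=config.mi_pvalue_threshold,
        dpi_tolerance=config.dpi_tolerance,
        consensus_alpha=config.consensus_alpha,
    )
    target_expr = gene_f.subset_features(de_genes)
    log_mirna_f = mirna_f.log2()
    networks: dict[str, netinfer.InteractionNetwork] = {}
    groups = (
        ("C1", list(is_c1.index[is_c1])),
        ("nonC1", list(is_c1.index[~is_c1])),
    )
    for group, members in groups:
        for stratum, mask_fn in STRATA.items():
            mask = mask_fn(clinical)
            samples = [s for s in members if bool(mask.get(s, False))]
            key = f"{group}:{stratum}"
            if len(samples) < config.min_stratum_samples:
                logger.warning("stratum %s has %d samples; skipped", key, len(samples))
                continue
            cfg_s = netinfer.AracneConfig(
                **aracne_base, seed=config.stage_seed(f"aracne:{key}")
            )
            networks[key] = netinfer.bootstrap_consensus(
                log_mirna_f.subset_samples(samples),
                target_expr.subset_samples(samples),
                deseq_list,
                cfg_s,
                stratum=key,
            )

    rewiring = netinfer.rewire_c1(
        networks,
        predictions,
        mirna_de,
        gene_de,
        min_degree=config.min_degree,
        gene_p_threshold=config.gene_p_threshold,
    )
    return {
        "mirna_filtered": mirna_f,
        "gene_filtered": gene_f,
        "mirna_de": mirna_de,
        "gene_de": gene_de,
        "deseq_list": deseq_list,
        "de_genes": de_genes,
        "networks": networks,
        "rewiring": rewiring,
    }


def run_all(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline; returns the summary dict written to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    summary: dict = {"seed": config.seed, "fidelity": config.fidelity}

    def stage(name):
        timings[name] = time.perf_counter()
        logger.info("stage %s", name)

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    stage("inputs")
    mirna, gene, clinical, predictions, panel, truth = _load_or_simulate(config, outdir)
    done("inputs")

    # --- clustering on the panel genes -----------------------------------
    stage("cluster")
    panel_expr = gene.subset_features([p for p in panel if p in gene.values.index]).log2()
    dendro = preprocess.hierarchical_cluster(panel_expr, center=config.clustering_center)
    clusters = preprocess.cut_k_branches(dendro, k=config.k_clusters)
    labels = preprocess.assign_c1(
        clusters, clinical, horizon=config.horizon_years, pool_alpha=config.pool_alpha
    )
    io.write_cluster_assignments(clusters, outdir / "clusters.tsv")
    io.write_cluster_assignments(
        labels.is_c1.map({True: "C1", False: "nonC1"}), outdir / "subtype.tsv"
    )
    summary["n_c1"] = int(labels.is_c1.sum())
    summary["n_non_c1"] = int((~labels.is_c1).sum())
    done("cluster")

    # --- filters, DE, networks, rewiring ------------------------------------
    stage("cascade")
    bundle = infer_hub_candidates(
        mirna, gene, clinical, labels.is_c1, predictions, config
    )
    mirna_f = bundle["mirna_filtered"]
    mirna_de, gene_de = bundle["mirna_de"], bundle["gene_de"]
    deseq_list, de_genes = bundle["deseq_list"], bundle["de_genes"]
    networks, rewiring = bundle["networks"], bundle["rewiring"]
    summary["n_mirna_detected"] = mirna_f.n_features
    summary["n_gene_top_variance"] = bundle["gene_filtered"].n_features
    io.write_de_table(mirna_de, outdir / "mirna_de.tsv")
    io.write_de_table(gene_de, outdir / "gene_de.tsv")
    for key, net in networks.items():
        io.write_network(net, outdir / f"network_{key.replace(':', '_')}.tsv")

    perm_cfg = diffexpr.PermutationTestConfig(
        n_perm=config.n_perm,
        confidence=config.perm_confidence,
        max_fp_proportion=config.perm_max_fp_proportion,
        seed=config.stage_seed("permutation"),
    )
    brb_list, _brb_table = diffexpr.multivariate_permutation_ttest(
        mirna_f.log2(), labels.is_c1, perm_cfg
    )
    both, _only_deseq, _only_brb = diffexpr.de_overlap(deseq_list, brb_list)
    io.write_feature_list(deseq_list, outdir / "mirna_deseq_list.tsv")
    io.write_feature_list(brb_list, outdir / "mirna_brb_list.tsv")
    summary["n_mirna_deseq"] = len(deseq_list)
    summary["n_mirna_brb"] = len(brb_list)
    summary["n_mirna_overlap"] = len(both)
    summary["n_gene_de"] = len(de_genes)
    done("cascade")

    # --- lasso signatures ---------------------------------------------------
    stage("signature")
    log_mirna = mirna_f.log2().values.T  # samples x features
    cvcfg = signature.CvConfig(
        n_folds=config.n_folds,
        n_repeats=config.n_repeats,
        n_lambda=config.n_lambda,
        seed=config.stage_seed("lasso"),
    )
    signatures: dict[str, signature.LogisticSignature] = {}
    for name, feat_list in (("deseq", deseq_list), ("brb", brb_list)):
        if len(feat_list) == 0:
            logger.warning("empty %s miRNA list; skipping its signature", name)
            continue
        sig = signature.lasso_logistic_cv(log_mirna[feat_list], labels.is_c1.astype(int), cvcfg)
        signatures[name] = sig
        io.write_signature(sig, outdir / f"signature_{name}.tsv")
        summary[f"signature_{name}_size"] = len(sig.selected_features)
    done("signature")

    # --- hub selection -------------------------------------------------------
    stage("rewire")
    summary["cascade"] = rewiring.cardinalities
    candidate_sigs = [set(sig.selected_features) for sig in signatures.values()]
    hubset = netinfer.select_hubs(rewiring, candidate_sigs or [set(deseq_list)])
    io.write_feature_list(sorted(hubset.hubs), outdir / "hubs.tsv")
    summary["n_hubs"] = len(hubset.hubs)
    if truth is not None:
        cand = rewiring.hub_candidates
        summary["hub_candidate_recall"] = len(cand & truth.hub_ids) / len(truth.hub_ids)
        summary["hub_candidate_false_positives"] = len(cand - truth.hub_ids)
        recovered = hubset.hubs & truth.hub_ids
        summary["hub_recall"] = len(recovered) / len(truth.hub_ids)
        summary["hub_false_positives"] = len(hubset.hubs - truth.hub_ids)
    done("rewire")

    # --- evaluation -----------------------------------------------------------
    stage("evaluate")
    eval_sigs = dict(signatures)
    if hubset.hubs:
        hub_sig = signature.lasso_logistic_cv(
            log_mirna[sorted(hubset.hubs)],
            labels.is_c1.astype(int),
            signature.CvConfig(
                n_folds=config.n_folds,
                n_repeats=config.n_repeats,
                n_lambda=config.n_lambda,
                lambda_grid=np.geomspace(1e-2, 1e-4, 10),
                seed=config.stage_seed("hub-signature"),
            ),
        )
        eval_sigs["hub"] = hub_sig
        io.write_signature(hub_sig, outdir / "signature_hub.tsv")

    evaluation: dict[str, dict] = {}
    surv_data = survival.truncate_followup(clinical, config.horizon_years)
    for name, sig in eval_sigs.items():
        feats = sig.selected_features or sig.feature_ids
        X = log_mirna[feats]
        cv_auc = signature.cross_validated_auc(
            X,
            labels.is_c1.astype(int),
            cv=signature.CvConfig(
                n_folds=config.n_folds,
                n_repeats=config.n_repeats,
                seed=config.stage_seed(f"cvauc:{name}"),
            ),
        )
        probs = signature.predict_c1_probability(
            signature.LogisticSignature(feats, [sig.coefficients[sig.feature_ids.index(f)] for f in feats], sig.intercept, sig.lambda_),
            X,
        )
        wmw_p = signature.wilcoxon_mann_whitney(
            probs[labels.is_c1], probs[~labels.is_c1]
        )
        predicted_c1 = probs >= config.predicted_c1_cutoff
        entry = {
            "cv_auc": cv_auc,
            "wmw_p": wmw_p,
            "n_predicted_c1": int(predicted_c1.sum()),
        }
        if predicted_c1.nunique() == 2:
            chi2, lr_p = survival.log_rank_test(surv_data, predicted_c1)
            entry["logrank_p"] = lr_p
            cox_in = surv_data.copy()
            cox_in["predicted_c1"] = predicted_c1.astype(float)
            for stratum in ("all", "stageI", "stageII_IV"):
                mask = STRATA[stratum](cox_in)
                sub = cox_in[mask]
                if sub["event"].sum() < 5 or sub["predicted_c1"].nunique() < 2:
                    continue
                uni = survival.cox_ph(sub, ["predicted_c1"])
                adj_covs = ["predicted_c1", "age", "sex", "smoking"]
                if stratum == "all":
                    adj_covs.append("stage")
                adj = survival.cox_ph(sub, adj_covs)
                entry[f"cox_{stratum}"] = {
                    "hr": float(uni.loc["predicted_c1", "hr"]),
                    "ci": [
                        float(uni.loc["predicted_c1", "ci_low"]),
                        float(uni.loc["predicted_c1", "ci_high"]),
                    ],
                    "p": float(uni.loc["predicted_c1", "p"]),
                    "hr_adjusted": float(adj.loc["predicted_c1", "hr"]),
                    "p_adjusted": float(adj.loc["predicted_c1", "p"]),
                    "n": int(len(sub)),
                    "n_events": int(sub["event"].sum()),
                }
        evaluation[name] = entry
    summary["evaluation"] = evaluation
    done("evaluate")

    # --- qPCR validation arm ---------------------------------------------------
    if config.run_qpcr_arm and truth is not None and hubset.hubs:
        stage("qpcr")
        card_features = sorted(hubset.hubs | set(truth.panel_gene_ids))
        combined = pd.concat(
            [
                mirna.values.loc[[f for f in card_features if f in mirna.values.index]],
                gene.values.loc[[f for f in card_features if f in gene.values.index]],
                mirna.values.loc[[truth.reference_mirna_id]],
            ]
        )
        card = ExpressionMatrix(combined, scale="raw")
        ct = syndata.generate_ct_matrix(
            card,
            truth.reference_mirna_id,
            reference_ct_mean=config.ct_reference_constant,
            noise_sd=config.ct_noise_sd,
            seed=config.stage_seed("ct"),
            sample_shift_sd=config.ct_sample_shift_sd,
        )
        io.write_ct_matrix(ct, outdir / "ct_raw.tsv")
        ct = qpcr.impute_undetermined(ct, config.ct_ceiling)
        ct_norm = qpcr.normalize_ct(
            ct, truth.reference_mirna_id, config.ct_reference_constant
        )
        io.write_ct_matrix(ct_norm, outdir / "ct_normalized.tsv")

        if config.risk_weights_path:
            genes_w, weights = io.read_risk_weights(config.risk_weights_path)
        else:
            # surrogate weights: planted direction of each panel gene, on the
            # CT scale (lower CT = higher expression, hence the sign flip)
            genes_w = [g for g in truth.panel_gene_ids if g in ct_norm.values.index]
            weights = [-1.0 if i % 2 == 0 else 1.0 for i in range(len(genes_w))]
            io.write_risk_weights(genes_w, weights, outdir / "risk_weights.tsv")
        rescaled = qpcr.q1q3_rescale(ct_norm.values.loc[genes_w])
        model = qpcr.RiskModel(
            genes_w, weights, threshold_percentile=config.risk_threshold_percentile
        )
        scores, risk_c1 = qpcr.risk_classify(rescaled, model)
        hub_model, auc_all, auc_stage1 = qpcr.refit_hub_model(
            ct_norm,
            sorted(hubset.hubs),
            risk_c1,
            stage=clinical["stage"],
        )
        io.write_signature(hub_model, outdir / "signature_qpcr_hub.tsv")
        summary["qpcr"] = {
            "n_risk_c1": int(risk_c1.sum()),
            "auc_all": auc_all,
            "auc_stage1": auc_stage1,
            "risk_label_agreement": float((risk_c1 == labels.is_c1).mean()),
        }
        done("qpcr")

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {
            s: config.stage_seed(s)
            for s in ("simulate", "predictions", "permutation", "lasso", "aracne", "ct")
        },
        "timings_s": timings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", outdir)
    return summary
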