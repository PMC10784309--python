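"""End-to-end orchestration: purify -> cluster -> classify -> score -> survival.

Each stage writes its outputs (CSV/JSON) into the run directory and the run
log records seeds and package version, so a run is a pure function of
(inputs, config).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohortio import (
    ExpressionMatrix,
    GeneSetCollection,
    join_check,
    log_transform,
    validate_clinical,
)
from .config import RunConfig
from .core37 import build_signatures, core37_score, differential_expression
from .purify import stratify_cohort, tissue_ntp
from .subtype_classifier import ntp_predict, select_classifier_genes, snr_scores
from .subtype_cluster import consensus_cluster, hierarchical_dendrogram, tree_to_newick
from .survival_eval import (
    cox_fit,
    km_logrank,
    nri_compare,
    records_from_clinical,
    time_dependent_auc,
)

__all__ = ["run_pipeline"]

DAYS_PER_YEAR = 365.25


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(
    config: RunConfig,
    expr: ExpressionMatrix,
    clin: pd.DataFrame,
    tissue_templates: GeneSetCollection,
    outdir,
) -> dict:
    """Run all stages in order; returns the run summary dict.

    ``expr`` must be TPM scale; ``tissue_templates`` holds the liver/pancreas
    marker sets used for purification.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clin = validate_clinical(clin)
    join_check(expr, clin)
    logx = log_transform(expr)
    summary: dict = {"version": __version__, "seed": config.seed, "n_samples": expr.shape[1]}

    # --- purify ---------------------------------------------------------
    ntp = _stage("purify")(tissue_ntp)(
        logx, tissue_templates, n_perm=config.classifier.n_perm, seed=config.stage_seed("purify")
    )
    split = _stage("purify")(stratify_cohort)(
        ntp, clin, fdr_max=config.thresholds.ntp_fdr, contamination_min=config.thresholds.contamination
    )
    split.reasons.to_csv(outdir / "purify.csv")
    summary["purified_n"] = len(split.purified)
    summary["verification_n"] = len(split.verification)

    # --- cluster (consensus on the purified cohort) ---------------------
    pur_log = logx.subset_samples(split.purified)
    cons = _stage("cluster")(consensus_cluster)(
        pur_log,
        k_range=range(config.cluster.k_min, config.cluster.k_max + 1),
        reps=config.cluster.reps,
        subsample_frac=config.cluster.subsample_frac,
        seed=config.stage_seed("cluster"),
        inner=config.cluster.inner,
        n_features=config.cluster.n_features,
    )
    lab = cons.labels_series()
    # name classes by size: smaller cluster = C1 (mesenchymal-like minority)
    sizes = lab.value_counts().sort_values(kind="stable")
    mapping = {old: f"C{i+1}" for i, old in enumerate(sizes.index)}
    subtype = lab.map(mapping)
    subtype.rename("subtype").to_csv(outdir / "cluster_labels.csv")
    pd.DataFrame(cons.consensus[cons.chosen_k], index=cons.samples, columns=cons.samples).to_csv(
        outdir / f"consensus_k{cons.chosen_k}.csv.gz"
    )
    Z, leaf_order = hierarchical_dendrogram(pur_log)
    (outdir / "dendrogram.nwk").write_text(tree_to_newick(Z, leaf_order) + "\n")
    summary["chosen_k"] = cons.chosen_k
    summary["pac"] = {str(k): v for k, v in cons.pac.items()}
    summary["class_proportions"] = (
        subtype.value_counts(normalize=True).sort_index().round(4).to_dict()
    )

    # --- classify -------------------------------------------------------
    if cons.chosen_k != 2:
        raise RuntimeError(f"pipeline stage 'classify' failed: expected 2 classes, got {cons.chosen_k}")
    snr = _stage("classify")(snr_scores)(pur_log, subtype, sigma_floor=config.classifier.sigma_floor)
    templates = _stage("classify")(select_classifier_genes)(
        snr, (config.classifier.n_genes_c1, config.classifier.n_genes_c2)
    )
    pred = _stage("classify")(ntp_predict)(
        logx,
        templates,
        n_perm=config.classifier.n_perm,
        seed=config.stage_seed("classify"),
        confident_call_fdr=config.thresholds.confident_call_fdr,
    )
    pred.table.to_csv(outdir / "classifier_calls.csv")
    resub = pred.table.loc[subtype.index]
    conf = resub["confident"]
    summary["confident_fraction"] = float(conf.mean())
    if conf.any():
        summary["resubstitution_precision"] = float(
            (resub.loc[conf, "predicted"] == subtype[conf]).mean()
        )

    # --- score ----------------------------------------------------------
    de = _stage("score")(differential_expression)(pur_log, subtype, reference="C2")
    sig = _stage("score")(build_signatures)(
        de,
        adj_p_max=config.thresholds.de_adj_p,
        abs_fc_min=config.thresholds.de_abs_fc,
        max_per_class=(config.classifier.sig_max_c1, config.classifier.sig_max_c2),
    )
    scores = _stage("score")(core37_score)(logx, sig)
    scores.to_csv(outdir / "core37_scores.csv")
    summary["signature_sizes"] = [len(sig.c1_like), len(sig.c2_like)]

    # --- survival -------------------------------------------------------
    extra = pd.DataFrame({"subtype": subtype}).join(scores[["core37", "quartile"]], how="inner")
    rec = records_from_clinical(clin, extra)
    km = _stage("survival")(km_logrank)(rec, "subtype")
    summary["km"] = {
        "medians": km["medians"],
        "logrank_chi2": km["chi2"],
        "logrank_p": km["p"],
    }
    cox_uni = _stage("survival")(cox_fit)(rec, ["subtype"], references={"subtype": "C2"})
    cox_multi = _stage("survival")(cox_fit)(
        rec,
        ["age", "site", "stage_group", "subtype"],
        references={"site": "dCCA", "stage_group": "early", "subtype": "C2"},
    )
    pd.concat(
        [cox_uni.assign(model="univariate"), cox_multi.assign(model="multivariate")]
    ).to_csv(outdir / "cox.csv", index=False)
    row = cox_multi[cox_multi["term"] == "subtype[C1]"].iloc[0]
    summary["subtype_hr_multivariate"] = {
        "hr": float(row["hr"]),
        "ci": [float(row["ci_low"]), float(row["ci_high"])],
        "p": float(row["p"]),
    }
    horizons = [y * DAYS_PER_YEAR for y in config.survival.roc_years]
    auc = _stage("survival")(time_dependent_auc)(rec, rec["core37"], horizons)
    summary["auc_years"] = {
        str(y): (None if np.isnan(a) else round(a, 4))
        for y, a in zip(config.survival.roc_years, auc.values())
    }
    std = _stage("survival")(cox_fit)(rec, ["age", "stage_group"], references={"stage_group": "early"})
    new = _stage("survival")(cox_fit)(rec, ["age", "core37"])
    nri = _stage("survival")(nri_compare)(
        rec,
        std.attrs["linear_predictor"],
        new.attrs["linear_predictor"],
        horizon=config.survival.nri_horizon_days,
    )
    summary["nri_vs_stage"] = {k: v for k, v in nri.items() if k != "horizon"}
    summary["nri_horizon_days"] = config.survival.nri_horizon_days

    config.to_yaml(outdir / "run_config.yaml")
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
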