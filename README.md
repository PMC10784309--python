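# ccacore

Anatomy-independent molecular subtyping and prognostic scoring for
cholangiocarcinoma (CCA) bulk transcriptomes.

CCA is conventionally classified by anatomical site (intrahepatic iCCA,
perihilar pCCA, distal dCCA), but surgical specimens — especially dCCA — often
carry substantial normal-tissue contamination (liver, pancreas, duodenum,
lymph node, nerve), which confounds transcriptome-based class discovery.
`ccacore` implements a contamination-aware subtyping pipeline for
gene-by-sample TPM matrices, for computational oncologists who want to apply
or re-derive an anatomy-independent two-class scheme and its derived
prognostic score on their own cohorts:

1. **Cohort purification.** Each sample is scored by nearest-template
   prediction (NTP) against liver- and pancreas-specific marker templates.
   Samples with NTP FDR ≤ 0.1 *and* a pathologist-estimated overall
   contamination fraction > 25% are set aside as a *verification* cohort; the
   rest form the *purified* cohort used for discovery.
2. **Class discovery.** Consensus clustering (subsampled average-linkage
   clustering aggregated into a consensus matrix, number of classes chosen by
   minimum PAC) on the purified cohort yields two subtypes: a
   mesenchymal/immunosuppressive class (C1) and a metabolic/proliferative
   class (C2). Brunet KL-NMF with cophenetic rank selection and UPGMA
   dendrograms are provided for the exploratory analyses.
3. **Subtype classifier.** Per-gene signal-to-noise ratios
   SNR = (μ₁ − μ₂)/(σ₁ + σ₂) rank class markers; the top 20 (C1) + 10 (C2)
   genes form templates for NTP with a permutation null
   p = (1 + #{random gene sets at least as close})/(n_perm + 1) and BH FDR
   across samples.
4. **Prognostic score.** Rank-sum differential expression between subtypes
   (adj. p ≤ 0.01, |FC| ≥ 2, C2 as reference) yields a 25-gene C1-like and a
   12-gene C2-like signature. Each is scored per sample with a rank-based
   single-sample score (mean signature-gene rank, centered and rescaled to
   [−0.5, 0.5]); the unified score = C1-like − C2-like ∈ [−1, 1] increases
   with C1-likeness and hence with hazard.
5. **Survival evaluation.** Kaplan–Meier/log-rank, univariate/multivariate
   Cox (Efron ties), IPCW cumulative/dynamic AUC(t) at 1–4 years, and the
   continuous net reclassification improvement against an age + stage model.

A synthetic-cohort generator (`ccacore.synth_cohort`) reproduces the
statistical structure all of this assumes — two latent expression programs,
site-correlated liver/pancreas contamination as convex TPM mixing, and
proportional-hazards survival with true subtype HR = 2 — so the whole
pipeline is exercisable and testable without any data download.

## Worked example

Simulate a 200-sample cohort and run every stage:

```sh
ccacore --seed 3 --outdir demo simulate --n-samples 200
printf 'cluster:\n  reps: 500\nclassifier:\n  n_perm: 500\n' > demo_cfg.yaml
ccacore --config demo_cfg.yaml --seed 3 --outdir demo run-all \
    demo/expression.tsv demo/clinical.csv demo/tissue_templates.gmt
```

which prints (abridged):

```json
{
  "purified_n": 133,
  "verification_n": 67,
  "chosen_k": 2,
  "class_proportions": {"C1": 0.3609, "C2": 0.6391},
  "confident_fraction": 0.8647,
  "resubstitution_precision": 1.0,
  "signature_sizes": [25, 12],
  "km": {"medians": {"C1": 222.0, "C2": 610.0}, "logrank_p": 0.000229},
  "subtype_hr_multivariate": {"hr": 2.36, "ci": [1.46, 3.80], "p": 0.00042},
  "auc_years": {"1": 0.6966, "2": 0.674, "3": 0.7429, "4": 0.729},
  "nri_vs_stage": {"nri": 0.6293}
}
```

Reading this: 67 of 200 samples were routed to the verification cohort by the
contamination rule; consensus clustering on the remaining 133 chose two
classes with a ~36/64 split; the 30-gene classifier called 86% of purified
samples confidently and every confident call matched the discovery label; the
differential-expression step produced the 25 + 12 gene signatures; C1
patients die markedly earlier (median 222 vs 610 days, subtype HR 2.4 after
adjusting for age, site and stage — the generator's true HR is 2); and the
unified score discriminates survival at 1–4 years (AUC ≈ 0.67–0.74) and
reclassifies better than the age + stage model (NRI > 0).

Per-stage outputs (`purify.csv`, `cluster_labels.csv`, `classifier_calls.csv`,
`core37_scores.csv`, `cox.csv`, `run_summary.json`) land in the output
directory. The same operations are importable from Python
(`ccacore.ntp_predict`, `ccacore.core37_score`, ...), and any published
signature or template can be supplied as a GMT file to score external
cohorts.

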