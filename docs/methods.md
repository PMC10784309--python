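# Methods

This note documents the statistical procedures implemented in `ccacore`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic cohort generator does and does not emulate.

## Data model

Everything operates on a gene-by-sample TPM matrix (`ExpressionMatrix`).
Two scales are tracked explicitly: raw TPM (column sums 10⁶) and
log2(TPM+1). Clustering, ssGSEA, SNR, NTP, differential expression and the
rank-based scores all work on log2(TPM+1); NMF requires non-negative input
and works on raw TPM. Re-applying the log transform is an error rather than a
silent no-op. Gene symbols are case-sensitive; duplicate rows on input are
collapsed to the row with the highest mean expression (deterministic and the
common convention for probe/transcript collapse).

The clinical table is a plain DataFrame with a fixed column contract
including per-tissue contamination fractions (hepatic, pancreatic, duodenal,
lymphatic, neural). When the overall contamination fraction is absent it is
computed as the sum of the per-tissue fractions capped at 1 — contamination
areas on a slide are disjoint, so areas add.

## Cohort purification

Normal-tissue contamination is detected two ways and both must fire:

* **Expression evidence.** NTP of each sample against liver-specific and
  pancreas-specific marker templates (the two dominant contaminants). BH FDR
  is computed across all samples of one run — a cohort-level reading of the
  false-discovery control; per-template FDR is not used.
* **Histology evidence.** The pathologist-estimated overall contamination
  fraction.

A sample joins the verification cohort iff NTP FDR ≤ 0.1 (inclusive) and
contamination > 0.25 (strict). The split is a partition by construction, and
verification membership is monotone in both thresholds.

## Nearest-template prediction

For a template set with classes k = 1..K (marker lists disjoint), expression
is restricted to the union of template genes present in the matrix (≥ 5 per
class required) and z-scored within sample. The distance to class k is the
correlation-type distance: cosine between the centered profile and the
*centered* indicator of the class-k markers, equivalently 1 − Pearson r with
the raw indicator, in [0, 2]. A sample expressing exactly the class-k markers
(two-valued profile) attains distance 0. Ties go to the lexicographically
first class and are flagged ambiguous.

Significance: n_perm (default 1000) random draws of gene sets of the same
sizes from the full gene universe of the input matrix;
p = (1 + #{draws whose *minimum* distance over all class templates ≤ observed
nearest distance}) / (n_perm + 1). Taking the minimum over classes in the
null mirrors the observed statistic (which is also a minimum), so the nominal
p is uniform on i.i.d. null data — the calibration the test suite asserts.
BH FDR is across samples; a call is "confident" at FDR ≤ 0.05. The 0.05
default is an assumption (the confidence cutoff behind published
high-confidence call rates is not standardized) and is config-exposed.

## Class discovery

**Consensus clustering.** Per repetition, 80% of samples are drawn without
replacement and clustered by average linkage on 1 − Pearson correlation
(k-means available as an alternative inner algorithm); one linkage per
subsample is cut at every k (2–5 by default, 1000 repetitions). The consensus
matrix is co-clustered count / co-sampled count; final labels come from
average-linkage clustering of 1 − M. The number of classes minimizes PAC
(fraction of off-diagonal consensus entries strictly inside (0.1, 0.9)); the
CDF area per k is reported alongside. Genes are pre-filtered to the top 2000
by median absolute deviation (config-overridable) — a standard variance
filter that also keeps desk-scale runtimes.

**NMF.** Brunet multiplicative updates minimizing the KL divergence
D(V‖WH), 30 runs per rank over ranks 2–6, each run's objective asserted
non-increasing per iteration. Rank selection maximizes the cophenetic
correlation of the run-consensus matrix (a perfectly stable consensus has
zero dispersion and is treated as cophenetic 1); labels are the argmax
coefficient of the lowest-objective run.

**Dendrogram.** UPGMA on Euclidean distances; samples are pre-sorted by ID so
leaf order is deterministic; Newick export included.

In the orchestrated pipeline the two consensus classes are named by size —
the minority class is C1 (mesenchymal/immunosuppressive-like), matching the
expected ~35/65 split.

## Single-sample scoring

**ssGSEA.** Per sample, genes get ascending ranks (ties averaged). Walking
the list in decreasing-rank order (rank ties broken by gene symbol for
determinism), the score is Σᵢ (Pin(i) − Pout(i)) where Pin weights in-set
genes by rank^α (α = 0.75) and Pout is the unweighted out-of-set ECDF.
Optional normalization divides all scores by (max − min) over every sample
and set. Scores are rank-statistics, hence invariant to strictly monotone
per-sample transforms; the implementation is checked against a brute-force
enumeration on all instances with ≤ 8 genes.

**Combined z.** Per-gene z across samples (sd with ddof 1, zero-variance
genes dropped with a warning); sample score = Σz/√k. Used for
ferroptosis-style signatures.

**singscore.** For an up-set of size m among n genes, the score is
(mean rank − (n+1)/2)/(n − m), spanning exactly [−0.5, +0.5]; down-sets are
scored on reversed ranks; up and down scores add.

**Unified prognostic score.** The C1-like signature (up to 25 genes up in
C1) and C2-like signature (up to 12 genes up in C2) come from per-gene
two-sided rank-sum tests on log2(TPM+1) with BH correction, thresholds
adj. p ≤ 0.01 and |FC| ≥ 2 against the C2 reference. (The alternative
thresholds 0.1/1 seen in some descriptions of this procedure are reachable
via config; the defaults are the ones tied to the 25/12 signature sizes. A
count-model DE backend is left as a pluggable slot — this package's data
model starts at TPM, where a rank test is the defensible default.) The
unified score is singscore(C1-like) − singscore(C2-like) ∈ [−1, 1]; the C2
sign flip makes the score increase with C1-likeness. Quartiles are assigned
within the scored cohort by score order with group sizes differing by ≤ 1;
Q4 is the most C1-like (highest risk).

## Survival analysis

Patients who died of causes unrelated to the cancer are excluded before any
estimator, as are zero-day follow-ups. KM/log-rank and Cox (Efron tie
handling, Wald CIs) are delegated to lifelines; categorical covariates expand
against explicit reference levels (dCCA, early stage, C2). Stage enters as
the two-level early/late grouping.

Time-dependent discrimination is the IPCW cumulative-case/dynamic-control
AUC(t): cases are events by t weighted by 1/Ĝ(T⁻) with Ĝ the KM of the
censoring distribution, controls are samples still at risk after t, risk
ties count ½. This matches Uno-type weighting and is verified against an
independent implementation and a hand-computed example.

The continuous NRI at a horizon (default 2 years, config-exposed) classifies
pairs by risk movement (new > standard = up); event probabilities by the
horizon within the up/down groups come from KM curves, which handles
censoring before the horizon and reduces to plain counting when follow-up is
complete. NRI = event component + non-event component and is antisymmetric
under model swap.

## Synthetic cohort generator

The generator emulates exactly the structure the pipeline assumes, with
defaults fixed to the study-like conditions: n = 200 samples, subtype
proportions 0.35/0.65, 2000 genes, two 60-gene programs (the C2 program
includes a 10-gene mitochondrial-tagged block) shifted by 2.0 log2 units in
the owning class over a shared N(3, 2) log2 baseline with N(0, 0.5) noise.
Liver and pancreas reference profiles are synthetic: disjoint 50-gene marker
blocks boosted by 6 log2 units; the same blocks are exported as the NTP
tissue templates, making the purification stage self-consistent. About 40%
of samples are contaminated by convex TPM mixing with fraction U(0.3, 0.7),
with the tissue tied to the site (liver for iCCA, pancreas for dCCA, either
for pCCA) to reproduce the site–contamination confounding. Survival is
exponential with a 565-day C2 median, true subtype log-HR log 2, independent
exponential censoring (rate 7e-4/day, roughly a third censored) and a 5%
independent unrelated-death rate to exercise the exclusion rule. Pathologist
contamination fractions equal the true mixing fractions (no estimation
noise), plus small unrelated lymphatic fractions on 20% of samples.

What the generator does **not** emulate: negative-binomial count noise and
library-size effects (the downstream methods are rank-based, so log-normal
TPM suffices), gene–gene correlation beyond the program blocks, batch
effects, intra-tumoral heterogeneity, and informative censoring. Passing
tests therefore demonstrate correctness of the machinery and recoverability
under the stated generative model, not performance on real FFPE RNA-seq.

## Numerical choices and degenerate inputs

* SNR denominators are floored at max(σ, 0.2·|μ|, 10⁻⁶) per class, so
  constant genes stay finite (and score 0 when means are equal).
* All-constant NTP profiles have zero z-norm and are assigned distance 1 to
  every template (maximally ambiguous) rather than NaN.
* Rank-sum p-values of genes constant across both classes are defined as 1.
* Consensus entries with zero co-sampling count (possible only at very low
  repetition counts) are treated as 0.
* The KL-NMF objective is allowed a 10⁻⁹ relative tolerance in the
  monotonicity assertion to absorb floating-point rounding.
* Seeds: every stochastic operation takes an explicit seed; the pipeline
  derives per-stage seeds from the master seed by fixed offsets, so repeated
  runs are byte-identical.

## Problem sizes used by the test suite and acceptance script

The suite runs the full default-condition cohort (n = 200, 2000 genes,
1000 consensus repetitions, 1000 NTP permutations) for the recovery checks,
a 2000-gene × 100-sample null matrix for permutation calibration, 50
simulations of n = 150 for Cox CI coverage, and exhaustive scoring-oracle
enumeration up to 8 genes; smaller fixtures cover the unit-level contracts.
These sizes were chosen as the smallest at which the statistical guarantees
(binomial tolerances, ARI, CI coverage) are meaningfully testable.
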