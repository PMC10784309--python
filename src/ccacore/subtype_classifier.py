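"""Nearest-template subtype classifier.

The classifier is built in three steps: per-gene signal-to-noise ratio (SNR)
scoring against a two-class labelling, selection of the top class markers
(default 20 for the mesenchymal/immunosuppressive class and 10 for the
metabolic/proliferative class), and nearest-template prediction (NTP) with a
permutation null for call confidence.

NTP works on the within-sample z-scored template-gene profile: the distance of
a sample to class *k* is the cosine distance to the indicator vector of the
class-*k* markers, and significance comes from random gene sets of the same
sizes drawn from the full gene universe.  The nominal p-value compares the
observed nearest-template distance with the minimum distance over all class
templates in each random draw, which keeps the null calibrated when more than
one template competes.  FDR is Benjamini-Hochberg across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohortio import ExpressionMatrix, GeneSetCollection

__all__ = ["SNRTable", "TemplateSet", "NTPResult", "snr_scores", "select_classifier_genes", "ntp_predict"]

_EPS = 1e-6


@dataclass
class SNRTable:
    """Per-gene signed SNR with the two class names it was computed against."""

    table: pd.DataFrame  # index gene; columns snr, rank_a, rank_b
    class_a: str
    class_b: str


@dataclass
class TemplateSet:
    """Class label -> marker gene list; lists must be disjoint and non-empty."""

    classes: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, genes in self.classes.items():
            if not genes:
                raise ValueError(f"template {name!r} is empty")
            dup = seen & set(genes)
            if dup:
                raise ValueError(f"marker lists not disjoint: {sorted(dup)[:5]}")
            seen |= set(genes)

    def to_collection(self) -> GeneSetCollection:
        return GeneSetCollection({k: list(v) for k, v in self.classes.items()})

    @classmethod
    def from_collection(cls, coll: GeneSetCollection) -> "TemplateSet":
        return cls({name: list(coll[name]) for name in coll.names()})


@dataclass
class NTPResult:
    """Per-sample NTP calls: predicted class, distances, permutation p, BH FDR."""

    table: pd.DataFrame  # index sample_id
    classes: list[str] = field(default_factory=list)

    def predicted(self) -> pd.Series:
        return self.table["predicted"]

    def confident(self) -> pd.Series:
        return self.table["confident"]


def snr_scores(expr: ExpressionMatrix, labels: pd.Series, sigma_floor: float = 0.2) -> SNRTable:
    """Signed signal-to-noise ratio per gene between two classes.

    snr = (mu_A - mu_B) / (sigma_A + sigma_B) on the log2(TPM+1) scale, with
    each sigma floored at max(sigma, sigma_floor*|mu|, eps) so constant genes
    stay finite.  Class A is the lexicographically first label.
    """
    if expr.scale != "log2p1":
        raise ValueError("snr_scores expects log2(TPM+1) input")
    labels = labels.reindex(expr.samples)
    classes = sorted(labels.dropna().unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    a, b = classes
    na, nb = int((labels == a).sum()), int((labels == b).sum())
    if na < 3 or nb < 3:
        raise ValueError(f"each class needs >=3 samples (got {a}:{na}, {b}:{nb})")
    X = expr.data.values
    ia = (labels == a).values
    ib = (labels == b).values
    mu_a, mu_b = X[:, ia].mean(axis=1), X[:, ib].mean(axis=1)
    sd_a, sd_b = X[:, ia].std(axis=1, ddof=1), X[:, ib].std(axis=1, ddof=1)
    sd_a = np.maximum.reduce([sd_a, sigma_floor * np.abs(mu_a), np.full_like(sd_a, _EPS)])
    sd_b = np.maximum.reduce([sd_b, sigma_floor * np.abs(mu_b), np.full_like(sd_b, _EPS)])
    snr = (mu_a - mu_b) / (sd_a + sd_b)
    tbl = pd.DataFrame({"snr": snr, "gene": [str(g) for g in expr.genes]}, index=expr.genes)
    # rank 1 = strongest marker for the given class direction; ties by symbol
    order_a = tbl.sort_values(["snr", "gene"], ascending=[False, True]).index
    tbl["rank_a"] = pd.Series(np.arange(1, len(tbl) + 1), index=order_a)
    order_b = tbl.sort_values(["snr", "gene"], ascending=[True, True]).index
    tbl["rank_b"] = pd.Series(np.arange(1, len(tbl) + 1), index=order_b)
    tbl = tbl.drop(columns="gene")
    return SNRTable(tbl, class_a=str(a), class_b=str(b))


def select_classifier_genes(snr: SNRTable, n_per_class: tuple[int, int] = (20, 10)) -> TemplateSet:
    """Top-n marker panels per class direction by |snr|, ties broken by symbol."""
    n_a, n_b = n_per_class
    if n_a < 0 or n_b < 0:
        raise ValueError("n_per_class must be non-negative")
    tbl = snr.table
    if n_a + n_b > len(tbl):
        raise ValueError(f"requested {n_a}+{n_b} genes but only {len(tbl)} available")
    by_sym = tbl.assign(gene=tbl.index.astype(str))
    up = by_sym.sort_values(["snr", "gene"], ascending=[False, True]).index[:n_a]
    down = by_sym.sort_values(["snr", "gene"], ascending=[True, True]).index[:n_b]
    classes: dict[str, list[str]] = {}
    if n_a:
        classes[snr.class_a] = list(up)
    if n_b:
        classes[snr.class_b] = list(down)
    ts = TemplateSet.__new__(TemplateSet)  # allow empty when (0,0)
    ts.classes = classes
    if classes:
        TemplateSet.__post_init__(ts)
    return ts


def _zscore_rows(a: np.ndarray) -> np.ndarray:
    mu = a.mean(axis=-1, keepdims=True)
    sd = a.std(axis=-1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - mu) / sd


def _cosine_to_blocks(z: np.ndarray, blocks: list[np.ndarray]) -> np.ndarray:
    """Correlation-type distances of z-profiles (..., M) to block indicators.

    z is centered (within-sample z-scores), so cosine against the *centered*
    indicator equals 1 - Pearson correlation with the raw indicator; a sample
    expressing exactly the class-k markers scores distance 0.  Degenerate
    all-constant profiles (z = 0) get distance 1 to every template.
    """
    M = z.shape[-1]
    norm = np.linalg.norm(z, axis=-1)
    norm = np.where(norm == 0, 1.0, norm)
    out = []
    for idx in blocks:
        m = len(idx)
        ind_norm = np.sqrt(m * (M - m) / M)  # ||centered indicator||
        sim = z[..., idx].sum(axis=-1) / (norm * ind_norm)
        out.append(1.0 - sim)
    return np.stack(out, axis=-1)  # (..., n_classes)


def ntp_predict(
    expr: ExpressionMatrix,
    templates: TemplateSet,
    n_perm: int = 1000,
    seed: int = 0,
    confident_call_fdr: float = 0.05,
    min_overlap: int = 5,
) -> NTPResult:
    """Nearest-template prediction with permutation confidence.

    Per sample, expression is restricted to the union of template genes
    present in the matrix and z-scored within sample; the predicted class is
    the template at minimum cosine distance (tie -> lexicographically first
    class, flagged ambiguous).  p = (1 + #{random same-size gene-set draws
    whose minimum template distance <= observed}) / (n_perm + 1); BH FDR is
    across samples; a call is confident iff FDR <= ``confident_call_fdr``.
    """
    if expr.scale != "log2p1":
        raise ValueError("ntp_predict expects log2(TPM+1) input")
    classes = sorted(templates.classes)
    if len(classes) < 2:
        raise ValueError("need at least two class templates")
    gene_index = {g: i for i, g in enumerate(expr.genes)}
    kept: dict[str, list[str]] = {}
    for c in classes:
        present = [g for g in templates.classes[c] if g in gene_index]
        if len(present) < min_overlap:
            missing = [g for g in templates.classes[c] if g not in gene_index]
            raise ValueError(
                f"template {c!r} has {len(present)} genes in matrix "
                f"(need >= {min_overlap}); missing: {missing[:10]}"
            )
        kept[c] = present
    union = [g for c in classes for g in kept[c]]
    sizes = [len(kept[c]) for c in classes]
    starts = np.cumsum([0] + sizes)
    blocks = [np.arange(starts[i], starts[i + 1]) for i in range(len(classes))]

    X = expr.data.values.T  # samples x genes
    sub = X[:, [gene_index[g] for g in union]]
    z = _zscore_rows(sub)
    d_obs = _cosine_to_blocks(z, blocks)  # samples x classes
    pred_idx = np.argmin(d_obs, axis=1)  # argmin -> first index on ties (classes sorted)
    d_min = d_obs[np.arange(len(d_obs)), pred_idx]
    ambiguous = (np.abs(d_obs - d_min[:, None]) < 1e-12).sum(axis=1) > 1

    # permutation null: same-size random gene sets from the whole matrix universe
    rng = np.random.default_rng(seed)
    G, M = len(expr.genes), len(union)
    draws = np.argpartition(rng.random((n_perm, G)), M - 1, axis=1)[:, :M]
    n_samples = X.shape[0]
    counts = np.zeros(n_samples, dtype=int)
    chunk = max(1, int(2e7 // (n_perm * M)))  # cap working memory
    for s0 in range(0, n_samples, chunk):
        xs = X[s0 : s0 + chunk]  # (c, G)
        null = xs[:, draws]  # (c, n_perm, M)
        zn = _zscore_rows(null)
        d_null = _cosine_to_blocks(zn, blocks).min(axis=-1)  # (c, n_perm)
        counts[s0 : s0 + chunk] = (d_null <= d_min[s0 : s0 + chunk, None]).sum(axis=1)
    p = (1.0 + counts) / (n_perm + 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]

    tbl = pd.DataFrame(index=pd.Index(expr.samples, name="sample_id"))
    tbl["predicted"] = [classes[i] for i in pred_idx]
    for i, c in enumerate(classes):
        tbl[f"dist_{c}"] = d_obs[:, i]
    tbl["distance"] = d_min
    tbl["p"] = p
    tbl["fdr"] = fdr
    tbl["confident"] = fdr <= confident_call_fdr
    tbl["ambiguous"] = ambiguous
    return NTPResult(tbl, classes=classes)
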