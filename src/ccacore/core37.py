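"""Subtype-derived prognostic signature and the unified CORE-37-style score.

The signature comes from differential expression between the two molecular
classes (metabolic/proliferative class as reference): genes passing the
adjusted-p and fold-change thresholds split by direction into a C1-like and a
C2-like list (published sizes 25 and 12).  Each list is scored per sample with
a rank-based single-sample score (singscore): the mean normalized rank of the
signature genes, centered and rescaled so the attainable range is exactly
[-0.5, +0.5].  The unified score is the C1-like score minus the C2-like score
(the C2 sign is flipped), so it lies in [-1, 1] and increases with
C1-likeness; quartiles are taken within the scored cohort with Q4 the most
C1-like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .cohortio import ExpressionMatrix, GeneSetCollection

__all__ = [
    "DEResult",
    "Core37Signature",
    "differential_expression",
    "build_signatures",
    "singscore",
    "core37_score",
]


@dataclass
class DEResult:
    """Per-gene log2 fold change (class A vs reference B), raw and BH-adjusted p."""

    table: pd.DataFrame  # index gene: log2fc, p, adj_p
    class_a: str
    class_b: str  # reference


@dataclass
class Core37Signature:
    c1_like: list[str]
    c2_like: list[str]

    def __post_init__(self) -> None:
        if not self.c1_like or not self.c2_like:
            raise ValueError("signature lists must be non-empty")
        if set(self.c1_like) & set(self.c2_like):
            raise ValueError("signature lists must be disjoint")

    def to_collection(self) -> GeneSetCollection:
        return GeneSetCollection(
            {"c1_like": list(self.c1_like), "c2_like": list(self.c2_like)},
            {"c1_like": "up", "c2_like": "down"},
        )


def differential_expression(
    expr: ExpressionMatrix,
    labels: pd.Series,
    reference: str | None = None,
    method: str = "ranksum",
) -> DEResult:
    """Per-gene differential expression between two classes.

    Default: two-sided Wilcoxon rank-sum test per gene on the log2(TPM+1)
    scale with BH correction; log2fc is the mean log2p1 difference of the
    non-reference class minus the reference.  ``reference`` defaults to the
    lexicographically last class.  (A count-model backend could be slotted in
    via ``method``; only ``"ranksum"`` is implemented.)
    """
    if method != "ranksum":
        raise ValueError(f"unknown DE method {method!r}")
    if expr.scale != "log2p1":
        raise ValueError("differential_expression expects log2(TPM+1) input")
    labels = labels.reindex(expr.samples)
    classes = sorted(labels.dropna().unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if reference is None:
        reference = classes[1]
    if reference not in classes:
        raise ValueError(f"reference {reference!r} not among classes {classes}")
    a = [c for c in classes if c != reference][0]
    ia = (labels == a).values
    ib = (labels == reference).values
    if ia.sum() < 3 or ib.sum() < 3:
        raise ValueError("each class needs >= 3 samples")
    X = expr.data.values
    A, B = X[:, ia], X[:, ib]
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    p = np.ones(X.shape[0])
    used = np.hstack([A, B])
    varies = used.max(axis=1) > used.min(axis=1)  # constant genes: p = 1 by convention
    if varies.any():
        res = mannwhitneyu(A[varies], B[varies], axis=1, alternative="two-sided")
        p[varies] = res.pvalue
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    adj = multipletests(p, method="fdr_bh")[1]
    tbl = pd.DataFrame({"log2fc": log2fc, "p": p, "adj_p": adj}, index=expr.genes)
    return DEResult(tbl, class_a=str(a), class_b=str(reference))


def build_signatures(
    de: DEResult,
    adj_p_max: float = 0.01,
    abs_fc_min: float = 2.0,
    max_per_class: tuple[int, int] = (25, 12),
) -> Core37Signature:
    """Split DE genes passing the thresholds into C1-like / C2-like lists.

    A gene passes when adj_p <= adj_p_max and |fold change| >= abs_fc_min
    (fold change = 2^log2fc); passing genes are ranked by |log2fc| and each
    direction truncated to ``max_per_class``.
    """
    if not 0 < adj_p_max <= 1 or abs_fc_min < 1:
        raise ValueError("invalid thresholds")
    tbl = de.table
    passing = tbl[(tbl["adj_p"] <= adj_p_max) & (tbl["log2fc"].abs() >= np.log2(abs_fc_min))]
    up = passing[passing["log2fc"] > 0].sort_values(
        ["log2fc"], ascending=False, kind="stable"
    )
    down = passing[passing["log2fc"] < 0].sort_values(
        ["log2fc"], ascending=True, kind="stable"
    )
    if up.empty or down.empty:
        raise ValueError(
            f"no genes pass thresholds in some direction (up: {len(up)}, down: {len(down)})"
        )
    n1, n2 = max_per_class
    return Core37Signature(list(up.index[:n1]), list(down.index[:n2]))


def singscore(
    expr: ExpressionMatrix,
    up_set,
    down_set=None,
) -> pd.Series:
    """Rank-based single-sample signature score.

    Per sample, genes get ascending ranks (average ranks on ties).  For an
    up-set of size m among n genes the score is
    (mean rank - (n+1)/2) / (n - m), which spans exactly [-0.5, +0.5]; a
    down-set is scored the same way on reversed ranks, and up+down scores add.
    """
    up = [g for g in up_set if g in set(expr.genes)]
    if not up:
        raise ValueError("up_set has no genes in the matrix")
    X = expr.data.values
    n = X.shape[0]
    gene_pos = {g: i for i, g in enumerate(expr.genes)}
    up_idx = np.array([gene_pos[g] for g in up])
    scores = np.zeros(X.shape[1])
    down_idx = None
    if down_set is not None:
        down = [g for g in down_set if g in set(expr.genes)]
        if not down:
            raise ValueError("down_set has no genes in the matrix")
        down_idx = np.array([gene_pos[g] for g in down])
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j])
        scores[j] = _set_score(ranks, up_idx, n)
        if down_idx is not None:
            scores[j] += _set_score(n + 1 - ranks, down_idx, n)
    return pd.Series(scores, index=expr.samples, name="singscore")


def _set_score(ranks: np.ndarray, idx: np.ndarray, n: int) -> float:
    m = len(idx)
    if n == m:
        return 0.0
    return float((ranks[idx].mean() - (n + 1) / 2.0) / (n - m))


def core37_score(expr: ExpressionMatrix, sig: Core37Signature) -> pd.DataFrame:
    """Per-sample CORE-37-style score table.

    c1_component / c2_component are the singscores of the two lists (each in
    [-0.5, 0.5]); unified = c1 - c2 in [-1, 1] (C2 sign flipped so higher =
    more C1-like = worse prognosis); quartiles are within-cohort, Q4 highest,
    with group sizes differing by at most one.
    """
    c1 = singscore(expr, sig.c1_like)
    c2 = singscore(expr, sig.c2_like)
    unified = c1 - c2
    order = np.lexsort((np.array(expr.samples, dtype=object), unified.values))
    quart = np.empty(len(order), dtype=object)
    for qi, chunk in enumerate(np.array_split(order, 4), start=1):
        quart[chunk] = f"Q{qi}"
    return pd.DataFrame(
        {
            "c1_component": c1,
            "c2_component": c2,
            "core37": unified,
            "quartile": pd.Series(quart, index=c1.index),
        }
    )
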