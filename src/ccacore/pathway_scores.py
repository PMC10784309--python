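"""Single-sample gene-set scoring: ssGSEA, combined z-scores, stromal/immune.

ssGSEA is the rank-weighted ECDF-difference statistic: per sample, genes are
ranked by expression (average ranks on ties); walking down the
descending-ranked list, the enrichment score is the running sum of
(weighted in-set ECDF - out-of-set ECDF) steps with weight rank^alpha.
Scores depend only on within-sample ranks, so they are invariant to strictly
monotone per-sample transforms of expression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohortio import ExpressionMatrix, GeneSetCollection

__all__ = ["ssgsea_score", "zscore_combine", "microenv_scores"]


def _ssgsea_sample(ranks: np.ndarray, order: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Enrichment score for one sample.

    ranks: per-gene expression ranks (ascending, ties averaged);
    order: gene indices sorted by decreasing rank; in_set: boolean mask.
    """
    inset_ord = in_set[order]
    w = ranks[order] ** alpha
    w_in = np.where(inset_ord, w, 0.0)
    denom_in = w_in.sum()
    n_out = (~inset_ord).sum()
    p_in = np.cumsum(w_in) / denom_in
    p_out = np.cumsum(~inset_ord) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.75,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA scores, samples x signatures.

    ``normalize`` divides all scores by (max - min) over every sample and set,
    the cross-sample normalization of the standard ssGSEA definition.  A set
    with zero overlap with the matrix is an error; partial overlap is allowed.
    """
    if expr.scale != "log2p1":
        raise ValueError("ssgsea_score expects log2(TPM+1) input")
    genes = np.array([str(g) for g in expr.genes])
    masks = {}
    for name in sets.names():
        mask = np.isin(genes, np.array(sets[name], dtype=object))
        if not mask.any():
            raise ValueError(f"gene set {name!r} has no genes in the matrix")
        if mask.all():
            raise ValueError(f"gene set {name!r} covers the whole matrix")
        masks[name] = mask
    X = expr.data.values
    n_genes, n_samples = X.shape
    out = np.zeros((n_samples, len(masks)))
    sym_order = np.argsort(genes, kind="stable")  # tie-break ranks by symbol
    for j in range(n_samples):
        ranks = rankdata(X[:, j])
        # sort by decreasing rank, ties by gene symbol for determinism
        key = np.lexsort((np.argsort(sym_order), -ranks))
        for i, name in enumerate(masks):
            out[j, i] = _ssgsea_sample(ranks, key, masks[name], alpha)
    table = pd.DataFrame(out, index=expr.samples, columns=list(masks))
    if normalize:
        span = table.values.max() - table.values.min()
        if span > 0:
            table = table / span
    return table


def zscore_combine(expr: ExpressionMatrix, gene_set) -> pd.Series:
    """Combined-z score: per-gene z across samples, summed over the set / sqrt(k).

    Zero-variance genes are dropped with a warning; all set genes constant is
    an error.  Requires >= 2 samples.
    """
    if expr.shape[1] < 2:
        raise ValueError("zscore_combine needs >= 2 samples")
    genes = [g for g in gene_set if g in set(expr.genes)]
    if not genes:
        raise ValueError("gene set has no genes in the matrix")
    sub = expr.data.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all set genes have zero variance")
    if (~keep).any():
        warnings.warn(f"dropped {(~keep).sum()} zero-variance genes from set", stacklevel=2)
    sub = sub.loc[keep]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)
    score = z.sum(axis=0) / np.sqrt(keep.sum())
    score.name = "zscore"
    return score


def microenv_scores(
    expr: ExpressionMatrix,
    stromal_set,
    immune_set,
    alpha: float = 0.75,
) -> pd.DataFrame:
    """Stromal/immune/combined microenvironment scores (ssGSEA-based).

    ``combined`` is the element-wise sum of the stromal and immune columns;
    normalization spans the two sets jointly so the sum stays meaningful.
    """
    coll = GeneSetCollection({"stromal": list(stromal_set), "immune": list(immune_set)})
    table = ssgsea_score(expr, coll, alpha=alpha, normalize=True)
    table["combined"] = table["stromal"] + table["immune"]
    return table
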