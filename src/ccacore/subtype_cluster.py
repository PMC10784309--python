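"""Unsupervised class discovery: consensus clustering, KL-NMF, dendrograms.

Consensus clustering follows the resampling scheme of the ConsensusClusterPlus
family: ``reps`` subsamples of the cohort are clustered, co-clustering counts
are normalized by co-sampling counts into a consensus matrix per k, and the
number of classes is chosen by minimum PAC (proportion of ambiguous consensus
entries).  NMF is the Brunet Kullback-Leibler multiplicative-update variant
with rank selection by the cophenetic correlation of the run-consensus matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .cohortio import ExpressionMatrix

__all__ = [
    "ConsensusResult",
    "NMFResult",
    "consensus_cluster",
    "nmf_cluster",
    "hierarchical_dendrogram",
    "mad_filter",
    "tree_to_newick",
]


@dataclass
class ConsensusResult:
    samples: list[str]
    consensus: dict[int, np.ndarray]  # k -> samples x samples in [0,1]
    labels: dict[int, np.ndarray]  # k -> int labels 1..k
    pac: dict[int, float]
    cdf_area: dict[int, float]
    chosen_k: int

    def labels_series(self, k: int | None = None) -> pd.Series:
        k = self.chosen_k if k is None else k
        return pd.Series(self.labels[k], index=self.samples, name=f"k{k}")


@dataclass
class NMFResult:
    ranks: list[int]
    basis: dict[int, np.ndarray]  # best-run W per rank
    coef: dict[int, np.ndarray]  # best-run H per rank
    cophenetic: dict[int, float]
    chosen_rank: int
    labels: dict[int, np.ndarray] = field(default_factory=dict)

    def labels_series(self, rank: int | None = None, samples: list[str] | None = None) -> pd.Series:
        rank = self.chosen_rank if rank is None else rank
        return pd.Series(self.labels[rank], index=samples)


def mad_filter(expr: ExpressionMatrix, n_features: int) -> ExpressionMatrix:
    """Keep the top-n genes by median absolute deviation across samples."""
    if n_features >= expr.shape[0]:
        return expr
    med = expr.data.median(axis=1)
    mad = (expr.data.sub(med, axis=0)).abs().median(axis=1)
    keep = mad.sort_values(ascending=False, kind="stable").index[:n_features]
    return expr.subset_genes(sorted(keep))


def _sample_distance(expr: ExpressionMatrix, metric: str) -> np.ndarray:
    X = expr.data.values.T  # samples x genes
    if metric == "pearson":
        d = 1.0 - np.corrcoef(X)
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist

        d = squareform(pdist(X, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def consensus_cluster(
    expr: ExpressionMatrix,
    k_range=(2, 3, 4, 5),
    reps: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    inner: str = "hierarchical",
    metric: str = "pearson",
    n_features: int = 2000,
    pac_bounds: tuple[float, float] = (0.1, 0.9),
) -> ConsensusResult:
    """Consensus clustering over subsampled cohorts.

    For each k, M(i,j) = (#runs i,j co-clustered) / (#runs i,j co-sampled);
    final labels come from average-linkage clustering of 1-M; chosen_k
    minimizes PAC (fraction of off-diagonal consensus entries strictly inside
    ``pac_bounds``).  With hierarchical inner clustering one linkage per
    subsample is cut at every k.
    """
    if expr.scale != "log2p1":
        raise ValueError("consensus_cluster expects log2(TPM+1) input")
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 for k in ks):
        raise ValueError("k_range must not contain k < 2")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must be in (0, 1]")
    n = expr.shape[1]
    if n < 2 * max(ks):
        raise ValueError(f"need >= {2 * max(ks)} samples for k up to {max(ks)}")

    expr_f = mad_filter(expr, n_features)
    D = _sample_distance(expr_f, metric)
    X = expr_f.data.values.T

    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample_frac * n)))
    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in ks}
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        ones = np.zeros(n)
        ones[idx] = 1.0
        co_sampled += np.outer(ones, ones)
        if inner == "hierarchical":
            Z = linkage(squareform(D[np.ix_(idx, idx)], checks=False), method="average")
            for k in ks:
                lab = fcluster(Z, t=k, criterion="maxclust")
                _accumulate(co_clustered[k], idx, lab)
        elif inner == "kmeans":
            for k in ks:
                lab = KMeans(n_clusters=k, n_init=3, random_state=int(rng.integers(2**31))).fit_predict(X[idx])
                _accumulate(co_clustered[k], idx, lab)
        else:
            raise ValueError(f"unknown inner algorithm {inner!r}")

    consensus: dict[int, np.ndarray] = {}
    labels: dict[int, np.ndarray] = {}
    pac: dict[int, float] = {}
    cdf_area: dict[int, float] = {}
    lo, hi = pac_bounds
    iu = np.triu_indices(n, k=1)
    for k in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(co_sampled > 0, co_clustered[k] / co_sampled, 0.0)
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 1.0)
        consensus[k] = M
        Zf = linkage(squareform(1.0 - M, checks=False), method="average")
        labels[k] = fcluster(Zf, t=k, criterion="maxclust")
        vals = M[iu]
        pac[k] = float(np.mean((vals > lo) & (vals < hi)))
        # area under the empirical CDF of consensus entries
        xs = np.sort(vals)
        cdf_area[k] = float(np.trapezoid(np.arange(1, len(xs) + 1) / len(xs), xs))
    chosen_k = min(ks, key=lambda k: (pac[k], k))
    return ConsensusResult(expr.samples, consensus, labels, pac, cdf_area, chosen_k)


def _accumulate(mat: np.ndarray, idx: np.ndarray, lab: np.ndarray) -> None:
    for c in np.unique(lab):
        members = idx[lab == c]
        mat[np.ix_(members, members)] += 1.0


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    out = np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum()
    return float(out)


def nmf_cluster(
    expr: ExpressionMatrix,
    rank_range=(2, 3, 4, 5, 6),
    n_runs: int = 30,
    max_iter: int = 200,
    tol: float = 1e-5,
    seed: int = 0,
) -> NMFResult:
    """Brunet KL-NMF with cophenetic rank selection.

    Multiplicative updates minimize D(V || WH); the objective is checked to be
    non-increasing on every run.  Per rank, run-to-run stability is summarized
    by the cophenetic correlation of the sample co-clustering consensus; the
    chosen rank maximizes it.  Labels = argmax coefficient of the best
    (lowest-objective) run.
    """
    if expr.scale != "tpm":
        raise ValueError("nmf_cluster expects non-negative TPM input")
    V = expr.data.values
    if (V < 0).any():
        raise ValueError("negative entries in matrix")
    ranks = sorted(set(int(r) for r in rank_range))
    if max(ranks) >= min(V.shape):
        raise ValueError("rank must be < min(n_genes, n_samples)")
    n = V.shape[1]
    rng = np.random.default_rng(seed)
    eps = 1e-10
    basis, coef, coph, labels = {}, {}, {}, {}
    for rank in ranks:
        best = None
        consensus = np.zeros((n, n))
        for _ in range(n_runs):
            W = rng.uniform(eps, 1.0, size=(V.shape[0], rank)) * V.mean()
            H = rng.uniform(eps, 1.0, size=(rank, n))
            prev = np.inf
            for _it in range(max_iter):
                WH = W @ H + eps
                H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], eps)
                WH = W @ H + eps
                W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], eps)
                obj = _kl_divergence(V, W @ H + eps)
                if obj > prev * (1 + 1e-9) + 1e-9:
                    raise AssertionError("KL objective increased during NMF update")
                if prev - obj < tol * max(abs(prev), 1.0):
                    prev = obj
                    break
                prev = obj
            lab = np.argmax(H, axis=0)
            consensus += (lab[:, None] == lab[None, :]).astype(float)
            if best is None or prev < best[0]:
                best = (prev, W.copy(), H.copy(), lab.copy())
        consensus /= n_runs
        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cd = cophenet(Z, squareform(dist, checks=False))[0]
        # a perfectly stable consensus has zero distances; treat as maximal
        coph[rank] = float(cd) if np.isfinite(cd) else 1.0
        basis[rank], coef[rank] = best[1], best[2]
        labels[rank] = best[3] + 1
    chosen = max(ranks, key=lambda r: (coph[r], -r))
    return NMFResult(ranks, basis, coef, coph, chosen, labels)


def hierarchical_dendrogram(expr: ExpressionMatrix):
    """UPGMA (average-linkage) tree on Euclidean distances between samples.

    Samples are pre-sorted by ID so the leaf order is deterministic.  Returns
    ``(linkage_matrix, ordered_sample_ids)``.
    """
    if expr.scale != "log2p1":
        raise ValueError("hierarchical_dendrogram expects log2(TPM+1) input")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    order = sorted(expr.samples)
    sub = expr.subset_samples(order)
    from scipy.spatial.distance import pdist

    Z = linkage(pdist(sub.data.values.T, metric="euclidean"), method="average")
    return Z, order


def tree_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix to a Newick string with branch lengths."""
    from scipy.cluster.hierarchy import to_tree

    root = to_tree(Z)

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0) if parent_height is not None else 0.0
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(root, None) + ";"
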