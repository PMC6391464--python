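"""Multivariate pattern diagnostics: PCA, t-SNE, hierarchical clustering.

These reproduce the diagnostic observations an incubation study leans on:
when one compound dominates every mixture, nearly all variance collapses
onto the first principal component (high collinearity); t-SNE separates the
dose groups more evenly, with pooled QC samples embedding near the Low
group (the pool approximates the average composition); hierarchical
clustering with per-feature z-scores discriminates blank incubations from
substrate-containing ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.manifold import TSNE

from .table import FeatureTable

__all__ = ["PcaResult", "ClusterResult", "pca", "tsne", "hclust_heatmap"]


@dataclass
class PcaResult:
    """PCA of a samples x features matrix.

    ``scores``: samples x components; ``loadings``: features x components,
    orthonormal columns; ``variance_explained``: percent per component,
    summing to 100 over all components, in decreasing order. Component signs
    are fixed by making each column's largest-magnitude loading positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.variance_explained)


def _as_matrix(data: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Samples as rows, features as columns."""
    if isinstance(data, FeatureTable):
        return data.abundance.T
    return data


def pca(data: FeatureTable | pd.DataFrame) -> PcaResult:
    """Full-rank PCA via SVD of the column-centered samples x features matrix."""
    X = _as_matrix(data)
    Xc = X.to_numpy(dtype=float) - X.to_numpy(dtype=float).mean(axis=0)
    total = (Xc ** 2).sum()
    if total <= 0:
        raise ValueError("constant matrix: PCA is undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = s ** 2 / total * 100.0
    comp = [f"PC{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(U * s, index=X.index, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=comp)
    return PcaResult(scores, loadings, var)


def tsne(data: FeatureTable | pd.DataFrame, perplexity: float = 5.0,
         seed: int = 42, n_iter: int = 1000) -> pd.DataFrame:
    """2-D t-SNE embedding, deterministic under a fixed seed (PCA init)."""
    X = _as_matrix(data)
    n = X.shape[0]
    if perplexity >= n - 1:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} samples "
            f"(must be < n_samples - 1)")
    emb = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
               init="pca", max_iter=n_iter).fit_transform(
        X.to_numpy(dtype=float))
    return pd.DataFrame(emb, index=X.index, columns=["tsne1", "tsne2"])


@dataclass
class ClusterResult:
    """Agglomerative clustering of samples and features on z-scored data."""

    zscores: pd.DataFrame          # features x samples
    sample_linkage: np.ndarray
    feature_linkage: np.ndarray
    sample_order: list[str]
    feature_order: list[str]
    dropped_features: list[str]

    def cut_samples(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.sample_linkage, n_clusters,
                                    criterion="maxclust")
        return pd.Series(labels, index=self.zscores.columns)


def hclust_heatmap(data: FeatureTable | pd.DataFrame,
                   method: str = "complete",
                   metric: str = "euclidean") -> ClusterResult:
    """Per-feature z-scoring then agglomerative clustering of samples and
    features (Euclidean distance, complete linkage by default).

    Zero-variance features cannot be z-scored and are dropped with a record
    in ``dropped_features``. Leaf ordering is the deterministic scipy
    dendrogram order.
    """
    X = _as_matrix(data)            # samples x features
    M = X.to_numpy(dtype=float).T   # features x samples
    sd = M.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = [str(f) for f, k in zip(X.columns, keep) if not k]
    M = M[keep]
    feats = [str(f) for f, k in zip(X.columns, keep) if k]
    Z = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, ddof=1, keepdims=True)
    zdf = pd.DataFrame(Z, index=feats, columns=X.index)
    sample_link = hierarchy.linkage(Z.T, method=method, metric=metric)
    feature_link = hierarchy.linkage(Z, method=method, metric=metric)
    s_order = [str(X.index[i]) for i in hierarchy.leaves_list(sample_link)]
    f_order = [feats[i] for i in hierarchy.leaves_list(feature_link)]
    return ClusterResult(zdf, sample_link, feature_link, s_order, f_order,
                         dropped)
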