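"""Correlation, PCA and hierarchical clustering of lipophilicity measures.

All three operate on standardized columns so that measures on different
scales (CHI indices vs logP units) contribute equally.  PCA is computed
on the correlation structure via singular value decomposition; cluster
analysis uses Ward linkage on Euclidean distances, with measures treated
as vectors over compounds (and compounds, symmetrically, as vectors over
measures for the heat-map's other axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "correlation_matrix",
    "PCAResult",
    "pca",
    "Dendrogram",
    "hierarchical_cluster",
    "cluster_membership",
]


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between all column pairs (diagonal 1)."""
    if len(table) < 3:
        raise ValueError("need at least 3 compounds")
    sd = table.std(axis=0, ddof=1)
    zero = sd.index[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance column: {zero[0]!r}")
    return table.corr(method="pearson")


@dataclass
class PCAResult:
    scores: pd.DataFrame          # compounds x components
    loadings: pd.DataFrame        # measures x components
    explained_variance_ratio: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """scores @ loadings.T — equals the input when all components kept."""
        return self.scores.to_numpy() @ self.loadings.to_numpy().T


def pca(table: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Principal component analysis of a standardized table.

    The input is expected to be column-standardized (see
    :func:`lipochemo.transforms.standardize_columns`), which makes this a
    PCA of the correlation matrix.  Sign convention: within each
    component the largest-magnitude loading is made positive, so outputs
    are reproducible across runs and BLAS builds.
    """
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}]")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    ev = S**2
    ratio = ev / ev.sum()
    comp = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame((U[:, :n_components] * S[:n_components]),
                          index=table.index, columns=comp)
    loadings = pd.DataFrame(Vt[:n_components].T, index=table.columns, columns=comp)
    return PCAResult(scores, loadings, ratio[:n_components])


@dataclass
class Dendrogram:
    """Ward/Euclidean agglomeration tree over ``labels``.

    ``linkage`` is the standard (n-1) x 4 merge matrix: items merged,
    merge height, cluster size.
    """

    linkage: np.ndarray
    labels: list[str]
    method: str = "ward"
    metric: str = "euclidean"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hierarchical_cluster(items: pd.DataFrame) -> Dendrogram:
    """Ward clustering of the rows of ``items`` (items x features).

    To cluster measures, pass the standardized table transposed; to
    cluster compounds, pass it as-is.
    """
    if len(items) < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = hierarchy.linkage(items.to_numpy(dtype=float), method="ward",
                          metric="euclidean")
    return Dendrogram(Z, [str(i) for i in items.index])


def cluster_membership(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cut the tree into ``k`` clusters; labels are 1..k per item."""
    n = len(dendrogram.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    labels = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=dendrogram.labels, name="cluster")
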