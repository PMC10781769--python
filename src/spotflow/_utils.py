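"""Shared numerical helpers: seeded graph clustering and z-scoring."""

from __future__ import annotations

import numpy as np

__all__ = ["zscore_columns", "knn_graph", "leiden_partition", "pca_knn_leiden"]


def zscore_columns(x: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Column-wise z-scores; constant columns map to 0."""
    x = np.asarray(x, dtype=float)
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=ddof)
    out = np.zeros_like(x)
    ok = sd > 0
    out[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return out


def knn_graph(x: np.ndarray, *, n_pcs: int = 20, k: int = 20):
    """Symmetric k-nearest-neighbor graph in (deterministic) PC space."""
    import igraph
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} observations, got {n}")
    n_comp = min(n_pcs, x.shape[1], n - 1)
    if n_comp >= 1 and x.shape[1] > n_comp:
        x = PCA(n_components=n_comp, svd_solver="full").fit_transform(x)
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(x)
    _, idx = nn.kneighbors(x)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    return igraph.Graph(n=n, edges=sorted(edges), directed=False)


def leiden_partition(graph, *, resolution: float = 0.5, seed: int = 0) -> np.ndarray:
    """Seeded Leiden modularity partition; labels renumbered by first occurrence."""
    import leidenalg

    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    remap: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


def pca_knn_leiden(
    x: np.ndarray,
    *,
    n_pcs: int = 20,
    k: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Seeded modularity clustering of rows of ``x``.

    PCA (deterministic full SVD) -> symmetric k-nearest-neighbor graph in PC
    space -> Leiden modularity optimization (RBConfiguration, seedable) at the
    given resolution.
    """
    return leiden_partition(knn_graph(x, n_pcs=n_pcs, k=k), resolution=resolution, seed=seed)
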