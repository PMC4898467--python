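"""SP pseudo-time initialization.

The progenitor mean expression vector is appended to the cells as a root
point, the joint matrix is projected by PCA (2 components by default), a
minimum spanning tree is built on the projected points with Prim's
algorithm, and each cell's initial pseudo-time is the total edge weight of
the unique tree path from the root to the cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .types import DataError, ExpressionMatrix, InitialDistribution

__all__ = ["ReducedEmbedding", "pca_embed", "mst_prim", "sp_pseudotime"]


@dataclass(frozen=True)
class ReducedEmbedding:
    """(C+1) x D projected coordinates; the last row is the appended root."""

    coordinates: np.ndarray
    root_index: int


def pca_embed(E: ExpressionMatrix, mu0, dims: int = 2, scale: bool = False) -> ReducedEmbedding:
    """Project cells plus the progenitor-mean root point to `dims` components.

    The sign of each component is fixed so that its largest-magnitude loading
    is positive, making the embedding deterministic. With ``scale`` the
    columns are standardized to unit variance first (the default operates on
    the raw log-scale values).
    """
    mu0 = np.asarray(mu0, dtype=float)
    if mu0.shape != (E.n_genes,):
        raise DataError("mu0 length must equal the gene count")
    X = np.vstack([E.values, mu0[None, :]])
    if dims > min(X.shape):
        raise DataError(f"dims={dims} exceeds min(C+1, G)")
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    if np.allclose(X.var(axis=0), 0.0):
        raise DataError("expression matrix is constant; PCA is degenerate")
    pca = PCA(n_components=dims, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(dims):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] = -coords[:, j]
    return ReducedEmbedding(coordinates=coords, root_index=X.shape[0] - 1)


def mst_prim(points) -> list[tuple[int, int, float]]:
    """Minimum spanning tree of a Euclidean point set via Prim's algorithm.

    Returns n-1 edges (i, j, weight) for n points; ties are broken by the
    smallest (i, j) index pair so the tree is deterministic. Duplicate points
    simply yield zero-weight edges.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < 2:
        raise DataError("need at least 2 points")
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    # best known connection of each outside node to the tree
    dist = np.linalg.norm(pts - pts[0], axis=1)
    parent = np.zeros(n, dtype=int)
    edges: list[tuple[int, int, float]] = []
    for _ in range(n - 1):
        masked = np.where(in_tree, np.inf, dist)
        j = int(np.argmin(masked))  # argmin takes the smallest index on ties
        i = int(parent[j])
        edges.append((min(i, j), max(i, j), float(dist[j])))
        in_tree[j] = True
        new_d = np.linalg.norm(pts - pts[j], axis=1)
        closer = new_d < dist
        dist = np.where(closer, new_d, dist)
        parent = np.where(closer, j, parent)
    return edges


def _tree_distances_from_root(edges, n: int, root: int) -> np.ndarray:
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, j, w in edges:
        adj[i].append((j, w))
        adj[j].append((i, w))
    dist = np.full(n, -1.0)
    dist[root] = 0.0
    stack = [root]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + w
                stack.append(v)
    return dist


def sp_pseudotime(E: ExpressionMatrix, init: InitialDistribution, dims: int = 2,
                  normalize: bool = True, scale: bool = False) -> np.ndarray:
    """Initial per-cell pseudo-time: shortest-path weight to the MST root.

    The root is the projected progenitor mean; in a tree the shortest path is
    the unique path, so the time is the summed edge weight along it. With
    ``normalize`` the times are divided by their maximum.
    """
    emb = pca_embed(E, init.mu0, dims=dims, scale=scale)
    edges = mst_prim(emb.coordinates)
    dist = _tree_distances_from_root(edges, emb.coordinates.shape[0], emb.root_index)
    t = np.delete(dist, emb.root_index)
    if normalize and t.max() > 0:
        t = t / t.max()
    return t
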