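"""Point-density clustering of residues in 3D.

Groups residues purely by their CA coordinates — optionally restricted
to hotspot residues — via two interchangeable back-ends: HDBSCAN
(density-based, the default) and Markov chain clustering (MCL) on a
fixed-radius contact graph.  Labels use -1 for noise/unselected
residues; clusters are numbered 0..K-1 by decreasing size (ties broken
by the lowest member residue index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Fold, ca_coords

__all__ = ["ClusterLabels", "cluster", "mcl"]


@dataclass
class ClusterLabels:
    """Per-residue integer cluster assignment; -1 = noise/unselected."""

    labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if (self.labels >= 0).any() else 0

    def __len__(self) -> int:
        return len(self.labels)


def _renumber(labels: np.ndarray) -> np.ndarray:
    """Renumber clusters by decreasing size, ties by lowest member index."""
    out = np.full(len(labels), -1, dtype=int)
    ids = [c for c in np.unique(labels) if c >= 0]
    keyed = sorted(
        ids,
        key=lambda c: (-(labels == c).sum(), int(np.flatnonzero(labels == c)[0])),
    )
    for new, old in enumerate(keyed):
        out[labels == old] = new
    return out


def _resolve_selection(fold: Fold, selection) -> np.ndarray:
    """Selection -> sorted residue-index array.

    Accepts None (all residues), a HotspotResult (its hot flags), a
    boolean/0-1 mask of length n, or an iterable of residue indices.
    """
    n = len(fold)
    if selection is None:
        return np.arange(n)
    if hasattr(selection, "hot"):
        sel = np.flatnonzero(np.asarray(selection.hot))
    else:
        arr = np.asarray(selection)
        if arr.dtype == bool or (len(arr) == n and set(np.unique(arr)) <= {0, 1}):
            sel = np.flatnonzero(arr)
        else:
            sel = np.unique(arr.astype(int))
            if len(sel) and (sel[0] < 0 or sel[-1] >= n):
                raise ValueError(f"residue index out of range 0..{n - 1}")
    if len(sel) == 0:
        raise ValueError("selection selects no residues")
    return sel


def cluster(
    fold: Fold,
    selection=None,
    method: str = "hdbscan",
    min_cluster_size: int = 5,
    allow_single_cluster: bool = True,
    mcl_inflation: float = 2.0,
    mcl_radius: float = 8.0,
    mcl_expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ClusterLabels:
    """Cluster (selected) residues on CA coordinates.

    ``selection`` may be a HotspotResult, a boolean mask, an index list,
    or None for all residues.  Residues outside the selection keep
    label -1.  ``allow_single_cluster`` (hdbscan back-end) defaults to
    True because a hotspot selection is often one compact region, which
    should come back as one cluster rather than all-noise.  Typical use
    mirrors::

        clusters = cluster(model, hotspots, min_cluster_size=5)
    """
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    sel = _resolve_selection(fold, selection)
    coords = ca_coords(fold)[sel]
    n = len(fold)
    labels = np.full(n, -1, dtype=int)
    if method == "hdbscan":
        if len(sel) < min_cluster_size:
            sub = np.full(len(sel), -1, dtype=int)  # too few points: all noise
        else:
            from sklearn.cluster import HDBSCAN

            sub = HDBSCAN(
                min_cluster_size=min_cluster_size,
                allow_single_cluster=allow_single_cluster,
                copy=True,
            ).fit_predict(coords)
        params = {"min_cluster_size": min_cluster_size}
    elif method == "mcl":
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(coords))
        adj = ((d > 0) & (d <= mcl_radius)).astype(float)
        res = mcl(adj, inflation=mcl_inflation, expansion=mcl_expansion,
                  max_iter=max_iter, tol=tol)
        sub = res.labels
        params = {
            "inflation": mcl_inflation,
            "radius": mcl_radius,
            "expansion": mcl_expansion,
            "converged": res.params["converged"],
        }
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    labels[sel] = sub
    labels = _renumber(labels)
    return ClusterLabels(labels, method, params)


def mcl(
    adjacency: np.ndarray,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-6,
) -> ClusterLabels:
    """Markov chain clustering on a symmetric nonnegative adjacency matrix.

    Algorithm: add self-loops (1.0), column-normalize, then iterate
    {matrix power ``expansion``, elementwise power ``inflation``, column
    renormalization, pruning of entries < 1e-6} until the largest column
    change falls below ``tol`` or ``max_iter`` is reached.  Clusters are
    read off the converged matrix as connected attractor sets: attractors
    are rows with nonzero mass; each node joins its first attractor (by
    index); attractors that attract one another merge.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if (A < 0).any():
        raise ValueError("adjacency must be nonnegative")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    n = A.shape[0]
    M = A.copy()
    np.fill_diagonal(M, 1.0)
    M = M / M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M**inflation
        M = M / M.sum(axis=0, keepdims=True)
        M[M < prune] = 0.0
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    # attractors: rows with remaining mass
    attractors = np.flatnonzero(M.sum(axis=1) > 0)
    # merge attractors that attract one another (connected attractor sets)
    parent = {a: a for a in attractors}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in attractors:
        for b in attractors:
            if b > a and (M[a, b] > 0 or M[b, a] > 0):
                parent[find(b)] = find(a)
    roots = sorted({find(a) for a in attractors})
    root_id = {r: i for i, r in enumerate(roots)}
    labels = np.full(n, -1, dtype=int)
    for j in range(n):
        pulled = np.flatnonzero(M[attractors, j] > 0)
        if len(pulled):
            labels[j] = root_id[find(attractors[pulled[0]])]  # first by index
    return ClusterLabels(
        _renumber(labels),
        "mcl",
        {
            "inflation": inflation,
            "expansion": expansion,
            "max_iter": max_iter,
            "tol": tol,
            "converged": converged,
        },
    )
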