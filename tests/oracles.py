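"""Independent brute-force reference implementations used as test oracles.

These deliberately mirror the closed forms with naive loops and stay
independent of the library's vectorized code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_getis(x, w, include_self: bool) -> np.ndarray:
    """Getis-Ord z by direct per-residue evaluation of the closed form."""
    x = np.asarray(x, float)
    n = len(x)
    z = np.zeros(n)
    for i in range(n):
        if include_self:
            js = list(range(n))
            xbar = sum(x) / n
            s = math.sqrt(sum((v - xbar) ** 2 for v in x) / n)
            m = n
        else:
            js = [j for j in range(n) if j != i]
            vals = [x[j] for j in js]
            m = n - 1
            xbar = sum(vals) / m
            s = math.sqrt(sum((v - xbar) ** 2 for v in vals) / m)
        Wi = sum(w[i][j] for j in js)
        S1 = sum(w[i][j] ** 2 for j in js)
        num = sum(w[i][j] * x[j] for j in js) - xbar * Wi
        den = s * math.sqrt(max(m * S1 - Wi**2, 0.0) / (m - 1))
        z[i] = num / den if den > 0 else 0.0
    return z


def naive_local_moran(x, w) -> np.ndarray:
    """Anselin local Moran by direct evaluation (self-weight zeroed)."""
    x = np.asarray(x, float)
    n = len(x)
    xbar = sum(x) / n
    m2 = sum((v - xbar) ** 2 for v in x) / n
    out = np.zeros(n)
    for i in range(n):
        acc = sum(w[i][j] * (x[j] - xbar) for j in range(n) if j != i)
        out[i] = (x[i] - xbar) / m2 * acc
    return out


def naive_global_moran(x, w) -> float:
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    w = np.asarray(w, float).copy()
    np.fill_diagonal(w, 0.0)
    num = sum(
        w[i][j] * (x[i] - xbar) * (x[j] - xbar)
        for i in range(n)
        for j in range(n)
    )
    return n / w.sum() * num / sum((v - xbar) ** 2 for v in x)


def naive_bh(p, rate):
    """Step-up BH by literal sort-and-scan."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return q, q <= rate


def exact_conditional_pvalues(x, stat_fn, alternative="greater"):
    """Exhaustive conditional-permutation p-values (tiny n only).

    For each residue i, enumerate every permutation of the remaining
    values over the remaining positions and count statistics at i that
    reach the observed one.  The identity permutation is part of the
    enumeration, so p = count/total is already never zero — it is the
    quantity the Monte-Carlo (1+c)/(1+n_perm) estimator converges to.
    """
    x = np.asarray(x, float)
    n = len(x)
    observed = stat_fn(x)
    p = np.zeros(n)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        vals = [x[j] for j in others]
        count = 0
        total = 0
        for perm in itertools.permutations(vals):
            xv = x.copy()
            for pos, v in zip(others, perm):
                xv[pos] = v
            st = stat_fn(xv)[i]
            if alternative == "greater":
                count += st >= observed[i]
            else:
                count += abs(st) >= abs(observed[i])
            total += 1
        p[i] = count / total
    return p


def brute_force_interface(cx, chain_a, chain_b, cutoff):
    """All-heavy-atom-pairs scan for interface residues of chain_a."""
    b_atoms = [
        a.coords
        for r in cx.residues
        if r.chain_id == chain_b
        for a in r.atoms
        if a.is_heavy
    ]
    hits = []
    for r in cx.residues:
        if r.chain_id != chain_a:
            continue
        dmin = min(
            float(np.linalg.norm(a.coords - bxyz))
            for a in r.atoms
            if a.is_heavy
            for bxyz in b_atoms
        )
        if dmin <= cutoff:
            hits.append(r.index)
    return np.asarray(hits)


def brute_force_sliding(coords, x, radius, agg):
    """O(n^2) double loop over CA pairs."""
    fns = {"mean": np.mean, "sum": np.sum, "max": np.max}
    coords = np.asarray(coords, float)
    x = np.asarray(x, float)
    out = []
    for i in range(len(x)):
        vals = [
            x[j]
            for j in range(len(x))
            if np.linalg.norm(coords[i] - coords[j]) <= radius
        ]
        out.append(fns[agg](vals))
    return np.asarray(out)


def reference_mcl_partition(adjacency, inflation=2.0, expansion=2,
                            max_iter=100, tol=1e-6):
    """Independent run of the same MCL update rule, reading clusters as
    connected components of the converged matrix's nonzero pattern."""
    M = np.asarray(adjacency, float).copy()
    n = M.shape[0]
    np.fill_diagonal(M, 1.0)
    M /= M.sum(axis=0)
    for _ in range(max_iter):
        prev = M.copy()
        M = np.linalg.matrix_power(M, expansion) ** inflation
        M /= M.sum(axis=0)
        M[M < 1e-6] = 0.0
        if np.abs(M - prev).max() < tol:
            break
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if M[i, j] > 0:
                g.add_edge(i, j)
    labels = np.zeros(n, int)
    for cid, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            labels[node] = cid
    return labels


def partition_sets(labels):
    """Partition as a frozenset of frozensets (noise points as singletons)."""
    labels = np.asarray(labels)
    groups = {}
    singles = []
    for i, lab in enumerate(labels):
        if lab < 0:
            singles.append(frozenset([i]))
        else:
            groups.setdefault(lab, set()).add(i)
    return frozenset(
        [frozenset(g) for g in groups.values()] + singles
    )
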