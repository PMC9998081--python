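"""Local spatial autocorrelation on protein structures.

Detects feature "hotspots" — residues whose attached feature values are
more spatially clustered than expected under random permutation of the
feature over residue positions — using the Getis-Ord G/G* family of
statistics (default) or Anselin's local Moran's I, with conditional
permutation inference and Benjamini-Hochberg FDR control.  Also provides
spatial neighbor-weight construction (fixed radius, k-nearest, distance
decay) and spherical sliding-window feature aggregation.

The Getis-Ord z-statistic at residue i is

    z_i = [ sum_j w_ij x_j  -  xbar * W_i ]
          / ( s * sqrt( (n * sum_j w_ij^2 - W_i^2) / (n - 1) ) )

with xbar and s the mean and population standard deviation of x and
W_i = sum_j w_ij.  The G* variant (self-inclusive weights) includes
j = i in all sums; the G variant excludes residue i from the sums and
from xbar, s for that residue.

The local Moran statistic is I_i = (x_i - xbar)/m2 * sum_j w_ij (x_j - xbar)
with m2 = sum_k (x_k - xbar)^2 / n and the self-weight forced to zero;
its sum over residues equals S0 * I_global.

Significance is assessed by conditional permutation: x_i stays fixed
while the remaining values are permuted over the remaining positions;
p_i = (1 + #{permutations with statistic >= observed}) / (1 + n_perm)
for the one-sided "greater" alternative, so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure import Fold, ca_coords

__all__ = [
    "SpatialWeights",
    "FeatureTrack",
    "HotspotResult",
    "build_weights",
    "getis_ord",
    "local_moran",
    "permutation_pvalues",
    "bh_fdr",
    "find_hotspots",
    "sliding_window",
]


@dataclass
class FeatureTrack:
    """A named per-residue numeric feature vector."""

    name: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def _as_values(x) -> np.ndarray:
    if isinstance(x, FeatureTrack):
        return x.values
    return np.asarray(x, dtype=float)


@dataclass
class SpatialWeights:
    """An n x n nonnegative neighbor-weight matrix over residues.

    ``binary_radius`` and ``decay`` weights are symmetric before row
    standardization; ``knn`` may be asymmetric.  The diagonal is zero
    unless ``include_self`` (the G* convention).
    """

    w: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    include_self: bool = False
    row_standardized: bool = False

    @property
    def n(self) -> int:
        return self.w.shape[0]


def build_weights(
    coords: np.ndarray,
    method: str = "binary_radius",
    *,
    radius: float = 8.0,
    k: int = 4,
    decay_scale: float = 8.0,
    include_self: bool = False,
    row_standardize: bool = False,
) -> SpatialWeights:
    """Construct residue neighbor weights from coordinates.

    binary_radius : w_ij = 1 iff 0 < d(i,j) <= radius
    knn           : w_ij = 1 iff j is among i's k nearest (ties: lower index)
    decay         : w_ij = exp(-d(i,j) / decay_scale)

    then optional self-inclusion (diagonal set to 1) and row
    standardization (each nonzero row rescaled to sum to 1).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 residues to build weights")
    d = squareform(pdist(coords))
    if method == "binary_radius":
        if radius <= 0:
            raise ValueError("radius must be positive")
        w = ((d > 0) & (d <= radius)).astype(float)
        params = {"radius": float(radius)}
        if (w.sum(axis=1) == 0).any():
            import warnings

            isolated = int((w.sum(axis=1) == 0).sum())
            warnings.warn(
                f"{isolated} residue(s) have no neighbor within {radius} A "
                "(row left all-zero)",
                stacklevel=2,
            )
    elif method == "knn":
        if not 1 <= k <= n - 1:
            raise ValueError(f"k must be in [1, {n - 1}]")
        w = np.zeros((n, n))
        idx = np.arange(n)
        for i in range(n):
            order = np.lexsort((idx, d[i]))  # distance, then lower index
            order = order[order != i][:k]
            w[i, order] = 1.0
        params = {"k": int(k)}
    elif method == "decay":
        if decay_scale <= 0:
            raise ValueError("decay_scale must be positive")
        w = np.exp(-d / decay_scale)
        np.fill_diagonal(w, 0.0)
        params = {"decay_scale": float(decay_scale)}
    else:
        raise ValueError(f"unknown weights method {method!r}")
    if include_self:
        np.fill_diagonal(w, 1.0)
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        nz = rs[:, 0] > 0
        w[nz] = w[nz] / rs[nz]
    return SpatialWeights(w, method, params, include_self, row_standardize)


def _check_feature(x: np.ndarray, n: int) -> None:
    if x.shape[0] != n:
        raise ValueError(f"feature length {x.shape[0]} != weights size {n}")
    if np.ptp(x) == 0:
        raise ValueError("feature track has zero variance; statistic undefined")


def getis_ord(x, W: SpatialWeights) -> np.ndarray:
    """Per-residue Getis-Ord z-statistic (G* if W is self-inclusive, else G)."""
    x = _as_values(x)
    w = W.w
    n = W.n
    _check_feature(x, n)
    if W.include_self:
        xbar = x.mean()
        s = x.std()  # population s.d.
        Wi = w.sum(axis=1)
        S1 = (w**2).sum(axis=1)
        num = w @ x - xbar * Wi
        den = s * np.sqrt(np.maximum(n * S1 - Wi**2, 0.0) / (n - 1))
    else:
        # G variant: residue i excluded from sums and from xbar, s
        m = n - 1
        tot, tot2 = x.sum(), (x**2).sum()
        xbar = (tot - x) / m
        s = np.sqrt(np.maximum((tot2 - x**2) / m - xbar**2, 0.0))
        wz = w.copy()
        np.fill_diagonal(wz, 0.0)
        Wi = wz.sum(axis=1)
        S1 = (wz**2).sum(axis=1)
        num = wz @ x - xbar * Wi
        den = s * np.sqrt(np.maximum(m * S1 - Wi**2, 0.0) / (m - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return z


def local_moran(x, W: SpatialWeights) -> np.ndarray:
    """Anselin-style local Moran's I per residue (self-weight forced to 0)."""
    x = _as_values(x)
    n = W.n
    _check_feature(x, n)
    w = W.w.copy()
    np.fill_diagonal(w, 0.0)
    z = x - x.mean()
    m2 = (z**2).sum() / n
    return z / m2 * (w @ z)


def global_moran(x, W: SpatialWeights) -> float:
    """Global Moran's I (internal; used by invariants and tests)."""
    x = _as_values(x)
    w = W.w.copy()
    np.fill_diagonal(w, 0.0)
    z = x - x.mean()
    s0 = w.sum()
    return len(x) / s0 * (z @ w @ z) / (z**2).sum()


def _conditional_stats(x, W, method, n_perm, rng):
    """Observed statistic + per-residue conditional permutation draws.

    Exploits the fact that under conditional permutation the feature
    multiset is unchanged, so mean/s.d./m2 are constants and only the
    weighted neighbor sum varies.  Yields (observed, sims) where sims is
    (n, n_perm).
    """
    x = _as_values(x)
    n = W.n
    if method == "getis_ord":
        observed = getis_ord(x, W)
    elif method == "moran":
        observed = local_moran(x, W)
    else:
        raise ValueError(f"unknown hotspot method {method!r}")
    sims = np.empty((n, n_perm))
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        vals = x[others]
        perms = rng.permuted(np.tile(vals, (n_perm, 1)), axis=1)
        xmat = np.empty((n_perm, n))
        xmat[:, others] = perms
        xmat[:, i] = x[i]
        if method == "getis_ord":
            if W.include_self:
                xbar, s = x.mean(), x.std()
                w_i = W.w[i]
                Wi = w_i.sum()
                den = s * np.sqrt(max(n * (w_i**2).sum() - Wi**2, 0.0) / (n - 1))
            else:
                m = n - 1
                xbar, s = vals.mean(), vals.std()
                w_i = W.w[i].copy()
                w_i[i] = 0.0
                Wi = w_i.sum()
                den = s * np.sqrt(max(m * (w_i**2).sum() - Wi**2, 0.0) / (m - 1))
            num = xmat @ w_i - xbar * Wi
            sims[i] = num / den if den > 0 else 0.0
        else:
            xbar = x.mean()
            m2 = ((x - xbar) ** 2).sum() / n
            w_i = W.w[i].copy()
            w_i[i] = 0.0
            sims[i] = (x[i] - xbar) / m2 * ((xmat - xbar) @ w_i)
    return observed, sims


def permutation_pvalues(
    x,
    W: SpatialWeights,
    method: str = "getis_ord",
    n_perm: int = 999,
    seed: int = 42,
    alternative: str = "greater",
) -> np.ndarray:
    """Conditional-permutation p-values for a local statistic.

    For residue i, x_i stays fixed and the remaining values are permuted
    over the other positions; p_i = (1 + #{stat >= observed}) / (1 + n_perm)
    for ``"greater"`` (absolute values for ``"two_sided"``).
    Deterministic under a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(seed)
    observed, sims = _conditional_stats(x, W, method, n_perm, rng)
    # tie tolerance: permuted statistics that equal the observed one up to
    # round-off count as exceedances (discrete features produce exact ties)
    tol = 1e-9 * (1.0 + np.abs(observed))
    if alternative == "greater":
        exceed = (sims >= (observed - tol)[:, None]).sum(axis=1)
    else:
        exceed = (np.abs(sims) >= (np.abs(observed) - tol)[:, None]).sum(axis=1)
    return (1.0 + exceed) / (1.0 + n_perm)


def bh_fdr(p, rate: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values and reject flags at ``rate``.

    q_(i) = min over j >= i of m * p_(j) / j, capped at 1; reject where
    q <= rate.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= rate


@dataclass
class HotspotResult:
    """Per-residue hotspot statistics.

    ``hot[i]`` requires both q_i <= fdr and a positive local statistic
    (high-value hotspot); significant cold-spots are not flagged under
    the default one-sided test.
    """

    statistic: np.ndarray
    p: np.ndarray
    q: np.ndarray
    hot: np.ndarray
    method: str
    n_perm: int
    seed: int
    fdr: float
    weights: SpatialWeights | None = None

    def __len__(self) -> int:
        return len(self.statistic)

    @property
    def hotspot_indices(self) -> np.ndarray:
        return np.flatnonzero(self.hot)


def find_hotspots(
    fold,
    x,
    false_discovery_rate: float = 0.05,
    method: str = "getis_ord",
    weights_method: str = "binary_radius",
    radius: float = 8.0,
    k: int = 4,
    decay_scale: float = 8.0,
    n_perm: int = 999,
    seed: int = 42,
    alternative: str = "greater",
) -> HotspotResult:
    """Detect feature hotspots on a structure.

    Composes CA coordinates -> neighbor weights -> local statistic ->
    conditional permutation p-values -> BH FDR.  Defaults: G* statistic
    on self-inclusive binary 8-Angstrom-radius weights, 999 permutations,
    one-sided "greater".  For Moran's I the weights are row-standardized
    without self-inclusion.

    ``fold`` may be a Fold or an n x 3 coordinate matrix; ``x`` a
    FeatureTrack, array, or 0/1 list as in::

        hotspots = find_hotspots(model, positive, false_discovery_rate=0.05)
    """
    if not 0 < false_discovery_rate < 1:
        raise ValueError("false_discovery_rate must be in (0, 1)")
    coords = ca_coords(fold) if isinstance(fold, Fold) else np.asarray(fold, float)
    if method == "getis_ord":
        include_self, row_std = True, False
    elif method == "moran":
        include_self, row_std = False, True
    else:
        raise ValueError(f"unknown hotspot method {method!r}")
    W = build_weights(
        coords,
        weights_method,
        radius=radius,
        k=k,
        decay_scale=decay_scale,
        include_self=include_self,
        row_standardize=row_std,
    )
    xv = _as_values(x)
    stat = getis_ord(xv, W) if method == "getis_ord" else local_moran(xv, W)
    p = permutation_pvalues(xv, W, method, n_perm, seed, alternative)
    q, reject = bh_fdr(p, false_discovery_rate)
    hot = reject & (stat > 0)
    return HotspotResult(
        stat, p, q, hot, method, n_perm, seed, false_discovery_rate, W
    )


def sliding_window(fold, x, radius: float, agg: str = "mean") -> FeatureTrack:
    """Aggregate a feature in a spherical window around each residue.

    output[i] = agg of x over residues whose CA lies within ``radius``
    Angstrom of residue i's CA (always including i itself).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    aggs = {"mean": np.mean, "sum": np.sum, "max": np.max}
    if agg not in aggs:
        raise ValueError(f"unknown aggregation {agg!r} (use mean, sum or max)")
    coords = ca_coords(fold) if isinstance(fold, Fold) else np.asarray(fold, float)
    xv = _as_values(x)
    if xv.shape[0] != coords.shape[0]:
        raise ValueError("feature length does not match residue count")
    d = squareform(pdist(coords))
    fn = aggs[agg]
    out = np.array([fn(xv[d[i] <= radius]) for i in range(len(xv))])
    name = x.name if isinstance(x, FeatureTrack) else "feature"
    return FeatureTrack(f"{name}_{agg}_r{radius:g}", out)
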