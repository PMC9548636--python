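"""Single-bandwidth geographically weighted regression.

At each focal unit i the model is calibrated by weighted least squares,

    beta_hat_i = (X' W_i X)^{-1} X' W_i y,

where W_i holds adaptive bi-square kernel weights: with b_i the distance to
the k-th nearest unit (self included at distance zero),

    w_ij = (1 - (d_ij / b_i)^2)^2   if d_ij < b_i,   else 0.

The bandwidth is the neighbor count k, selected by minimizing AICc with a
golden-section search over integers (exhaustive scan on small ranges).  Row
i of the hat matrix is x_i'(X'W_iX)^{-1}X'W_i, whose trace feeds AICc and
the residual-variance estimate.

Dense n x n distance matrices are used throughout; at the few thousand
units typical of county analyses this is faster and simpler than spatial
indexing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .baseline import model_aicc
from .dataset import SpatialDataset
from .exceptions import ConfigError, LocalSingularityError, OversaturatedModelError

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class KernelSpec:
    """Adaptive bi-square kernel with a neighbor-count bandwidth."""

    k_neighbors: int
    kind: str = "adaptive-bisquare"

    def validate(self, n: int, p: int) -> None:
        if self.kind != "adaptive-bisquare":
            raise ConfigError(f"unsupported kernel kind {self.kind!r}")
        if self.k_neighbors < max(2, p + 1):
            raise ConfigError(
                f"bandwidth {self.k_neighbors} too small for {p} design columns"
            )
        if self.k_neighbors > n:
            raise ConfigError(f"bandwidth {self.k_neighbors} exceeds n = {n}")


@dataclass
class GWRResult:
    names: list[str]
    params: np.ndarray        # n x (k+1) local coefficients
    se: np.ndarray            # n x (k+1)
    tvalues: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    trace_s: float
    rss: float
    aicc: float
    bandwidth: int
    local_r2: np.ndarray
    leverage: np.ndarray      # diagonal of the hat matrix
    scaling: dict | None = None

    @property
    def sigma2(self) -> float:
        n = len(self.fitted)
        return self.rss / (n - self.trace_s)


def distance_matrix(units_or_coords, metric: str = "euclidean") -> np.ndarray:
    """Symmetric inter-unit distance matrix with zero diagonal.

    ``haversine`` expects x = longitude, y = latitude in degrees and
    returns great-circle kilometres.
    """
    if hasattr(units_or_coords, "columns"):
        coords = units_or_coords[["x", "y"]].to_numpy(dtype=float)
    else:
        coords = np.asarray(units_or_coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ConfigError("non-finite coordinates")
    if metric == "euclidean":
        D = cdist(coords, coords)
    elif metric == "haversine":
        lon = np.radians(coords[:, 0])
        lat = np.radians(coords[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        D = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    else:
        raise ConfigError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    return D


def adaptive_bisquare(dist_row: np.ndarray, k_neighbors: int) -> np.ndarray:
    """Bi-square weights for one focal unit from its distance row.

    The focal unit itself (distance 0) counts as the nearest neighbor and
    receives weight 1; units at exactly the bandwidth distance get weight 0
    (open kernel support).
    """
    dist_row = np.asarray(dist_row, dtype=float)
    if k_neighbors < 2:
        raise ConfigError("k_neighbors must be >= 2")
    if k_neighbors > dist_row.size:
        raise ConfigError("k_neighbors exceeds the number of units")
    b = np.partition(dist_row, k_neighbors - 1)[k_neighbors - 1]
    if b <= 0:
        raise ConfigError("bandwidth distance is zero (coincident units?)")
    w = np.zeros_like(dist_row)
    inside = dist_row < b
    w[inside] = (1.0 - (dist_row[inside] / b) ** 2) ** 2
    return w


def kernel_weights(D: np.ndarray, k_neighbors: int, D_sorted: np.ndarray | None = None) -> np.ndarray:
    """All-units bi-square weight matrix (row i = weights of unit i)."""
    if D_sorted is None:
        b = np.partition(D, k_neighbors - 1, axis=1)[:, k_neighbors - 1]
    else:
        b = D_sorted[:, k_neighbors - 1]
    if np.any(b <= 0):
        raise ConfigError("zero bandwidth distance (coincident units?)")
    b = b[:, None]
    with np.errstate(invalid="ignore"):
        W = np.where(D < b, (1.0 - (D / b) ** 2) ** 2, 0.0)
    return W


def local_fit(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, focal: int, unit_id=None
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least squares at one focal unit.

    Returns ``(beta_hat, leverage_row)`` where the leverage row is row
    ``focal`` of the hat matrix, x_i'(X'WX)^{-1}X'W.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    p = X.shape[1]
    if int(np.count_nonzero(w > 0)) < p:
        raise LocalSingularityError(
            f"only {np.count_nonzero(w > 0)} weighted units for {p} parameters",
            unit_id=unit_id,
        )
    Xw = X * w[:, None]             # W X
    A = X.T @ Xw                    # X' W X
    try:
        C = np.linalg.solve(A, Xw.T)    # (X'WX)^{-1} X'W
    except np.linalg.LinAlgError as exc:
        raise LocalSingularityError(
            f"singular local design at focal unit {focal}", unit_id=unit_id
        ) from exc
    beta = C @ y
    leverage_row = X[focal] @ C
    return beta, leverage_row


def fit_gwr(data: SpatialDataset, kernel: KernelSpec) -> GWRResult:
    """Calibrate GWR at every unit with a shared bandwidth.

    Variables are standardized first (the package-wide convention); local
    standard errors use sigma2 * diag[(X'WX)^-1 X'W^2 X (X'WX)^-1] with
    sigma2 = RSS / (n - tr S).
    """
    std = data.standardized()
    X, y = std.X, std.y
    n, p = X.shape
    kernel.validate(n, p)
    D = distance_matrix(std.units, std.metric)
    W = kernel_weights(D, kernel.k_neighbors)

    params = np.empty((n, p))
    cc_diag = np.empty((n, p))  # diag of C C' per focal unit
    leverage = np.empty(n)
    fitted = np.empty(n)
    ids = std.units["unit_id"].to_numpy()
    for i in range(n):
        w = W[i]
        Xw = X * w[:, None]
        A = X.T @ Xw
        try:
            C = np.linalg.solve(A, Xw.T)
        except np.linalg.LinAlgError as exc:
            raise LocalSingularityError(
                f"singular local design at unit {ids[i]}", unit_id=ids[i]
            ) from exc
        beta = C @ y
        params[i] = beta
        cc_diag[i] = np.sum(C * C, axis=1)
        leverage[i] = X[i] @ C[:, i]
        fitted[i] = X[i] @ beta

    residuals = y - fitted
    rss = float(np.sum(residuals**2))
    trace_s = float(np.sum(leverage))
    aicc = model_aicc(rss, n, trace_s)
    sigma2 = rss / (n - trace_s)
    se = np.sqrt(sigma2 * cc_diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvalues = np.where(se > 0, params / se, np.inf)

    # local R^2: weighted residual/total sums with the estimation weights
    wsum = W.sum(axis=1)
    ybar_local = (W @ y) / wsum
    wrss = W @ (residuals**2)
    wtss = np.einsum("ij,ij->i", W, (y[None, :] - ybar_local[:, None]) ** 2)
    local_r2 = 1.0 - wrss / wtss

    return GWRResult(
        names=list(std.names),
        params=params,
        se=se,
        tvalues=tvalues,
        fitted=fitted,
        residuals=residuals,
        trace_s=trace_s,
        rss=rss,
        aicc=aicc,
        bandwidth=kernel.k_neighbors,
        local_r2=local_r2,
        leverage=leverage,
        scaling=std.scaling,
    )


def _gwr_aicc(data_std: SpatialDataset, D: np.ndarray, D_sorted: np.ndarray, k: int) -> float:
    """AICc of a GWR fit at bandwidth k (infinite when undefined)."""
    X, y = data_std.X, data_std.y
    n = X.shape[0]
    W = kernel_weights(D, k, D_sorted)
    rss = 0.0
    trace = 0.0
    for i in range(n):
        Xw = X * W[i][:, None]
        A = X.T @ Xw
        try:
            C = np.linalg.solve(A, Xw.T)
        except np.linalg.LinAlgError:
            return np.inf
        beta = C @ y
        rss += (y[i] - X[i] @ beta) ** 2
        trace += X[i] @ C[:, i]
    try:
        return model_aicc(float(rss), n, float(trace))
    except OversaturatedModelError:
        return np.inf


def golden_section_integers(f, lo: int, hi: int, exhaustive_below: int = 64):
    """Minimize f over the integers [lo, hi].

    Small ranges are scanned exhaustively; larger ones use golden-section
    with memoization, preferring the left candidate on ties so plateau ties
    resolve toward the smallest bandwidth.  Returns (argmin, cache).
    """
    if hi < lo:
        raise ConfigError(f"empty bandwidth range [{lo}, {hi}]")
    cache: dict[int, float] = {}

    def F(k: int) -> float:
        if k not in cache:
            cache[k] = f(k)
        return cache[k]

    if hi - lo + 1 <= exhaustive_below:
        best = min(range(lo, hi + 1), key=lambda k: (F(k), k))
        return best, cache

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = int(round(b - (b - a) * invphi))
    d = int(round(a + (b - a) * invphi))
    while b - a > 2:
        if c == d:
            d = min(b, c + 1)
        if F(c) <= F(d):
            b = d
        else:
            a = c
        c = int(round(b - (b - a) * invphi))
        d = int(round(a + (b - a) * invphi))
    best = min(range(a, b + 1), key=lambda k: (F(k), k))
    return best, cache


def select_bandwidth(
    data: SpatialDataset,
    criterion: str = "aicc",
    bw_min: int | None = None,
    bw_max: int | None = None,
) -> int:
    """AICc-minimizing adaptive bandwidth for a full GWR model."""
    if criterion != "aicc":
        raise ConfigError(f"unsupported criterion {criterion!r}")
    std = data.standardized()
    n, p = std.X.shape
    lo = bw_min if bw_min is not None else max(p + 2, 10)
    hi = bw_max if bw_max is not None else n
    if lo < p + 1 or hi > n or hi < lo:
        raise ConfigError(f"infeasible bandwidth range [{lo}, {hi}] for n={n}, p={p}")
    D = distance_matrix(std.units, std.metric)
    D_sorted = np.sort(D, axis=1)
    best, _ = golden_section_integers(lambda k: _gwr_aicc(std, D, D_sorted, k), lo, hi)
    return int(best)
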