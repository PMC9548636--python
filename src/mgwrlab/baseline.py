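"""Global OLS baseline with VIF diagnostics and AICc.

The global model is the comparator for the multiscale fit: everything is
z-scored, so the intercept is ~0 and coefficients are standardized effects.
AICc uses the hat-trace form shared by every model in the package,

    AICc = 2n ln(sigma_hat) + n ln(2 pi) + n (n + tr S) / (n - 2 - tr S),

with sigma_hat^2 = RSS/n; for OLS tr S = k + 1.  Using one formula across
OLS, GWR and MGWR keeps the model-comparison column internally consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .dataset import SpatialDataset
from .exceptions import CollinearityError, OversaturatedModelError


@dataclass
class OLSResult:
    names: list[str]
    coefficients: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    adjusted_r2: float
    aicc: float
    residuals: np.ndarray
    rss: float
    fitted: np.ndarray
    scaling: dict | None = None


@dataclass
class VIFReport:
    names: list[str]
    vif: np.ndarray
    flagged: list[str] = field(default_factory=list)  # infinite/huge VIFs


def model_aicc(rss: float, n: int, trace_s: float) -> float:
    """Corrected AIC with the effective-parameter (hat-trace) penalty."""
    if n - 2.0 - trace_s <= 0:
        raise OversaturatedModelError(
            f"AICc undefined: n - 2 - trace(S) = {n - 2.0 - trace_s:.3f} <= 0"
        )
    sigma2 = max(rss / n, 1e-300)  # rss == 0 would otherwise blow up the log
    return float(
        n * math.log(sigma2) + n * math.log(2.0 * math.pi)
        + n * (n + trace_s) / (n - 2.0 - trace_s)
    )


def vif(X: np.ndarray, names: list[str] | None = None) -> VIFReport:
    """Variance inflation factors: VIF_j = 1/(1 - R^2_j).

    ``X`` is the covariate matrix WITHOUT the intercept.  Each column is
    regressed on the others (with intercept).  Perfectly collinear columns
    get VIF = inf and are flagged rather than raising.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    names = names or [f"x{j+1}" for j in range(k)]
    out = np.empty(k)
    flagged = []
    for j in range(k):
        xj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ beta
        tss = np.sum((xj - xj.mean()) ** 2)
        r2 = 0.0 if tss == 0 else 1.0 - np.sum(resid**2) / tss
        if r2 >= 1.0 - 1e-12:
            out[j] = np.inf
            flagged.append(names[j])
        else:
            out[j] = 1.0 / (1.0 - r2)
    return VIFReport(names=names, vif=out, flagged=flagged)


def fit_ols(data: SpatialDataset) -> OLSResult:
    """Global least squares on standardized outcome and covariates."""
    std = data.standardized()
    X, y = std.X, std.y
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        report = vif(X[:, 1:], std.names[1:])
        cols = report.flagged or std.names[1:]
        raise CollinearityError(
            f"singular design matrix; offending columns: {cols}", columns=cols
        )
    res = sm.OLS(y, X).fit()
    rss = float(np.sum(res.resid**2))
    return OLSResult(
        names=list(std.names),
        coefficients=np.asarray(res.params),
        se=np.asarray(res.bse),
        tvalues=np.asarray(res.tvalues),
        pvalues=np.asarray(res.pvalues),
        adjusted_r2=float(res.rsquared_adj),
        aicc=model_aicc(rss, n, float(p)),
        residuals=np.asarray(res.resid),
        rss=rss,
        fitted=np.asarray(res.fittedvalues),
        scaling=std.scaling,
    )
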