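"""Composite county covariates: PCA indices and mean-of-z scales.

Three composite measures are standard in this literature: a social-isolation
index and a concentrated-disadvantage index, each the first principal
component of a block of standardized inputs, and residential stability, the
plain average of standardized inputs.  PCA is run on the correlation matrix
(inputs are z-scored first) because the blocks mix percentages with logged
dollar amounts; loadings are reported as correlations between each input and
the score so the conventional "loading > 0.65" reading applies.

Eigenvector sign is arbitrary, so each index names an *anchor* input whose
loading must be positive — e.g. anchoring on the poverty share makes higher
scores mean higher isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .exceptions import ConfigError, DataError, DegenerateVariableError

METHODS = ("pca-first-component", "mean-of-z")


@dataclass(frozen=True)
class IndexSpec:
    name: str
    variables: list[str]
    method: str = "pca-first-component"
    anchor: str | None = None

    def validate(self) -> None:
        if len(self.variables) < 2:
            raise ConfigError(f"index {self.name!r} needs >= 2 input variables")
        if self.method not in METHODS:
            raise ConfigError(f"unknown index method {self.method!r}")
        if self.anchor is not None and self.anchor not in self.variables:
            raise ConfigError(
                f"anchor {self.anchor!r} is not among the inputs of {self.name!r}"
            )


@dataclass
class IndexResult:
    name: str
    scores: np.ndarray
    loadings: np.ndarray | None
    variance_explained: float | None
    method: str
    variables: list[str] = field(default_factory=list)


def standardize(v: np.ndarray) -> np.ndarray:
    """z-score with sample SD (ddof=1); constant input raises."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise DataError("non-finite values in input")
    sd = np.std(v, ddof=1)
    if sd == 0:
        raise DegenerateVariableError("cannot standardize a constant variable")
    return (v - np.mean(v)) / sd


def _as_matrix(X, variables: list[str] | None):
    if isinstance(X, pd.DataFrame):
        cols = variables if variables is not None else list(X.columns)
        return X[cols].to_numpy(dtype=float), cols
    M = np.asarray(X, dtype=float)
    cols = variables if variables is not None else [f"v{j}" for j in range(M.shape[1])]
    return M, cols


def pca_index(X, spec: IndexSpec) -> IndexResult:
    """First-principal-component score of the column-standardized inputs.

    Scores have mean zero; the sign is flipped if needed so the anchor
    variable's loading (correlation with the score) is positive.
    """
    spec.validate()
    if spec.method != "pca-first-component":
        raise ConfigError("pca_index requires method 'pca-first-component'")
    M, cols = _as_matrix(X, spec.variables)
    if M.shape[0] < 3:
        raise DataError("PCA index needs >= 3 units")
    if not np.all(np.isfinite(M)):
        raise DataError(f"missing/non-finite values in inputs of index {spec.name!r}")
    Z = np.column_stack([standardize(M[:, j]) for j in range(M.shape[1])])
    pca = PCA(n_components=1)
    scores = pca.fit_transform(Z)[:, 0]
    var_explained = float(pca.explained_variance_ratio_[0])
    if np.std(scores) == 0:
        raise DegenerateVariableError(
            f"index {spec.name!r}: inputs are rank deficient after standardization"
        )
    # loadings = correlation of each standardized input with the score
    loadings = np.array(
        [np.corrcoef(Z[:, j], scores)[0, 1] for j in range(Z.shape[1])]
    )
    anchor = spec.anchor or cols[0]
    a = cols.index(anchor)
    if loadings[a] < 0:
        scores, loadings = -scores, -loadings
    return IndexResult(
        name=spec.name,
        scores=scores,
        loadings=loadings,
        variance_explained=var_explained,
        method=spec.method,
        variables=cols,
    )


def mean_index(X, variables: list[str] | None = None, name: str = "mean_index") -> IndexResult:
    """Row-wise mean of column-standardized inputs (e.g. residential
    stability from owner occupancy and residential tenure)."""
    M, cols = _as_matrix(X, variables)
    if M.shape[1] < 2:
        raise ConfigError("mean index needs >= 2 input variables")
    if not np.all(np.isfinite(M)):
        raise DataError("missing/non-finite values in mean-index inputs")
    Z = np.column_stack([standardize(M[:, j]) for j in range(M.shape[1])])
    return IndexResult(
        name=name,
        scores=Z.mean(axis=1),
        loadings=None,
        variance_explained=None,
        method="mean-of-z",
        variables=cols,
    )


def build_index(X, spec: IndexSpec) -> IndexResult:
    """Dispatch on the spec's method."""
    spec.validate()
    if spec.method == "pca-first-component":
        return pca_index(X, spec)
    res = mean_index(X, spec.variables, name=spec.name)
    return res
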