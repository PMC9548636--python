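"""Core spatial data container shared by every fitting stage.

A :class:`SpatialDataset` holds one row per spatial unit (a county analogue):
planar or geographic coordinates, a population weight (beneficiary count),
the outcome vector ``y`` and the design matrix ``X`` whose first column is
the intercept.  All model stages operate on standardized variables, the
convention under which local coefficients are comparable across units; use
:meth:`SpatialDataset.standardized` to z-score outcome and covariates while
recording the original means and standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError, DegenerateVariableError

UNIT_COLUMNS = ("unit_id", "x", "y", "population")

METRICS = ("euclidean", "haversine")


def validate_units(units: pd.DataFrame) -> pd.DataFrame:
    """Validate a unit table (unit_id, x, y, population) and return it.

    Enforces unique ids, unique coordinate pairs, strictly positive
    populations and finite coordinates.
    """
    missing = [c for c in UNIT_COLUMNS if c not in units.columns]
    if missing:
        raise DataError(f"unit table is missing columns: {missing}")
    if units["unit_id"].duplicated().any():
        dupes = units.loc[units["unit_id"].duplicated(), "unit_id"].tolist()
        raise DataError(f"duplicate unit_id values: {dupes[:5]}")
    coords = units[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise DataError("non-finite coordinates in unit table")
    if units[["x", "y"]].duplicated().any():
        raise DataError("duplicated coordinate pairs in unit table")
    pop = units["population"].to_numpy()
    if np.any(pop < 1):
        raise DataError("populations must be >= 1")
    return units


@dataclass
class SpatialDataset:
    """Units with coordinates, populations, outcome and design matrix.

    Parameters
    ----------
    units:
        DataFrame with columns ``unit_id, x, y, population``.
    y:
        Outcome vector, one entry per unit.
    X:
        ``n x (k+1)`` design matrix whose first column is the intercept
        (all ones).
    names:
        Column labels for ``X``; ``names[0] == "intercept"``.
    metric:
        ``"euclidean"`` for planar x/y, ``"haversine"`` when x/y are
        longitude/latitude in degrees (distances in kilometres).
    scaling:
        ``None`` for raw data; after :meth:`standardized`, a dict mapping
        ``"y"`` and each covariate name to its original ``(mean, sd)``.
    """

    units: pd.DataFrame
    y: np.ndarray
    X: np.ndarray
    names: list[str] = field(default_factory=list)
    metric: str = "euclidean"
    scaling: dict | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        validate_units(self.units)
        if self.metric not in METRICS:
            raise ConfigError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        n = len(self.units)
        if self.y.shape != (n,):
            raise DataError(f"y has shape {self.y.shape}, expected ({n},)")
        if self.X.ndim != 2 or self.X.shape[0] != n:
            raise DataError(f"X has shape {self.X.shape}, expected ({n}, k+1)")
        if self.X.shape[1] < 2:
            raise DataError("X must contain the intercept and at least one covariate")
        if not self.names:
            self.names = ["intercept"] + [f"x{j}" for j in range(1, self.X.shape[1])]
        if len(self.names) != self.X.shape[1]:
            raise DataError("names length does not match X columns")
        if not np.allclose(self.X[:, 0], 1.0):
            raise DataError("first design column must be the intercept (all ones)")
        if not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(self.X)):
            raise DataError("missing or non-finite values in y/X")

    @property
    def n(self) -> int:
        return len(self.units)

    @property
    def k(self) -> int:
        """Number of covariates (intercept excluded)."""
        return self.X.shape[1] - 1

    @property
    def coords(self) -> np.ndarray:
        return self.units[["x", "y"]].to_numpy(dtype=float)

    @property
    def populations(self) -> np.ndarray:
        return self.units["population"].to_numpy(dtype=float)

    def standardized(self) -> "SpatialDataset":
        """Return a copy with z-scored outcome and covariates (sample SD).

        Idempotent: if scaling metadata is already attached the dataset is
        returned unchanged.  Constant columns raise
        :class:`DegenerateVariableError` naming the column.
        """
        if self.scaling is not None:
            return self
        scaling: dict[str, tuple[float, float]] = {}
        y_mean, y_sd = float(np.mean(self.y)), float(np.std(self.y, ddof=1))
        if y_sd == 0:
            raise DegenerateVariableError("outcome is constant")
        scaling["y"] = (y_mean, y_sd)
        X = self.X.copy()
        for j in range(1, X.shape[1]):
            mu, sd = float(np.mean(X[:, j])), float(np.std(X[:, j], ddof=1))
            if sd == 0:
                raise DegenerateVariableError(f"covariate {self.names[j]!r} is constant")
            scaling[self.names[j]] = (mu, sd)
            X[:, j] = (X[:, j] - mu) / sd
        return replace(self, y=(self.y - y_mean) / y_sd, X=X, scaling=scaling)

    def to_frame(self, outcome_col: str = "y_outcome") -> pd.DataFrame:
        """Flatten to a tidy table: unit columns, outcome, covariates."""
        out = self.units.copy()
        out[outcome_col] = self.y
        for j, name in enumerate(self.names):
            if j == 0:
                continue
            out[name] = self.X[:, j]
        return out

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        covariates: list[str],
        outcome_col: str = "y_outcome",
        metric: str = "euclidean",
    ) -> "SpatialDataset":
        """Build a dataset from a tidy table with an intercept attached."""
        units = frame[list(UNIT_COLUMNS)].reset_index(drop=True)
        y = frame[outcome_col].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(frame))] + [frame[c].to_numpy(dtype=float) for c in covariates]
        )
        return cls(units=units, y=y, X=X, names=["intercept"] + list(covariates), metric=metric)
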