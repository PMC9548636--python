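"""Three-dimension classification of multiscale spatial processes.

Given calibrated local coefficients, each covariate is characterized along:

level of influence
    the share of the total population living in units where its local
    estimate is significant; above 50% the variable is a *primary*
    influencer, otherwise *secondary*.

scalability
    its bandwidth relative to the total unit count n: above 75% of n the
    process is *global*, below 25% *local*, the closed interval between is
    *regional*.

specificity
    within each unit, the covariate with the largest absolute standardized
    local coefficient (direction ignored) is that unit's *dominant*
    variable; dominance counts partition the units.  All covariates compete
    regardless of significance, so every unit receives a dominant variable.

The intercept is listed in the scalability summary but excluded from
influence and specificity, which are defined over substantive covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SpatialDataset
from .exceptions import ConfigError, DataError
from .mgwr import MGWRResult

logger = logging.getLogger(__name__)

INFLUENCE_THRESHOLD_PCT = 50.0
SCALABILITY_HI = 0.75
SCALABILITY_LO = 0.25


@dataclass
class DimensionReport:
    """Per-variable classification table plus the per-unit dominant labels."""

    table: pd.DataFrame           # variable, bandwidth, influence, scalability, dominance
    dominant: pd.Series           # per-unit dominant covariate label
    alpha_policy: str

    def __post_init__(self):
        counts = self.table["dominance_count"].to_numpy(dtype=float)
        if counts.sum() != len(self.dominant):
            raise DataError("dominance counts do not partition the units")


def scalability_thresholds(n_units: int) -> tuple[float, float]:
    """(lo, hi) bandwidth thresholds: 0.25*n and 0.75*n."""
    return SCALABILITY_LO * n_units, SCALABILITY_HI * n_units


def scalability_class(bandwidth: int, n_units: int) -> str:
    """Classify a bandwidth as global (> 0.75 n), local (< 0.25 n), or
    regional (the closed interval in between)."""
    if not 1 <= bandwidth <= n_units:
        raise ConfigError(f"bandwidth {bandwidth} outside [1, {n_units}]")
    lo, hi = scalability_thresholds(n_units)
    if bandwidth > hi:
        return "global"
    if bandwidth < lo:
        return "local"
    return "regional"


def scalability_conflict(bandwidth: int, n_units: int, reported_label: str) -> bool:
    """True when a reported label disagrees with the threshold rule.

    Published tables occasionally carry labels inconsistent with their own
    stated thresholds; the classifier is by-the-letter, and this helper
    flags such conflicts instead of reproducing them.
    """
    return scalability_class(bandwidth, n_units) != reported_label.lower()


def level_of_influence(
    significant: np.ndarray, populations: np.ndarray, names: list[str] | None = None
) -> pd.DataFrame:
    """Population-weighted influence share and class per variable.

    share_j = 100 * (population in units where variable j is significant)
    / (total population); primary iff share > 50.
    """
    significant = np.asarray(significant, dtype=bool)
    populations = np.asarray(populations, dtype=float)
    if significant.ndim != 2 or significant.shape[0] != populations.size:
        raise ConfigError("significance mask and populations have mismatched shapes")
    total = populations.sum()
    if total <= 0:
        raise ConfigError("total population is zero")
    shares = 100.0 * (significant * populations[:, None]).sum(axis=0) / total
    names = names or [f"x{j+1}" for j in range(significant.shape[1])]
    return pd.DataFrame(
        {
            "variable": names,
            "influence_share": shares,
            "influence_class": np.where(
                shares > INFLUENCE_THRESHOLD_PCT, "primary", "secondary"
            ),
        }
    )


def specificity(
    local_coeffs: np.ndarray, names: list[str] | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Dominant covariate per unit and dominance counts per covariate.

    ``local_coeffs`` excludes the intercept.  Ties in |coefficient| break
    to the first column (and are logged).
    """
    B = np.asarray(local_coeffs, dtype=float)
    if B.ndim != 2 or B.shape[1] < 1:
        raise ConfigError("need a unit x covariate coefficient matrix")
    if not np.all(np.isfinite(B)):
        raise DataError("non-finite local coefficients")
    names = names or [f"x{j+1}" for j in range(B.shape[1])]
    absB = np.abs(B)
    dom_idx = absB.argmax(axis=1)  # argmax takes the first maximum: tie -> lowest index
    n_ties = int(np.sum((absB == absB.max(axis=1, keepdims=True)).sum(axis=1) > 1))
    if n_ties:
        logger.info("specificity: %d unit(s) had tied |coefficients|; first column wins", n_ties)
    dominant = pd.Series([names[j] for j in dom_idx], name="dominant_variable")
    counts = np.bincount(dom_idx, minlength=len(names))
    table = pd.DataFrame(
        {
            "variable": names,
            "dominance_count": counts,
            "dominance_share": 100.0 * counts / B.shape[0],
        }
    )
    return dominant, table


def dimension_report(
    result: MGWRResult, data: SpatialDataset, alpha_policy: str = "corrected"
) -> DimensionReport:
    """Assemble the full three-dimension table from a fitted multiscale model."""
    if result.params.shape[0] != data.n:
        raise ConfigError("fitted result and dataset are not aligned")
    names = result.names
    cov_cols = [j for j, nm in enumerate(names) if nm != "intercept"]
    cov_names = [names[j] for j in cov_cols]

    sig = result.significant(alpha_policy)
    influence = level_of_influence(
        sig[:, cov_cols], data.populations, cov_names
    ).set_index("variable")
    dominant, dom_table = specificity(result.params[:, cov_cols], cov_names)
    dom_table = dom_table.set_index("variable")

    rows = []
    for j, nm in enumerate(names):
        row = {
            "variable": nm,
            "bandwidth": int(result.bandwidths[j]),
            "scalability_class": scalability_class(int(result.bandwidths[j]), data.n),
        }
        if nm == "intercept":
            row.update(
                influence_share=np.nan,
                influence_class="",
                dominance_count=0,
                dominance_share=0.0,
            )
        else:
            row.update(
                influence_share=float(influence.loc[nm, "influence_share"]),
                influence_class=str(influence.loc[nm, "influence_class"]),
                dominance_count=int(dom_table.loc[nm, "dominance_count"]),
                dominance_share=float(dom_table.loc[nm, "dominance_share"]),
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    dominant.index = data.units["unit_id"].to_numpy()
    return DimensionReport(table=table, dominant=dominant, alpha_policy=alpha_policy)
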