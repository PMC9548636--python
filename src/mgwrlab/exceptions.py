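"""Exception hierarchy for mgwrlab.

All configuration and data problems raise a subclass of :class:`MgwrlabError`
so callers can catch pipeline failures with a single except clause.
"""


class MgwrlabError(Exception):
    """Base class for all mgwrlab errors."""


class ConfigError(MgwrlabError):
    """Invalid configuration: bad layout name, out-of-range bandwidth, ..."""


class DataError(MgwrlabError):
    """Invalid data: missing values, duplicate unit ids, non-finite entries."""


class DegenerateVariableError(DataError):
    """A variable is constant (zero variance) where variation is required."""


class CollinearityError(DataError):
    """The design matrix is rank deficient.

    ``columns`` names the offending covariates when they could be identified.
    """

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class LocalSingularityError(MgwrlabError):
    """A local weighted fit is singular (too few distinct neighbors).

    Carries the focal ``unit_id`` and, when known, the ``variable`` being
    back-fitted so failures deep inside MGWR sweeps are diagnosable.
    """

    def __init__(self, message: str, unit_id=None, variable: str | None = None):
        super().__init__(message)
        self.unit_id = unit_id
        self.variable = variable


class OversaturatedModelError(MgwrlabError):
    """AICc undefined: effective parameters too close to the sample size."""
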