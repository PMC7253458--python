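"""Exception hierarchy for the disaggregation pipeline.

Every error raised by the package derives from :class:`DasycropError`,
so callers can catch pipeline failures with a single except clause while
still distinguishing parameter mistakes from data problems.
"""


class DasycropError(Exception):
    """Base class for all package errors."""


class ParameterError(DasycropError, ValueError):
    """An argument violates a documented precondition (e.g. cap <= 0)."""


class AlignmentError(DasycropError):
    """Two grids that must share a GridSpec do not."""


class OverlapError(DasycropError):
    """Two admin units claim the same pixel centre or overlap in area."""


class SchemaError(DasycropError):
    """An input file fails validation; message names file, column and row."""


class UnscalableCountryError(DasycropError):
    """A country's raw census sum is zero but its national total is positive."""


class MissingTotalError(DasycropError):
    """A census record's country has no national reference total."""


class UnimputableUnitError(DasycropError):
    """A missing-rate unit has no donor with data anywhere in its country."""


class InfeasibleUnitError(DasycropError):
    """A unit's adjusted total exceeds its pixel capacity and policy is 'error'."""
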