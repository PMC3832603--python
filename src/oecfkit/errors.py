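"""Exception hierarchy shared by all modules.

Exit-code mapping used by the CLI: usage errors exit 2 (click's default),
:class:`DataError` and friends exit 3, :class:`FitConvergenceError` exits 4.
"""


class OECFError(Exception):
    """Base class for all oecfkit errors."""

    exit_code = 1


class DataError(OECFError):
    """Invalid, insufficient or mutually inconsistent input data."""

    exit_code = 3


class StateError(OECFError):
    """Operation called on an object missing required derived state."""

    exit_code = 3


class EstimationError(DataError):
    """A quantity (e.g. E_max) could not be estimated from the data."""


class NoSolutionError(DataError):
    """Requested inversion has no solution (response at/above asymptote)."""


class BelowRangeError(DataError):
    """Response below the linearisable range (under the p_min anchor)."""


class LUTError(DataError):
    """Curve cannot be tabulated for inversion (non-monotone response)."""


class FitConvergenceError(OECFError):
    """Curve fitting failed to converge from every starting point."""

    exit_code = 4
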