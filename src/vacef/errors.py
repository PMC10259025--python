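"""Exception hierarchy shared across the package."""


class VacefError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(VacefError, ValueError):
    """A measurement or parameter violates its physical precondition.

    The message names the offending field so batch callers can report
    row-level failures without string parsing on their side.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DomainError(VacefError, ValueError):
    """Argument outside the mathematical domain of a formula."""


class NoSolutionError(VacefError):
    """The coupling residual has no positive root in the search bracket."""

    def __init__(self, message: str, g_low: float, g_high: float):
        self.g_low = g_low
        self.g_high = g_high
        super().__init__(f"{message} (residual at bracket ends: {g_low:.6g}, {g_high:.6g})")


class NonConvergenceError(VacefError):
    """Root iteration exhausted its budget without meeting tolerance."""

    def __init__(self, message: str, last_iterate: float, residual: float):
        self.last_iterate = last_iterate
        self.residual = residual
        super().__init__(f"{message} (last x={last_iterate:.9g}, residual={residual:.3g})")


class DegenerateLoopError(VacefError, ValueError):
    """Pressure-volume loop with ESV = V0 (infinite end-systolic elastance)."""


class InfeasibleTruthError(VacefError, ValueError):
    """Requested ground-truth coupling implies a non-positive ejection time."""


class GenerationError(VacefError, RuntimeError):
    """Synthetic-cohort sampling rejected too many draws to be trustworthy."""


class SchemaError(VacefError, ValueError):
    """Input table is missing required columns or is otherwise unreadable."""
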