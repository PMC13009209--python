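"""Exception hierarchy shared across the package."""


class MobiusGateError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(MobiusGateError, ValueError):
    """A configuration value violates its stated constraint."""


class InsufficientDataError(MobiusGateError, ValueError):
    """The input is too short / too empty for the requested operation."""


class DegenerateReferenceError(MobiusGateError, ValueError):
    """Control reference cannot be formed (e.g. zero control variance)."""


class DegenerateSampleError(MobiusGateError, ValueError):
    """A two-group sample is degenerate for the requested statistic."""


class NumericalSingularityError(MobiusGateError, ValueError):
    """A matrix that must be inverted is numerically singular."""


class ConvergenceError(MobiusGateError, RuntimeError):
    """An iterative fit failed to converge (e.g. perfect separation)."""
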