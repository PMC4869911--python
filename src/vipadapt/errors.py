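"""Exception hierarchy shared across the package."""


class VipAdaptError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VipAdaptError):
    """Invalid generator or pipeline configuration."""


class ParameterError(VipAdaptError):
    """Invalid argument to an analysis operation."""


class AlignmentError(VipAdaptError):
    """Malformed codon alignment (length mismatch, frame)."""


class EstimationError(VipAdaptError):
    """An estimator could not be computed (degenerate counts/bins)."""


class UndefinedRatioError(EstimationError):
    """pN/pS requested in raw mode with pS = 0."""


class UndefinedAlphaError(EstimationError):
    """Classic MK alpha undefined (DN = 0 or pS = 0)."""


class InfeasibleTargetError(VipAdaptError):
    """Target-average sampler could not keep the running mean in the interval."""


class CalibrationError(VipAdaptError):
    """No (a, X) grid point produced feasible matched samples."""


class MatchingError(VipAdaptError):
    """GO matching failed for too many focal genes."""


class ValidationError(VipAdaptError):
    """Input file failed schema or cross-reference validation."""
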