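"""Exception hierarchy shared across the pipeline stages."""


class AequovarError(ValueError):
    """Base class for all validation and configuration errors."""


class ValidationError(AequovarError):
    """Malformed input data (non-monotone time grid, out-of-range score ...)."""


class WindowCoverageError(AequovarError):
    """The integration window extends beyond the recorded trace."""


class MissingWildtypeError(AequovarError):
    """A plate lacks wild-type control wells and cannot be normalized."""


class DegenerateControlError(AequovarError):
    """A wild-type control with zero AUC or latency cannot serve as denominator."""


class CalibrationError(AequovarError):
    """Too few control variants to derive z-score thresholds."""


class DegenerateReadoutError(AequovarError):
    """An OddsPath readout proportion of exactly 0 or 1 after pseudo-counts."""


class DegenerateContextError(AequovarError):
    """Min-max normalization context with zero dynamic range."""


class UndefinedCorrelationError(AequovarError):
    """Correlation requested on a constant score vector."""


class UnsupportedCaseError(AequovarError):
    """A splice scenario outside the supported mechanism (terminal exons)."""
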