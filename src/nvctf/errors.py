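"""Exception hierarchy for the transfer-function pipeline."""


class NVCTFError(Exception):
    """Base class for all package errors."""


class InvalidInputError(NVCTFError, ValueError):
    """Input data violates a precondition (shape, monotonicity, window)."""


class InvalidParameterError(NVCTFError, ValueError):
    """Transfer-function parameters outside their admissible domain."""


class DegenerateBaselineError(NVCTFError, ValueError):
    """Relative baseline normalization requested with zero baseline mean."""


class DegenerateScaleError(NVCTFError, ValueError):
    """Amplitude rescale requested against an all-zero prediction window."""


class UndefinedCorrelationError(NVCTFError, ValueError):
    """Pearson correlation of a zero-variance series is undefined."""


class ModeAtOnsetError(NVCTFError, ValueError):
    """Gamma kernel with shape <= 1 peaks at the onset; no interior mode."""


class NoValidTFError(NVCTFError, RuntimeError):
    """No annealing run produced a candidate passing the validity screen."""


class DegenerateCombinationError(NVCTFError, ValueError):
    """Two-component amplitude fit collapsed: both amplitudes degenerate."""


class InvalidKineticsError(NVCTFError, ValueError):
    """Calcium kernel requires rise time constant < decay time constant."""


class JitterTooLargeError(NVCTFError, RuntimeError):
    """Cohort parameter jitter could not produce valid parameters."""


class ParseError(NVCTFError, ValueError):
    """Delimited-text trace file failed schema or monotonicity validation."""
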