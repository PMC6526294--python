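"""Exception hierarchy for the icgpv package."""


class IcgPvError(Exception):
    """Base class for all icgpv-specific errors."""


class InfeasibleDilutionError(IcgPvError, ValueError):
    """A target concentration cannot be reached from the given stock."""


class InvalidCurveError(IcgPvError, ValueError):
    """A calibration curve is unusable (non-positive slope, singular fit)."""


class InsufficientDataError(IcgPvError, ValueError):
    """Fewer observations than the operation requires."""


class NonpositiveConcentrationError(IcgPvError, ValueError):
    """A concentration is <= 0 where a log transform is required."""
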