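"""Exception hierarchy shared across the pipeline.

Every gate in the analysis (config validation, degenerate fits, session
quality exclusions) raises a dedicated subclass of :class:`BgpipeError` so
callers can distinguish "bad input" from "excluded by rule".
"""


class BgpipeError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(BgpipeError):
    """A configuration value violates its documented constraint."""


class EmptySessionError(BgpipeError):
    """An operation would leave no samples (e.g. trimming a whole session)."""


class DegenerateFitError(BgpipeError):
    """A regression target is constant; the fit is undefined."""


class DegenerateScaleError(BgpipeError):
    """A robust scale estimate (MAD) is zero; standardization is undefined."""


class DivisionGuardError(BgpipeError):
    """A denominator (F0) is non-positive at one or more samples."""

    def __init__(self, indices, message=None):
        self.indices = list(indices)
        super().__init__(
            message or f"non-positive denominator at {len(self.indices)} samples "
            f"(first offenders: {self.indices[:5]})"
        )


class InvalidWindowError(BgpipeError):
    """A moving window is too short for the operation."""


class MalformedInputError(BgpipeError):
    """An input file does not match the expected dialect."""


class PartUnusableError(BgpipeError):
    """A tracked body part has no frames above the likelihood threshold."""


class CalibrationError(BgpipeError):
    """Pixel-to-cm calibration is missing or degenerate."""


class SessionExcludedError(BgpipeError):
    """A session failed a published quality gate and must be dropped."""


class InsufficientDataError(BgpipeError):
    """Too few observations for the requested statistic."""


class UndefinedCorrelationError(BgpipeError):
    """Correlation requested on a zero-variance overlap."""


class AlignmentError(BgpipeError):
    """Clocks of two streams disagree beyond tolerance."""


class InvalidInputError(BgpipeError):
    """Generic invalid argument (e.g. empty unit list, zero denominator)."""
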