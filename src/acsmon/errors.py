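"""Exception hierarchy for the monitoring pipeline.

Every error raised by the package derives from :class:`AcsmonError` so
callers can catch pipeline failures without masking programming errors.
"""


class AcsmonError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AcsmonError):
    """Invalid or inconsistent configuration (bad profile, singular optics, ...)."""


class InputError(AcsmonError):
    """Invalid data passed to an operation (nonpositive resistance, empty series)."""


class TraceFormatError(AcsmonError):
    """A trace file violates the CSV trace schema (units, monotone time)."""


class QuadratureError(AcsmonError):
    """Oscillatory quadrature failed to reach its tolerance."""

    def __init__(self, message: str, *, estimate: float | None = None,
                 residual: float | None = None, intervals: int | None = None):
        super().__init__(message)
        self.estimate = estimate
        self.residual = residual
        self.intervals = intervals


class MissingDataError(AcsmonError):
    """All channels required by an inversion are missing/dropped out."""


class UndefinedRateError(AcsmonError):
    """No spectral peak above the noise floor; pulse rate is undefined."""


class AlignmentError(AcsmonError):
    """Two series have disjoint time support and cannot be aligned."""


class InsufficientDataError(AcsmonError):
    """Not enough data for the requested statistic (e.g. < 3 plateaus)."""


class FitError(AcsmonError):
    """A calibration fit is rank deficient or otherwise ill posed."""


class StageError(AcsmonError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
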