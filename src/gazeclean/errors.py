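"""Exception hierarchy for the gazeclean pipeline."""


class GazeCleanError(Exception):
    """Base class for all gazeclean errors."""


class EmptyInputError(GazeCleanError, ValueError):
    """An operation received no usable samples."""


class FormatError(GazeCleanError, ValueError):
    """A file or record does not conform to the expected layout."""


class InvalidArgumentError(GazeCleanError, ValueError):
    """A parameter is outside its valid domain."""


class DegenerateFitError(GazeCleanError, ValueError):
    """A transform fit is unidentifiable (e.g. all-zero chunk coordinates)."""


class InvalidModelError(GazeCleanError, ValueError):
    """A state-space model is malformed (non-finite or non-PSD covariances)."""


class RecalibrationRequired(GazeCleanError, RuntimeError):
    """Too many calibration transforms failed validation; fresh data needed."""


class CalibrationIncomplete(GazeCleanError, RuntimeError):
    """A calibration session is missing one or more dwell chunks."""


class LayoutOverflowError(GazeCleanError, ValueError):
    """Requested stimulus layout does not fit on the screen."""


class ARFitError(GazeCleanError, RuntimeError):
    """The velocity series is too short or degenerate for AR fitting."""
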