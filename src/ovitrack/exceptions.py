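"""Exception hierarchy shared across the package."""


class OvitrackError(Exception):
    """Base class for all package errors."""


class FormatError(OvitrackError, ValueError):
    """A file does not follow the expected CSV dialect (missing columns etc.)."""


class DataError(OvitrackError, ValueError):
    """Structurally valid input whose content is unusable (empty, unordered,
    too short, mismatched lengths)."""


class ParameterError(OvitrackError, ValueError):
    """An analysis parameter is out of its admissible range."""


class CalibrationError(OvitrackError, ValueError):
    """Calibration cannot proceed (e.g. single-class ground truth)."""
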