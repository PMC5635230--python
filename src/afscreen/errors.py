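"""Exception hierarchy for the screening pipeline."""


class AFScreenError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AFScreenError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive duration)."""


class InvalidInputError(AFScreenError, ValueError):
    """An input record or table cannot be processed (e.g. shorter than the filter)."""


class InsufficientBeatsError(AFScreenError):
    """Too few detected beats to compute rhythm statistics; the record is ungradable."""


class CalibrationError(AFScreenError):
    """Threshold calibration is impossible (e.g. a single-class training cohort)."""


class DataError(AFScreenError):
    """A required column or reference label is missing from an input table."""
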