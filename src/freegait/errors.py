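"""Exception hierarchy for the freegait package."""


class FreegaitError(Exception):
    """Base class for all freegait errors."""


class FormatError(FreegaitError):
    """A file or table does not match the expected layout."""


class SamplingError(FreegaitError):
    """Timestamps are not uniform within tolerance, or rates are invalid."""


class CalibrationError(FreegaitError):
    """Standing-trial calibration failed (motion, bad gravity norm, ...)."""


class CadenceError(FreegaitError):
    """No dominant stride/step frequency could be found in the PSD."""


class SelectionError(FreegaitError):
    """Feature selection returned an empty feature set."""


class TrainingError(FreegaitError):
    """Classifier training is impossible (e.g. single-class labels)."""


class EnvelopeError(FreegaitError):
    """sEMG segment too short for zero-phase envelope filtering."""


class AsymmetryUndefinedError(FreegaitError):
    """An asymmetry index is undefined (zero denominator / zero variance)."""
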