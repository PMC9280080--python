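"""Exception hierarchy for the emgband package."""


class EmgBandError(Exception):
    """Base class for all emgband errors."""


class EmptyInputError(EmgBandError):
    """An operation received an empty signal, window, or file."""


class MalformedInputError(EmgBandError):
    """A file or container violates its format contract (e.g. jittered timestamps)."""


class InvalidLabelsError(EmgBandError):
    """Episode labels are inconsistent with the requested episode."""


class DegenerateSpectrumError(EmgBandError):
    """A spectral statistic was requested on a spectrum with zero total power."""


class EmptyBandError(EmgBandError):
    """A frequency band contains no spectral bins."""


class CalibrationError(EmgBandError):
    """Threshold calibration failed (no clear contraction in the recording)."""


class ConfigurationError(EmgBandError):
    """A controller or pipeline configuration is inconsistent with its input."""
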