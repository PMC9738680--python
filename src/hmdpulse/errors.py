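"""Exception hierarchy shared across the pipeline stages."""


class HmdPulseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HmdPulseError, ValueError):
    """Invalid configuration value."""


class LandmarkError(HmdPulseError, ValueError):
    """Missing or malformed landmark data."""


class ExtractionError(HmdPulseError, RuntimeError):
    """ROI extraction failure (out-of-frame ROI, consecutive detection loss)."""


class WindowingError(HmdPulseError, ValueError):
    """Signal window shorter than the operation requires."""


class MetricsError(HmdPulseError, ValueError):
    """Undefined metric (length mismatch, zero ground truth, constant series)."""
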