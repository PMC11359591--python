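"""Exception types shared across the package."""


class BeebuzzError(Exception):
    """Base class for package-specific errors."""


class AudioFormatError(BeebuzzError, ValueError):
    """Raised for non-WAV, compressed, or empty audio input."""


class DegenerateSignalError(BeebuzzError, ValueError):
    """Raised when a signal has zero variance and cannot be modelled."""


class ConfigError(BeebuzzError, ValueError):
    """Raised for invalid analysis or network configuration."""


class DivergenceError(BeebuzzError, RuntimeError):
    """Raised when autoencoder training produces a non-finite loss."""


class UndefinedMetricError(BeebuzzError, ValueError):
    """Raised when a metric's denominator is zero."""
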