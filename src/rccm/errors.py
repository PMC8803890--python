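"""Exception types shared across the package."""


class RCCMError(Exception):
    """Base class for all package errors."""


class InsufficientDataError(RCCMError, ValueError):
    """A series, library or window is too short for the requested analysis."""


class AlignmentError(RCCMError, ValueError):
    """No usable overlap between prediction targets and manifold times."""


class DivergenceError(RCCMError, RuntimeError):
    """A simulated trajectory left its admissible domain."""


class ConfigError(RCCMError, ValueError):
    """Inconsistent or unknown configuration values."""


class DegenerateDistributionError(RCCMError, ValueError):
    """A sample is constant (or effectively so) where spread is required."""
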