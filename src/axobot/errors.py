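"""Exception hierarchy shared across the package."""


class AxobotError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AxobotError, ValueError):
    """Invalid configuration or function parameter."""


class InputError(AxobotError, ValueError):
    """Malformed runtime input (shape mismatch, empty image, ...)."""


class RangeError(AxobotError):
    """Commanded actuator position outside its travel range."""


class CalibrationError(AxobotError):
    """Calibration scan failed to bracket a usable optimum."""


class TargetingError(AxobotError):
    """A targeting sub-step could not be completed (caller flushes)."""


class NoAxonError(TargetingError):
    """No axon signal found above background in the sampled profile."""


class ContractViolation(AxobotError):
    """A precondition that upstream logic must guarantee was broken."""


class ConfigError(AxobotError, ValueError):
    """Configuration file failed schema validation."""


class FormatError(AxobotError, ValueError):
    """On-disk artifact is inconsistent (e.g. stack/sidecar mismatch)."""
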