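"""Exception hierarchy shared across the pipeline stages."""


class SleepNirsError(Exception):
    """Base class for all package errors."""


class ValidationError(SleepNirsError, ValueError):
    """A parameter or field is non-finite, out of range, or inconsistent."""


class ConfigurationError(SleepNirsError, ValueError):
    """A configuration is structurally unusable (too few distances, bad cutoff ...)."""


class DataError(SleepNirsError, ValueError):
    """Measured data violate a hard precondition (non-positive intensity ...)."""


class SingularInversionError(SleepNirsError, ArithmeticError):
    """Optical-property inversion hit a zero slope or vanishing determinant."""


class InsufficientDataError(SleepNirsError, ValueError):
    """A statistic was requested on too few observations."""


class CoverageError(SleepNirsError, ValueError):
    """An event window is not covered by the available trace."""
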