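"""Exception hierarchy shared across the package."""


class NatriqError(Exception):
    """Base class for all natriq-specific errors."""


class DomainError(NatriqError, ValueError):
    """A scalar argument is outside its mathematical domain."""


class InputError(NatriqError, ValueError):
    """Inputs are structurally invalid (empty masks, shape mismatches, ...)."""


class SizingError(NatriqError, ValueError):
    """The requested grid cannot contain all phantom regions."""


class DegenerateCalibrationError(NatriqError, ValueError):
    """Reference regions do not define a usable two-point calibration line."""


class SingularFitError(NatriqError, ValueError):
    """The regression design is rank deficient on the selected voxels."""


class EmptyROIError(NatriqError, ValueError):
    """A filter stage removed every voxel of a region of interest."""


class UndefinedStatisticError(NatriqError, ValueError):
    """A statistic is undefined for the given inputs (e.g. zero pooled SD)."""


class ConfigError(NatriqError, ValueError):
    """A pipeline configuration document failed validation."""
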