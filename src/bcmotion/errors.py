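"""Exception hierarchy shared by all bcmotion modules."""


class BCMotionError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BCMotionError, ValueError):
    """A parameter violates a documented precondition."""


class GridMismatchError(BCMotionError, ValueError):
    """Stimulus and receptive field are defined on incompatible grids."""


class UndefinedIndexError(BCMotionError, ValueError):
    """An index (preference, coherence, DSI) is undefined for this input."""


class UndefinedStatisticError(BCMotionError, ValueError):
    """A statistic (d') is undefined, e.g. zero pooled variance."""


class DegenerateTraceError(BCMotionError, ValueError):
    """A response trace has zero variance and cannot be normalized."""


class MissingConditionError(BCMotionError, KeyError):
    """A stimulus condition required for an analysis has no trials."""


class InsufficientDataError(BCMotionError, ValueError):
    """Not enough data to estimate the requested quantity."""


class DegenerateRFError(BCMotionError, ValueError):
    """A receptive field has no usable center/surround structure."""


class UndefinedPeakError(BCMotionError, ValueError):
    """A peak position is undefined (flat profile in the search window)."""


class FeatureMismatchError(BCMotionError, ValueError):
    """Feature vector dimensionality does not match a fitted model."""


class UndefinedCorrelationError(BCMotionError, ValueError):
    """Correlation is undefined because one input has zero variance."""


class InvalidRegionError(BCMotionError, ValueError):
    """Center/surround regions overlap or lie outside the RF extent."""


class ConfigError(BCMotionError, ValueError):
    """A model configuration references unknown labels or keys."""


class CalibrationError(BCMotionError, RuntimeError):
    """Input-scale calibration failed to bracket or converge."""


class NumericalInstabilityError(BCMotionError, RuntimeError):
    """A simulation produced NaN or diverged."""


class SchemaValidationError(BCMotionError, ValueError):
    """A serialized array container is missing required attributes."""
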