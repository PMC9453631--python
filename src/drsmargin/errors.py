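"""Exception hierarchy for the DRS margin-assessment toolkit."""


class DRSError(Exception):
    """Base class for all toolkit errors."""


class GridMismatchError(DRSError):
    """Spectra that must share a wavelength grid do not."""


class GridAlignmentError(DRSError):
    """A requested wavelength does not land on a grid point."""


class InsufficientFramesError(DRSError):
    """Fewer raw frames than the acquisition protocol requires."""


class CalibrationError(DRSError):
    """Invalid white/dark pair (e.g. white < dark somewhere)."""


class UnusableCalibrationError(CalibrationError):
    """Every wavelength was masked by the denominator floor."""


class PreconditionError(DRSError):
    """An operation was applied to data in the wrong state."""


class ConfigError(DRSError):
    """An invalid configuration value."""


class StratificationError(DRSError):
    """A class has too few rows for the requested fold count."""


class DegenerateSplitError(DRSError):
    """A held-out split contains a single class."""


class UndefinedMetricError(DRSError):
    """A metric's denominator is empty (class absent from the test set)."""


class UnsupportedEstimatorError(DRSError):
    """Estimator exposes neither coefficients nor feature importances."""


class NumericStateError(DRSError):
    """Kalman state became numerically invalid (non-PSD covariance etc.)."""


class NoTrackError(DRSError):
    """The marker was never detected in the whole sequence."""


class DependencyError(DRSError):
    """A pipeline stage is missing an upstream artifact."""
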