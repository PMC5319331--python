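"""Exception hierarchy used across the package."""


class SproutessError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(SproutessError, ValueError):
    """An argument violates a documented precondition."""


class MissingDataError(SproutessError):
    """Required input rows/columns/years are absent."""


class MissingCovariateError(SproutessError, KeyError):
    """A vital-rate model needs a covariate the caller did not supply."""


class EmptyDesignError(SproutessError):
    """A design-matrix build produced zero usable rows."""


class NonConvergenceError(SproutessError):
    """A model fit or iterative scheme failed to converge."""


class SelectionError(SproutessError):
    """Model selection had no converged candidate."""


class CalibrationError(SproutessError):
    """Density-dependence calibration could not reach the requested plateau."""


class EquilibriumError(SproutessError):
    """The density-coupled resident iteration did not reach stationarity."""


class NoESSError(SproutessError):
    """The selection gradient does not change sign inside the search bounds."""


class AlignmentError(SproutessError):
    """Two climate series share no overlapping years."""
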