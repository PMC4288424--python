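"""Exception hierarchy.

Every error raised by this package derives from :class:`AcceError` so callers
can catch the whole family; subclasses distinguish arithmetic domain problems
from invalid back-extrapolation, singular designs, degenerate estimation and
bad user input.
"""


class AcceError(Exception):
    """Base class for all errors raised by :mod:`acce`."""


class DomainError(AcceError, ValueError):
    """An argument is outside the mathematical domain of an operation
    (e.g. R-squared not in [0, 1), a non-positive Bross bias factor)."""


class ExtrapolationInvalidError(AcceError):
    """Back-extrapolation is undefined: the between-model amplification
    increment is zero or negative (Model 2 does not out-predict Model 1),
    or a propensity fit separates treatment perfectly."""


class SingularDesignError(AcceError):
    """The propensity design matrix is rank deficient; the message names
    the collinear columns."""


class EstimationError(AcceError):
    """A treatment-effect or coefficient estimate cannot be formed
    (e.g. every propensity-score stratum is degenerate)."""


class CohortValidationError(AcceError, ValueError):
    """A cohort table violates the input contract (non-binary coding,
    missing values, arms below the configured minimum size)."""


class ScenarioError(AcceError, ValueError):
    """A simulation scenario is misspecified (e.g. probability clipping
    affects more than a quarter of subjects)."""


class InferenceError(AcceError):
    """Bootstrap inference failed (too many failed replicates)."""


class ConfigError(AcceError, ValueError):
    """A run configuration is invalid (missing or unknown keys)."""
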