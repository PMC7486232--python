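"""Exception hierarchy shared across the package."""


class DepvalError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DepvalError, ValueError):
    """An input violates a documented precondition."""


class SchemaError(DepvalError, ValueError):
    """A table or model is missing required columns/predictors."""


class MissingDataError(DepvalError, ValueError):
    """Required values are absent; no imputation is performed."""


class DegenerateOutcomeError(DepvalError, ValueError):
    """The outcome vector contains a single class."""


class UnidentifiablePredictorError(DepvalError, ValueError):
    """A zero-variance predictor cannot be estimated without a penalty."""


class ConvergenceError(DepvalError, RuntimeError):
    """An iterative fit failed to converge."""


class UnsupportedConfigError(DepvalError, ValueError):
    """A configuration is valid but outside supported limits."""


class UndefinedMetricError(DepvalError, ValueError):
    """A metric is undefined for the given input (e.g. single-class AUC)."""


class CollinearityError(DepvalError, ValueError):
    """A design matrix is rank-deficient (e.g. constant group indicator)."""
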