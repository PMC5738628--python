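"""Exception types shared across the package."""


class PreopBayesError(Exception):
    """Base class for package errors."""


class ConfigurationError(PreopBayesError, ValueError):
    """A configuration value is invalid; the message names the field."""


class SchemaError(PreopBayesError, ValueError):
    """An input table is missing required columns or has illegal values."""


class EmptyInputError(PreopBayesError, ValueError):
    """An operation that needs data received an empty table."""


class ParameterError(PreopBayesError, ValueError):
    """A numerical-method parameter is out of its admissible range."""


class NumericalFailureError(PreopBayesError, RuntimeError):
    """A numerical routine failed to converge; carries diagnostics."""


class InsufficientSamplesError(PreopBayesError, ValueError):
    """Too few MCMC draws for the requested summary."""
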