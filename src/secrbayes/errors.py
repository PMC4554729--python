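"""Exception hierarchy shared across the package."""


class SecrBayesError(Exception):
    """Base class for all package errors."""


class FormatError(SecrBayesError):
    """An input file does not conform to the expected dialect."""


class ConsistencyError(SecrBayesError):
    """Inputs are individually valid but mutually inconsistent."""


class ConfigError(SecrBayesError):
    """A configuration value is missing, contradictory or out of range."""


class DomainError(SecrBayesError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""
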