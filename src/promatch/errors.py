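"""Exception hierarchy shared across the pipeline stages."""


class PromatchError(Exception):
    """Base class for all package errors."""


class ConfigError(PromatchError):
    """Invalid configuration value."""


class InputError(PromatchError):
    """Unusable input data (empty file, empty group, ...)."""


class SchemaError(PromatchError):
    """A required column or covariate is absent from the data."""


class PreconditionError(PromatchError):
    """An operation's stated precondition does not hold."""


class DesignError(PromatchError):
    """Rank-deficient or otherwise unusable design matrix."""


class SeparationError(PromatchError):
    """Perfect separation detected while fitting the propensity model."""


class OracleScopeError(PromatchError):
    """A brute-force verification was requested on a too-large instance."""


class CheckFailureError(PromatchError):
    """A specification or balance check failed while strict mode is on."""
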