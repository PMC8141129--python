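"""Exception hierarchy shared across the package."""


class ConfigError(ValueError):
    """Base class for configuration problems."""


class SchemaError(ConfigError):
    """A config file is structurally wrong: missing, unknown or mistyped keys."""


class ValidationError(ConfigError):
    """A value is outside its documented bounds or violates an invariant."""


class DomainError(ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ContractError(RuntimeError):
    """An operation was called in a state its contract forbids."""


class DistributionError(ValueError):
    """A sampling distribution is unusable (unknown family, endless rejections)."""
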