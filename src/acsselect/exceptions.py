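"""Exception hierarchy for acsselect."""


class AcsSelectError(Exception):
    """Base class for all package errors."""


class SchemaError(AcsSelectError):
    """A file or feature matrix does not match the covariate schema."""


class ValidationError(AcsSelectError):
    """Data values violate an invariant (e.g. non-binary entry)."""


class ConfigurationError(AcsSelectError):
    """An invalid configuration value or unknown option name."""


class DegenerateLabelsError(AcsSelectError):
    """An operation requiring both outcome classes saw only one."""
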