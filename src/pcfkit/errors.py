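"""Exception types shared across the pipeline stages."""


class PcfkitError(Exception):
    """Base class for all pcfkit errors."""


class InvalidInputError(PcfkitError, ValueError):
    """A value violates an operation's preconditions (bad dimension, empty input...)."""


class SchemaError(PcfkitError, ValueError):
    """A tabular input does not match its expected schema."""


class ConfigError(PcfkitError, ValueError):
    """A configuration value is missing or inconsistent."""
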