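"""Exception types shared across the package."""


class YieldcastError(Exception):
    """Base class for package errors."""


class ConfigError(YieldcastError):
    """Invalid configuration; the message names the offending field."""


class SchemaError(YieldcastError):
    """Tables/columns do not match the expected schema."""


class TrainingError(YieldcastError):
    """Model training failed (e.g. non-finite loss)."""
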