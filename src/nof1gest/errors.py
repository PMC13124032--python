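"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration field holds an invalid value; the message names the field."""


class SchemaError(ValueError):
    """An input table is missing a required column or holds malformed rows."""


class InsufficientDataError(ValueError):
    """A fit or test was requested on fewer points than its minimum.

    Carries a short machine-readable ``reason`` so cohort-level drivers can
    record skips instead of aborting.
    """

    def __init__(self, reason: str, message: str | None = None):
        super().__init__(message or reason)
        self.reason = reason
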