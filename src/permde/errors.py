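"""Exception types shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """A configuration value violates a documented bound."""


class EmptyResultError(RuntimeError):
    """An operation produced an empty result where data are required."""


class GmtParseError(ValueError):
    """A GMT gene-set file line could not be parsed."""
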