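"""Exception hierarchy shared across the pipeline stages."""


class PvdisproError(Exception):
    """Base class for all package errors."""


class ConfigError(PvdisproError):
    """Invalid configuration (bad probability, empty dictionary, ...)."""


class FormatError(PvdisproError):
    """A quarterly file does not conform to the expected dialect."""


class IntegrityError(PvdisproError):
    """Data violates a structural invariant (duplicate primaryid, negative cell)."""
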