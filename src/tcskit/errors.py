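"""Exception hierarchy shared across the toolkit."""


class TcskitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(TcskitError):
    """A file could not be parsed as the expected format."""


class ValidationError(TcskitError):
    """Parsed or supplied data violates an invariant."""
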