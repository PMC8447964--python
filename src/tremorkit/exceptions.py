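"""Exception hierarchy for tremorkit."""


class TremorkitError(Exception):
    """Base class for all tremorkit errors."""


class InputError(TremorkitError, ValueError):
    """Raised when input data violates an operation's preconditions."""


class ConfigurationError(TremorkitError, ValueError):
    """Raised when a parameter or plan violates its invariants."""


class ParseError(TremorkitError, ValueError):
    """Raised when a session container on disk is malformed."""
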