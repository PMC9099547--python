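"""Exception hierarchy.

Every error raised intentionally by this package derives from
:class:`FrailtyKitError`, so callers (and the CLI) can distinguish our
diagnostics from genuine bugs.
"""


class FrailtyKitError(Exception):
    """Base class for all frailtykit errors."""


class ParseError(FrailtyKitError):
    """A file could not be parsed (malformed timestamp, bad CSV row, ...)."""


class SchemaError(FrailtyKitError):
    """A record violates the data contract (payload/type mismatch, duplicate)."""


class UnknownRoomError(SchemaError):
    """A motion event carries a room label absent from the floor plan."""


class ContractError(FrailtyKitError):
    """A caller violated an operation precondition (e.g. unsorted events)."""


class ConfigError(FrailtyKitError):
    """Invalid or incomplete configuration."""


class DataError(FrailtyKitError):
    """The data is structurally valid but unusable for the requested analysis."""
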