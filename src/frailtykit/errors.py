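"""Exception hierarchy.

All errors raised deliberately by frailtykit derive from
:class:`FrailtykitError`, so callers can catch package failures with a
single except clause while letting genuine bugs propagate.
"""


class FrailtykitError(Exception):
    """Base class for all frailtykit errors."""


class ConfigurationError(FrailtykitError):
    """A configuration object or file violates its invariants."""


class DataError(FrailtykitError):
    """An input table violates its contract (bad cell, unparseable date, ...)."""


class MappingValidationError(FrailtykitError):
    """A deficit mapping fails partition/relation validation."""
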