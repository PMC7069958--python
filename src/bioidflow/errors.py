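"""Exception hierarchy.

All errors raised by this package derive from :class:`BioidError`, so callers
can catch one type at pipeline boundaries.
"""


class BioidError(Exception):
    """Base class for all bioidflow errors."""


class ConfigError(BioidError):
    """Invalid configuration (bad counts, unknown contrast, tissue mismatch...)."""


class SchemaError(BioidError):
    """Input file does not match the expected table schema."""


class ParseError(BioidError):
    """A cell of an input table could not be parsed; message carries row/column context."""


class DataError(BioidError):
    """Data are structurally valid but unusable for the requested computation."""
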