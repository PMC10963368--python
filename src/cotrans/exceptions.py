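"""Exception hierarchy shared by every stage.

All errors raised on purpose by cotrans derive from :class:`CotransError`,
so callers (and the CLI) can catch one base class and still distinguish
parse problems from validation and geometry failures.
"""


class CotransError(Exception):
    """Base class for all cotrans errors."""


class ParseError(CotransError):
    """A file does not conform to its declared format."""


class UnsupportedDialectError(ParseError):
    """The file uses a format feature outside the supported dialect
    (e.g. PDB insertion codes)."""


class EmptyInputError(ParseError):
    """A file parses but contains no usable records."""


class SchemaError(ParseError):
    """A tabular file is missing required columns or header declarations."""


class DuplicateKeyError(ParseError):
    """Two records share a key that must be unique."""


class ValidationError(CotransError):
    """An in-memory object violates a documented invariant."""


class ConfigError(ValidationError):
    """A configuration parameter is outside its valid range."""


class PlacementError(CotransError):
    """Toy-complex geometry constraints cannot be satisfied."""


class SuperpositionError(CotransError):
    """Least-squares superposition is undefined for the given atoms."""
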