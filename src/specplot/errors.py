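"""Exception hierarchy shared across the package.

All errors derive from :class:`SpecplotError` so callers (and the CLI) can
catch everything the library raises with one clause.  Parse-type errors carry
enough location information (byte offset, row index, line number) to point a
user at the offending part of their input file.
"""


class SpecplotError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(SpecplotError, ValueError):
    """Malformed input text (JSON or molfile)."""


class SchemaError(ParseError):
    """Input is structurally valid but does not match the documented schema."""


class SeriesConflictError(SpecplotError, KeyError):
    """A series name collides with one already in the dataset."""


class SeriesNotFoundError(SpecplotError, KeyError):
    """The named series is not in the dataset."""


class GroupNotFoundError(SpecplotError, KeyError):
    """The named annotation group does not exist."""


class ContractError(SpecplotError, ValueError):
    """A precondition of an internal stage was violated (e.g. unsorted input)."""


class MolfileDialectError(ParseError):
    """Molfile is a dialect this parser does not support (e.g. V3000)."""


class DegenerateGeometryError(SpecplotError, ValueError):
    """Molecule has no usable 2D coordinates (all atoms coincide)."""


class LayoutError(SpecplotError, ValueError):
    """Chart margins leave no drawable plot area."""
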