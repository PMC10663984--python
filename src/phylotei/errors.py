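"""Exception hierarchy.

All data-level failures raise a :class:`PhyloteiError` subclass so the CLI
can map them onto a single non-zero exit code; programming errors
(``TypeError`` etc.) are left alone.
"""


class PhyloteiError(Exception):
    """Base class for all data and configuration errors."""


class ParseError(PhyloteiError):
    """A record in an input file could not be parsed; the message names it."""


class StructureError(PhyloteiError):
    """Parsed data violates a structural invariant (multiple roots, cycles, duplicates)."""


class ConfigError(PhyloteiError):
    """Inconsistent arguments: missing species↔taxid entries, unknown tags, key collisions."""


class SchemaError(PhyloteiError):
    """A tabular input lacks a mandatory column."""


class TaxidNotFoundError(PhyloteiError, KeyError):
    """A taxid was looked up that is absent from the taxonomy."""
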