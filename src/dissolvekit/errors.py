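"""Exception hierarchy for dissolvekit.

Every error raised by the library derives from :class:`DissolveKitError`
so callers (and the CLI) can catch one type and map it to a nonzero exit.
"""


class DissolveKitError(Exception):
    """Base class for all dissolvekit errors."""


class FormatError(DissolveKitError):
    """Input table does not match the expected schema (names the column)."""


class ParseError(DissolveKitError):
    """A cell could not be parsed as a number (names the row)."""


class GridMismatchError(DissolveKitError):
    """Profiles in one study do not share the same sampling-time grid."""


class ComparisonError(DissolveKitError):
    """f1/f2 inputs are unusable (length mismatch, zero reference sum)."""


class QuantitationError(DissolveKitError):
    """Peak-area quantitation cannot proceed (e.g. non-positive standard area)."""


class GenerationError(DissolveKitError):
    """Synthetic generation failed (e.g. profile implies negative concentration)."""
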