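"""Exception hierarchy.

``CSCDecoderError`` maps to CLI exit code 2 (data error); click usage
errors map to exit code 1.
"""


class CSCDecoderError(Exception):
    """Base class for all data-level errors raised by this package."""


class ParseError(CSCDecoderError):
    """Malformed EvoPrint or sequence input."""


class ConstraintError(CSCDecoderError):
    """A search constraint violates its invariants (e.g. element < 6 bp)."""


class UndefinedScoreError(CSCDecoderError):
    """A score is requested on degenerate input (e.g. zero conserved bases)."""


class GenerationError(CSCDecoderError):
    """The synthetic generator could not satisfy a plant specification."""


class DatabaseError(CSCDecoderError):
    """Database construction or lookup failure (e.g. duplicate CSC names)."""
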