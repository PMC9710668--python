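"""Exception hierarchy.

Every user-facing failure raises a subclass of :class:`AlnmarkError` so the
CLI can turn any library error into a single diagnostic line and a nonzero
exit code.
"""


class AlnmarkError(Exception):
    """Base class for all errors raised by this package."""


class FastaParseError(AlnmarkError):
    """Input is not parseable FASTA (empty, leading junk, bad characters)."""


class RaggedAlignmentError(AlnmarkError):
    """Records in a putative alignment do not share one gapped length."""


class SelectorError(AlnmarkError):
    """A sequence selector is ambiguous or matches nothing."""


class PositionError(AlnmarkError):
    """A 1-based position or column is outside its valid range."""


class AnnotationError(AlnmarkError):
    """An annotation document fails schema or binding validation."""


class TokenError(AlnmarkError):
    """A change token does not match the supported HGVS-like forms."""


class SchemeError(AlnmarkError):
    """Unknown colour-scheme name."""


class RenderError(AlnmarkError):
    """A render plan cannot be satisfied (empty window, nothing to draw)."""


class FixtureError(AlnmarkError):
    """A synthetic-fixture specification is infeasible."""
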