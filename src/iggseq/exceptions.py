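"""Exception hierarchy for iggseq.

All errors raised by the package derive from :class:`IggSeqError` so callers
can catch everything with one clause while still distinguishing format
problems from scientific/degenerate-input problems.
"""


class IggSeqError(Exception):
    """Base class for all iggseq errors."""


class FormatError(IggSeqError):
    """A file or table does not conform to the expected layout."""


class ValidationError(IggSeqError):
    """A value violates a domain invariant (negative count, bad proportion...)."""


class AlignmentError(IggSeqError):
    """Taxon or sample identifiers do not line up across tables."""


class EmptyFractionError(IggSeqError):
    """A sorted fraction has zero probability mass but reads were requested."""


class DegenerateTestError(IggSeqError):
    """A statistical test is undefined for the given data (e.g. zero variance)."""
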