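"""Exception hierarchy.

Every error raised on user input derives from :class:`TruncvarError` so the
CLI can map validation failures to a single exit code.
"""

from __future__ import annotations


class TruncvarError(Exception):
    """Base class for all package errors."""


class ValidationError(TruncvarError):
    """Malformed input object (bad interval, inconsistent transcript, ...)."""


class NotExonicError(TruncvarError):
    """Genomic position falls in an intron or outside the transcript.

    ``upstream_exon`` / ``downstream_exon`` carry the 0-based indices (in
    transcription order) of the exons flanking the position, or ``None`` when
    the position lies beyond the corresponding end of the transcript.
    """

    def __init__(self, message: str, upstream_exon: int | None = None,
                 downstream_exon: int | None = None):
        super().__init__(message)
        self.upstream_exon = upstream_exon
        self.downstream_exon = downstream_exon


class NonCodingPositionError(TruncvarError):
    """cDNA position outside the ORF; ``utr`` is ``"5'UTR"`` or ``"3'UTR"``."""

    def __init__(self, message: str, utr: str):
        super().__init__(message)
        self.utr = utr


class UnsupportedSpanError(TruncvarError):
    """Variant spans an ORF boundary or an exon junction."""


class NonStopSubstitutionError(TruncvarError):
    """SNV does not create a stop codon (outside this pipeline's scope)."""


class SequenceRequiredError(TruncvarError):
    """Operation needs the cDNA sequence but the transcript carries none."""


class EmptyFragmentError(TruncvarError):
    """Truncation leaves no residues to evaluate."""


class IncompleteEvidenceError(TruncvarError):
    """Classifier is missing a required piece of evidence.

    ``missing`` names the absent input (e.g. ``"exposure"``, ``"nmd"``).
    """

    def __init__(self, message: str, missing: str):
        super().__init__(message)
        self.missing = missing
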