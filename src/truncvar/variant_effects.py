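"""Variant classification and protein-level consequence derivation.

Coding variants are grouped into three classes: nonsense SNVs (a sense codon
mutated to a stop), frameshifting indels (net length change not a multiple
of 3), and in-frame indels.  For frameshifts the edited cDNA is re-translated
from the start codon in the shifted frame and the first stop codon at or
after the edit is reported; scanning continues through the former 3'UTR
because the shifted frame ignores the original stop.  A frameshift with no
stop anywhere before the transcript end carries ``stop_codon_index = None``
("read-through").

In-frame insertions whose inserted sequence contains an in-register stop
triplet truncate translation exactly like a premature termination and get
their stop fields populated; out-of-register stop triplets inside inserted
sequence are invisible to the ribosome and are ignored.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from Bio.Seq import Seq

from . import gene_model
from .errors import (
    NonStopSubstitutionError,
    SequenceRequiredError,
    TruncvarError,
    UnsupportedSpanError,
    ValidationError,
)
from .gene_model import TranscriptModel, cdna_to_codon, genomic_to_cdna

__all__ = [
    "VariantClass",
    "VariantRecord",
    "ProteinConsequence",
    "classify_variant",
    "derive_consequence",
    "read_variants_tsv",
    "read_variants_vcf",
    "normalize_alleles",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class VariantClass(str, Enum):
    NONSENSE_SNP = "NONSENSE_SNP"
    FRAMESHIFT_INDEL = "FRAMESHIFT_INDEL"
    INFRAME_INDEL = "INFRAME_INDEL"


@dataclass(frozen=True)
class VariantRecord:
    """A coding variant in cDNA coordinates.

    ``ref_allele``/``alt_allele`` are minimal (no shared anchor bases); an
    empty ``ref_allele`` denotes a pure insertion occurring immediately
    before ``cdna_start``, an empty ``alt_allele`` a pure deletion of
    ``[cdna_start, cdna_end]``.
    """

    id: str
    transcript_id: str
    cdna_start: int
    cdna_end: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.cdna_start > self.cdna_end and self.ref_allele:
            raise ValidationError(f"variant {self.id}: start > end")
        if self.ref_allele and len(self.ref_allele) != self.cdna_end - self.cdna_start + 1:
            raise ValidationError(
                f"variant {self.id}: ref allele length does not match span")

    @property
    def net_length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass(frozen=True)
class ProteinConsequence:
    variant_class: VariantClass
    stop_codon_index: int | None = None
    stop_cdna_last_nt: int | None = None
    frameshift_codon_index: int | None = None
    inframe_span: tuple[int, int] | None = None
    inframe_residue_delta: int = 0

    @property
    def has_premature_stop(self) -> bool:
        return self.stop_codon_index is not None

    @property
    def truncation_codon(self) -> int | None:
        """Codon where native structure ends: the stop for nonsense SNVs and
        in-register inserted stops, the divergence point for frameshifts."""
        if self.variant_class is VariantClass.FRAMESHIFT_INDEL:
            return self.frameshift_codon_index
        return self.stop_codon_index


def _check_within_orf(v: VariantRecord, t: TranscriptModel) -> None:
    lo = v.cdna_start
    hi = v.cdna_end if v.ref_allele else v.cdna_start
    if hi < t.orf_start or lo > t.orf_end:
        raise TruncvarError(
            f"variant {v.id} lies outside the ORF of {t.id} (non-coding variant)")
    if lo < t.orf_start or hi > t.orf_end:
        raise UnsupportedSpanError(
            f"variant {v.id} spans the ORF boundary of {t.id}")


def classify_variant(v: VariantRecord, t: TranscriptModel) -> VariantClass:
    """Assign one of the three variant classes.

    SNVs must create a stop codon; other substitutions are outside this
    pipeline's scope and raise :class:`NonStopSubstitutionError`.
    """
    _check_within_orf(v, t)
    if v.is_snv:
        if t.cdna_sequence is not None and \
                t.cdna_sequence[v.cdna_start - 1] != v.ref_allele:
            raise ValidationError(
                f"variant {v.id}: ref allele {v.ref_allele} does not match "
                f"transcript sequence at {v.cdna_start}")
        if t.cdna_sequence is None:
            raise SequenceRequiredError(
                f"variant {v.id}: sequence needed to evaluate the alt codon")
        cp = cdna_to_codon(v.cdna_start, t)
        codon_start = gene_model.codon_to_cdna(cp.codon, t)
        codon = list(t.cdna_sequence[codon_start - 1:codon_start + 2])
        codon[cp.offset - 1] = v.alt_allele
        if "".join(codon) in STOP_CODONS:
            return VariantClass.NONSENSE_SNP
        raise NonStopSubstitutionError(
            f"variant {v.id}: substitution yields codon {''.join(codon)}, not a stop")
    if v.ref_allele and t.cdna_sequence is not None:
        observed = t.cdna_sequence[v.cdna_start - 1:v.cdna_end]
        if observed != v.ref_allele:
            raise ValidationError(
                f"variant {v.id}: ref allele {v.ref_allele} != transcript "
                f"sequence {observed} at [{v.cdna_start},{v.cdna_end}]")
    if v.net_length_change % 3:
        return VariantClass.FRAMESHIFT_INDEL
    return VariantClass.INFRAME_INDEL


def apply_edit(cdna: str, v: VariantRecord) -> str:
    """Return the edited cDNA sequence."""
    if v.ref_allele:
        return cdna[:v.cdna_start - 1] + v.alt_allele + cdna[v.cdna_end:]
    return cdna[:v.cdna_start - 1] + v.alt_allele + cdna[v.cdna_start - 1:]


def _first_stop_from(seq: str, orf_start: int, min_codon: int) -> int | None:
    """1-based index of the first stop codon at or after ``min_codon`` when
    translating ``seq`` from ``orf_start`` to the end of the sequence."""
    i = orf_start - 1 + 3 * (min_codon - 1)
    codon_index = min_codon
    while i + 3 <= len(seq):
        if seq[i:i + 3] in STOP_CODONS:
            return codon_index
        i += 3
        codon_index += 1
    return None


def derive_consequence(v: VariantRecord, t: TranscriptModel) -> ProteinConsequence:
    """Derive the protein-level consequence of a classified variant."""
    vclass = classify_variant(v, t)

    if vclass is VariantClass.NONSENSE_SNP:
        cp = cdna_to_codon(v.cdna_start, t)
        last_nt = t.orf_start + 3 * cp.codon - 1
        return ProteinConsequence(
            variant_class=vclass,
            stop_codon_index=cp.codon,
            stop_cdna_last_nt=last_nt,
        )

    first_pos = v.cdna_start
    first_codon = cdna_to_codon(first_pos, t).codon

    if vclass is VariantClass.FRAMESHIFT_INDEL:
        if t.cdna_sequence is None:
            raise SequenceRequiredError(
                f"variant {v.id}: cDNA sequence required for frameshift scanning")
        edited = apply_edit(t.cdna_sequence, v)
        stop = _first_stop_from(edited, t.orf_start, first_codon)
        last_nt = t.orf_start + 3 * stop - 1 if stop is not None else None
        return ProteinConsequence(
            variant_class=vclass,
            frameshift_codon_index=first_codon,
            stop_codon_index=stop,
            stop_cdna_last_nt=last_nt,
        )

    # In-frame indel.
    delta = v.net_length_change // 3
    if v.ref_allele:
        last_codon = cdna_to_codon(v.cdna_end, t).codon
    else:
        last_codon = first_codon
    stop = None
    last_nt = None
    if t.cdna_sequence is not None:
        edited = apply_edit(t.cdna_sequence, v)
        # Only an in-register stop introduced by the edit truncates; scan the
        # edited in-frame codons up to the (shifted) original stop codon.
        orig_stop_codon = (t.orf_end - t.orf_start + 1) // 3 + delta
        cand = _first_stop_from(edited, t.orf_start, first_codon)
        if cand is not None and cand < orig_stop_codon:
            stop = cand
            last_nt = t.orf_start + 3 * cand - 1
    return ProteinConsequence(
        variant_class=vclass,
        inframe_span=(first_codon, last_codon),
        inframe_residue_delta=delta,
        stop_codon_index=stop,
        stop_cdna_last_nt=last_nt,
    )


# ---------------------------------------------------------------------------
# readers


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Strip shared suffix then prefix from a VCF allele pair.

    Returns the minimal ``(pos, ref, alt)``; for pure indels one side becomes
    empty and ``pos`` is the first position of the remaining ref (for
    deletions) or the anchor position preceding the insertion point (for
    insertions, where ref is empty).
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and \
            not (len(ref) == 1 and len(alt) == 1):
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 0 and len(alt) > 0 and ref[0] == alt[0] and \
            not (len(ref) == 1 and len(alt) == 1):
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if not ref:
        pos -= 1  # anchor: insertion occurs between pos and pos+1
    return pos, ref, alt


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Read the direct cDNA-space dialect: transcript_id, cdna_start,
    cdna_end, ref, alt (with optional leading id column header)."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(VariantRecord(
                id=row.get("id") or f"var{len(out) + 1}",
                transcript_id=row["transcript_id"],
                cdna_start=int(row["cdna_start"]),
                cdna_end=int(row["cdna_end"]),
                ref_allele=row["ref"].strip("-"),
                alt_allele=row["alt"].strip("-"),
            ))
    return out


def project_vcf_alleles(chrom: str, pos: int, ref: str, alt: str,
                        t: TranscriptModel) -> VariantRecord | None:
    """Project one normalized genomic allele pair onto a transcript.

    Returns ``None`` when the variant does not touch the transcript's exons.
    Minus-strand transcripts get reverse-complemented alleles and flipped
    coordinates.  A deletion spanning an exon junction raises
    :class:`UnsupportedSpanError` (such inputs are out of scope).
    """
    if chrom != t.chrom:
        return None
    rc = gene_model.reverse_complement
    if ref and alt and len(ref) == 1 and len(alt) == 1:  # SNV
        try:
            cp = genomic_to_cdna(pos, t).pos
        except TruncvarError:
            return None
        if t.strand == "-":
            ref, alt = rc(ref), rc(alt)
        return VariantRecord("", t.id, cp, cp, ref, alt)
    if not alt:  # deletion of genomic [pos, pos+len(ref)-1]
        g_lo, g_hi = pos, pos + len(ref) - 1
        try:
            c_lo = genomic_to_cdna(g_lo, t).pos
            c_hi = genomic_to_cdna(g_hi, t).pos
        except TruncvarError:
            if any(e.contains(g_lo) or e.contains(g_hi) for e in t.exons):
                raise UnsupportedSpanError(
                    f"deletion at {chrom}:{pos} spans an exon junction of {t.id}")
            return None
        cs, ce = (c_lo, c_hi) if t.strand == "+" else (c_hi, c_lo)
        if ce - cs != g_hi - g_lo:
            raise UnsupportedSpanError(
                f"deletion at {chrom}:{pos} spans an exon junction of {t.id}")
        return VariantRecord("", t.id, cs, ce,
                             ref if t.strand == "+" else rc(ref), "")
    if not ref:  # insertion between pos and pos+1
        try:
            c_anchor = genomic_to_cdna(pos, t).pos
        except TruncvarError:
            return None
        if t.strand == "+":
            cstart = c_anchor + 1
            ins = alt
        else:
            cstart = c_anchor
            ins = rc(alt)
        return VariantRecord("", t.id, cstart, cstart, "", ins)
    raise ValidationError(f"unnormalized allele pair {ref}>{alt} at {chrom}:{pos}")


def read_variants_vcf(path: str | Path,
                      transcripts: dict[str, TranscriptModel],
                      ) -> list[VariantRecord]:
    """Read a VCF and project each alt allele onto every overlapping
    transcript; multi-allelic records are split per alt allele."""
    import pysam

    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts.values():
        by_chrom.setdefault(t.chrom, []).append(t)

    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for ai, alt in enumerate(rec.alts or ()):
                pos, ref, alt_n = normalize_alleles(rec.pos, rec.ref, alt)
                vid = rec.id or f"{rec.chrom}:{rec.pos}"
                if len(rec.alts) > 1:
                    vid = f"{vid}.{ai + 1}"
                for t in by_chrom.get(rec.chrom, ()):
                    pv = project_vcf_alleles(rec.chrom, pos, ref, alt_n, t)
                    if pv is not None:
                        out.append(VariantRecord(vid, t.id, pv.cdna_start,
                                                 pv.cdna_end, pv.ref_allele,
                                                 pv.alt_allele))
    return out


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string (Biopython, standard code)."""
    trimmed = seq[:len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())
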