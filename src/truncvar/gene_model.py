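"""Transcript models and genome / cDNA / codon coordinate conversion.

A :class:`TranscriptModel` stores exons in transcription order (5'→3' on the
mRNA) together with the annotated ORF on the cDNA.  All coordinates are
1-based inclusive: genomic intervals follow the GFF3 convention, cDNA
positions count exonic nucleotides from the transcription start, and codon
indices count from the start codon.

Minus-strand transcripts keep their cDNA sequence in mRNA sense (reverse
complement of the genome), so everything downstream of coordinate mapping is
strand-agnostic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import NonCodingPositionError, NotExonicError, ValidationError

__all__ = [
    "GenomeInterval",
    "TranscriptModel",
    "CdnaPosition",
    "CodonPosition",
    "genomic_to_cdna",
    "cdna_to_genomic",
    "cdna_to_codon",
    "last_junction_cdna",
    "read_transcripts_gff3",
    "read_transcripts_bed12",
    "read_cdna_fasta",
]


@dataclass(frozen=True)
class GenomeInterval:
    """1-based inclusive genomic interval on a single strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"interval start {self.start} > end {self.end} on {self.chrom}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class CdnaPosition:
    transcript_id: str
    pos: int


@dataclass(frozen=True)
class CodonPosition:
    """1-based codon index plus within-codon offset (1, 2 or 3)."""

    codon: int
    offset: int


@dataclass
class TranscriptModel:
    """Exon structure plus ORF annotation for one transcript.

    ``exons`` are in transcription order: ascending genomic coordinates on
    the plus strand, descending on the minus strand.  ``orf_start`` /
    ``orf_end`` are 1-based cDNA positions of the first nucleotide of the
    start codon and the last nucleotide of the stop codon.  ``cdna_sequence``
    (mRNA sense) is optional but required for frameshift scanning.
    """

    id: str
    exons: tuple[GenomeInterval, ...]
    orf_start: int
    orf_end: int
    cdna_sequence: str | None = None
    _cum: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.exons = tuple(self.exons)
        if not self.exons:
            raise ValidationError(f"transcript {self.id} has no exons")
        strand = self.exons[0].strand
        chrom = self.exons[0].chrom
        for e in self.exons:
            if e.strand != strand or e.chrom != chrom:
                raise ValidationError(
                    f"transcript {self.id}: exons mix chromosomes or strands")
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end >= b.start:
                raise ValidationError(f"transcript {self.id}: overlapping exons")
        expected = ordered if strand == "+" else ordered[::-1]
        if tuple(expected) != self.exons:
            raise ValidationError(
                f"transcript {self.id}: exons not in transcription order")
        cum = []
        total = 0
        for e in self.exons:
            total += len(e)
            cum.append(total)
        self._cum = tuple(cum)
        if not (1 <= self.orf_start < self.orf_end <= self.cdna_length):
            raise ValidationError(
                f"transcript {self.id}: ORF [{self.orf_start},{self.orf_end}] "
                f"outside cDNA of length {self.cdna_length}")
        if (self.orf_end - self.orf_start + 1) % 3:
            raise ValidationError(
                f"transcript {self.id}: ORF length not divisible by 3")
        if self.cdna_sequence is not None:
            self.cdna_sequence = self.cdna_sequence.upper()
            if len(self.cdna_sequence) != self.cdna_length:
                raise ValidationError(
                    f"transcript {self.id}: sequence length "
                    f"{len(self.cdna_sequence)} != exon total {self.cdna_length}")

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def cdna_length(self) -> int:
        return self._cum[-1]

    @property
    def n_codons(self) -> int:
        """Number of codons in the ORF including the stop codon."""
        return (self.orf_end - self.orf_start + 1) // 3

    @property
    def protein_length(self) -> int:
        """Residue count of the translated product (stop codon excluded)."""
        return self.n_codons - 1

    def orf_sequence(self) -> str:
        if self.cdna_sequence is None:
            raise ValidationError(f"transcript {self.id} carries no sequence")
        return self.cdna_sequence[self.orf_start - 1:self.orf_end]


def genomic_to_cdna(g: int, t: TranscriptModel) -> CdnaPosition:
    """Map a genomic position to its 1-based cDNA position.

    Counts exonic nucleotides in transcription order; on the minus strand
    counting starts at the highest genomic coordinate of the first exon.
    Raises :class:`NotExonicError` for intronic / flanking positions, with
    the indices of the flanking exons attached.
    """
    offset = 0
    for i, exon in enumerate(t.exons):
        if exon.contains(g):
            if t.strand == "+":
                return CdnaPosition(t.id, offset + (g - exon.start + 1))
            return CdnaPosition(t.id, offset + (exon.end - g + 1))
        offset += len(exon)
    # Not exonic: identify flanking exons in transcription order.
    upstream = downstream = None
    for i, exon in enumerate(t.exons):
        before = g < exon.start if t.strand == "+" else g > exon.end
        if before:
            downstream = i
            upstream = i - 1 if i > 0 else None
            break
    else:
        upstream = len(t.exons) - 1
    raise NotExonicError(
        f"position {g} is not exonic in transcript {t.id}",
        upstream_exon=upstream, downstream_exon=downstream)


def cdna_to_genomic(p: int, t: TranscriptModel) -> int:
    """Inverse of :func:`genomic_to_cdna` (used for round-trips and VCF I/O)."""
    if not 1 <= p <= t.cdna_length:
        raise ValidationError(
            f"cDNA position {p} outside transcript {t.id} (length {t.cdna_length})")
    prev = 0
    for exon, cum in zip(t.exons, t._cum):
        if p <= cum:
            within = p - prev  # 1-based offset inside this exon
            if t.strand == "+":
                return exon.start + within - 1
            return exon.end - within + 1
        prev = cum
    raise AssertionError("unreachable")


def cdna_to_codon(p: int, t: TranscriptModel) -> CodonPosition:
    """Codon index and within-codon offset for an ORF cDNA position."""
    if p < t.orf_start:
        raise NonCodingPositionError(
            f"cDNA position {p} is 5' of the ORF of {t.id}", utr="5'UTR")
    if p > t.orf_end:
        raise NonCodingPositionError(
            f"cDNA position {p} is 3' of the ORF of {t.id}", utr="3'UTR")
    rel = p - t.orf_start
    return CodonPosition(codon=rel // 3 + 1, offset=rel % 3 + 1)


def codon_to_cdna(codon: int, t: TranscriptModel) -> int:
    """cDNA position of the first nucleotide of a 1-based codon index."""
    return t.orf_start + 3 * (codon - 1)


def last_junction_cdna(t: TranscriptModel) -> int | None:
    """cDNA position of the last nucleotide of the penultimate exon.

    ``None`` for single-exon transcripts, which have no junction.
    """
    if len(t.exons) < 2:
        return None
    return t._cum[-2]


# ---------------------------------------------------------------------------
# readers


def read_cdna_fasta(path: str | Path) -> dict[str, str]:
    """Load cDNA sequences keyed by transcript id (first word of the header)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_transcripts_gff3(path: str | Path,
                          fasta_path: str | Path | None = None,
                          ) -> dict[str, TranscriptModel]:
    """Read transcripts from GFF3 (mRNA/exon/CDS features).

    The ORF is derived from the CDS features projected into cDNA space, and
    therefore includes the stop codon (the emitter is expected to include it,
    as this package's own writer does).  Sequences, when ``fasta_path`` is
    given, are keyed by transcript id and must be in mRNA sense.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    seqs = read_cdna_fasta(fasta_path) if fasta_path else {}
    out: dict[str, TranscriptModel] = {}
    for mrna in db.features_of_type("mRNA"):
        exon_feats = sorted(db.children(mrna, featuretype="exon"),
                            key=lambda f: f.start)
        cds_feats = sorted(db.children(mrna, featuretype="CDS"),
                           key=lambda f: f.start)
        if not exon_feats or not cds_feats:
            raise ValidationError(f"mRNA {mrna.id} lacks exon or CDS features")
        strand = mrna.strand
        intervals = [GenomeInterval(mrna.seqid, f.start, f.end, strand)
                     for f in exon_feats]
        if strand == "-":
            intervals = intervals[::-1]
        t = TranscriptModel(id=mrna.id, exons=tuple(intervals),
                            orf_start=1, orf_end=3,  # placeholder, fixed below
                            cdna_sequence=None)
        # Project the CDS span into cDNA coordinates.
        g_lo, g_hi = cds_feats[0].start, cds_feats[-1].end
        first_g = g_hi if strand == "-" else g_lo
        last_g = g_lo if strand == "-" else g_hi
        orf_start = genomic_to_cdna(first_g, t).pos
        orf_end = genomic_to_cdna(last_g, t).pos
        out[mrna.id] = TranscriptModel(
            id=mrna.id, exons=tuple(intervals),
            orf_start=orf_start, orf_end=orf_end,
            cdna_sequence=seqs.get(mrna.id))
    return out


def read_transcripts_bed12(path: str | Path,
                           fasta_path: str | Path | None = None,
                           ) -> dict[str, TranscriptModel]:
    """Read transcripts from BED12; the thick interval is taken as the ORF."""
    seqs = read_cdna_fasta(fasta_path) if fasta_path else {}
    out: dict[str, TranscriptModel] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith(("#", "track", "browser")):
                continue
            chrom, chrom_start, _chrom_end, name = row[0], int(row[1]), int(row[2]), row[3]
            strand = row[5]
            thick_start, thick_end = int(row[6]), int(row[7])
            n_blocks = int(row[9])
            sizes = [int(x) for x in row[10].rstrip(",").split(",")]
            starts = [int(x) for x in row[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValidationError(f"BED12 record {name}: block count mismatch")
            intervals = [
                GenomeInterval(chrom, chrom_start + s + 1, chrom_start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
            if strand == "-":
                intervals = intervals[::-1]
            t = TranscriptModel(id=name, exons=tuple(intervals),
                                orf_start=1, orf_end=3, cdna_sequence=None)
            first_g = thick_end if strand == "-" else thick_start + 1
            last_g = thick_start + 1 if strand == "-" else thick_end
            orf_start = genomic_to_cdna(first_g, t).pos
            orf_end = genomic_to_cdna(last_g, t).pos
            out[name] = TranscriptModel(id=name, exons=tuple(intervals),
                                        orf_start=orf_start, orf_end=orf_end,
                                        cdna_sequence=seqs.get(name))
    return out


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def exonic_positions(t: TranscriptModel) -> Iterable[int]:
    """Genomic positions of the transcript's exonic nucleotides, 5'→3'."""
    for exon in t.exons:
        rng = (range(exon.start, exon.end + 1) if t.strand == "+"
               else range(exon.end, exon.start - 1, -1))
        yield from rng
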