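"""Coordinate conversion between genome, cDNA and codon spaces."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from truncvar.errors import NonCodingPositionError, NotExonicError, \
    ValidationError
from truncvar.gene_model import (
    GenomeInterval,
    TranscriptModel,
    cdna_to_codon,
    cdna_to_genomic,
    exonic_positions,
    genomic_to_cdna,
    last_junction_cdna,
    read_transcripts_bed12,
    read_transcripts_gff3,
)


def tx(exons, orf=(1, 3), seq=None, tid="T1"):
    return TranscriptModel(id=tid, exons=tuple(exons), orf_start=orf[0],
                           orf_end=orf[1], cdna_sequence=seq)


def plus(start, end):
    return GenomeInterval("chr1", start, end, "+")


def minus(start, end):
    return GenomeInterval("chr1", start, end, "-")


class TestGenomicToCdna:
    def test_two_exon_plus_strand(self):
        t = tx([plus(101, 200), plus(301, 400)])
        assert genomic_to_cdna(350, t).pos == 150

    def test_single_exon_identity(self):
        t = tx([plus(1, 300)])
        assert genomic_to_cdna(7, t).pos == 7

    def test_minus_strand_counts_from_transcription_start(self):
        # oracle: enumerate exonic positions in transcription order
        t = tx([minus(301, 400), minus(101, 200)])
        order = list(exonic_positions(t))
        assert genomic_to_cdna(395, t).pos == order.index(395) + 1 == 6

    def test_intronic_position_reports_flanking_exons(self):
        t = tx([plus(101, 200), plus(301, 400)])
        with pytest.raises(NotExonicError) as exc:
            genomic_to_cdna(250, t)
        assert exc.value.upstream_exon == 0
        assert exc.value.downstream_exon == 1

    @given(st.data())
    def test_round_trip_and_monotonicity(self, data):
        n_exons = data.draw(st.integers(1, 5))
        strand = data.draw(st.sampled_from("+-"))
        cursor = data.draw(st.integers(1, 1000))
        exons = []
        for _ in range(n_exons):
            length = data.draw(st.integers(6, 50))
            exons.append(GenomeInterval("chrZ", cursor, cursor + length - 1,
                                        strand))
            cursor += length + data.draw(st.integers(10, 100))
        if strand == "-":
            exons = exons[::-1]
        total = sum(len(e) for e in exons)
        t = tx(exons, orf=(1, 3 * (total // 3 - 1)))
        seen = []
        for g in exonic_positions(t):
            p = genomic_to_cdna(g, t).pos
            assert cdna_to_genomic(p, t) == g
            seen.append(p)
        # bijection onto 1..cdna_length, strictly increasing along the mRNA
        assert seen == list(range(1, t.cdna_length + 1))


class TestCdnaToCodon:
    @pytest.mark.parametrize("orf_start,p,codon,offset", [
        (10, 10, 1, 1),
        (10, 18, 3, 3),
        (1, 100, 34, 1),
    ])
    def test_codon_arithmetic(self, orf_start, p, codon, offset):
        t = tx([plus(1, 200)], orf=(orf_start, orf_start + 119))
        cp = cdna_to_codon(p, t)
        assert (cp.codon, cp.offset) == (codon, offset)

    def test_codon_arithmetic_matches_walk(self):
        # brute-force oracle: walk the ORF in steps of 3
        t = tx([plus(1, 200)], orf=(1, 150))
        walk = {}
        codon = 0
        for p in range(1, 151):
            if (p - 1) % 3 == 0:
                codon += 1
            walk[p] = (codon, (p - 1) % 3 + 1)
        for p in (1, 2, 3, 4, 50, 99, 100, 150):
            cp = cdna_to_codon(p, t)
            assert (cp.codon, cp.offset) == walk[p]

    def test_utr_positions_rejected_with_side(self):
        t = tx([plus(1, 200)], orf=(31, 150))
        with pytest.raises(NonCodingPositionError) as e5:
            cdna_to_codon(10, t)
        assert e5.value.utr == "5'UTR"
        with pytest.raises(NonCodingPositionError) as e3:
            cdna_to_codon(180, t)
        assert e3.value.utr == "3'UTR"


class TestLastJunction:
    def test_three_exons(self):
        t = tx([plus(1, 300), plus(401, 600), plus(701, 800)])
        assert last_junction_cdna(t) == 500

    def test_single_exon_has_none(self):
        assert last_junction_cdna(tx([plus(1, 300)])) is None

    def test_two_exons(self):
        t = tx([plus(1, 50), plus(101, 150)])
        assert last_junction_cdna(t) == 50

    def test_junction_before_transcript_end(self):
        t = tx([plus(1, 300), plus(401, 600), plus(701, 800)])
        assert last_junction_cdna(t) < t.cdna_length


class TestValidation:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValidationError):
            tx([plus(1, 100), plus(50, 200)])

    def test_orf_not_multiple_of_three_rejected(self):
        with pytest.raises(ValidationError):
            tx([plus(1, 100)], orf=(1, 5))

    def test_wrong_transcription_order_rejected(self):
        with pytest.raises(ValidationError):
            tx([plus(301, 400), plus(101, 200)])  # + strand, descending


class TestReaders:
    def test_gff3_reader_matches_corpus_truth(self, corpus, truth):
        transcripts = read_transcripts_gff3(corpus["gff3"], corpus["fasta"])
        assert len(transcripts) == len(truth)
        for t in transcripts.values():
            assert (t.orf_end - t.orf_start + 1) % 3 == 0
            assert t.cdna_sequence is not None
            assert t.orf_sequence().startswith("ATG")
            assert t.orf_sequence()[-3:] == "TAA"

    def test_bed12_round_trip(self, tmp_path):
        # same transcript expressed in GFF3 and BED12 must load identically
        gff = tmp_path / "t.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t101\t400\t.\t-\t.\tID=g1\n"
            "chr1\tx\tmRNA\t101\t400\t.\t-\t.\tID=m1;Parent=g1\n"
            "chr1\tx\texon\t101\t200\t.\t-\t.\tID=m1.e2;Parent=m1\n"
            "chr1\tx\texon\t301\t400\t.\t-\t.\tID=m1.e1;Parent=m1\n"
            "chr1\tx\tCDS\t150\t200\t.\t-\t0\tID=m1.c;Parent=m1\n"
            "chr1\tx\tCDS\t301\t390\t.\t-\t0\tID=m1.c;Parent=m1\n")
        bed = tmp_path / "t.bed"
        # blockStarts relative to chromStart 100; thick = CDS genomic hull
        bed.write_text("chr1\t100\t400\tm1\t0\t-\t149\t390\t0\t2\t100,100\t0,200\n")
        t_gff = read_transcripts_gff3(gff)["m1"]
        t_bed = read_transcripts_bed12(bed)["m1"]
        assert t_gff.exons == t_bed.exons
        assert (t_gff.orf_start, t_gff.orf_end) == \
            (t_bed.orf_start, t_bed.orf_end)
        # minus strand: ORF starts at the highest genomic CDS coordinate
        assert genomic_to_cdna(390, t_gff).pos == t_gff.orf_start
        assert t_gff.orf_end - t_gff.orf_start + 1 == 141
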