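"""Variant classification and consequence derivation, checked against a
brute-force translation oracle."""

import numpy as np
import pytest

from helpers import oracle_first_stop
from truncvar.errors import NonStopSubstitutionError, SequenceRequiredError, \
    TruncvarError, UnsupportedSpanError
from truncvar.gene_model import GenomeInterval, TranscriptModel
from truncvar.variant_effects import (
    VariantClass,
    VariantRecord,
    apply_edit,
    classify_variant,
    derive_consequence,
    normalize_alleles,
    read_variants_vcf,
)


def make_tx(seq, orf_start=1, orf_end=None, tid="T1"):
    orf_end = orf_end if orf_end is not None else len(seq)
    return TranscriptModel(
        id=tid,
        exons=(GenomeInterval("chr1", 1, len(seq), "+"),),
        orf_start=orf_start, orf_end=orf_end, cdna_sequence=seq)


class TestClassify:
    def test_snv_to_stop_is_nonsense(self):
        t = make_tx("ATGTACCCCTAA")  # codon 2 = TAC
        v = VariantRecord("v", "T1", 6, 6, "C", "A")  # TAC -> TAA
        assert classify_variant(v, t) is VariantClass.NONSENSE_SNP

    def test_non_stop_snv_rejected(self):
        t = make_tx("ATGTACCCCTAA")
        v = VariantRecord("v", "T1", 6, 6, "C", "T")  # TAC -> TAT (Tyr)
        with pytest.raises(NonStopSubstitutionError):
            classify_variant(v, t)

    def test_two_nt_deletion_is_frameshift(self):
        t = make_tx("ATGAAACCCGGGTAA")
        v = VariantRecord("v", "T1", 4, 5, "AA", "")
        assert classify_variant(v, t) is VariantClass.FRAMESHIFT_INDEL

    def test_six_nt_insertion_is_inframe(self):
        t = make_tx("ATGAAACCCGGGTAA")
        v = VariantRecord("v", "T1", 4, 4, "", "GCAGCA")
        assert classify_variant(v, t) is VariantClass.INFRAME_INDEL

    def test_variant_outside_orf_rejected(self):
        t = make_tx("GGGATGAAATAACCC", orf_start=4, orf_end=12)
        v = VariantRecord("v", "T1", 14, 14, "C", "T")
        with pytest.raises(TruncvarError):
            classify_variant(v, t)

    def test_variant_spanning_orf_boundary_rejected(self):
        t = make_tx("GGGATGAAATAACCC", orf_start=4, orf_end=12)
        v = VariantRecord("v", "T1", 2, 5, "GGAT", "")
        with pytest.raises(UnsupportedSpanError):
            classify_variant(v, t)


class TestDeriveConsequence:
    def test_nonsense_stop_codon_index(self):
        t = make_tx("ATGAAACCCGGGTAA")
        v = VariantRecord("v", "T1", 4, 4, "A", "T")  # AAA -> TAA
        c = derive_consequence(v, t)
        assert c.variant_class is VariantClass.NONSENSE_SNP
        assert c.stop_codon_index == 2
        assert c.stop_cdna_last_nt == 6

    def test_frameshift_read_through_has_no_stop(self):
        t = make_tx("ATGAAACCCGGGTAA")
        v = VariantRecord("v", "T1", 4, 4, "A", "")
        c = derive_consequence(v, t)
        # new reading ATG AAC CCG GGT AA: no stop anywhere
        assert oracle_first_stop(apply_edit(t.cdna_sequence, v), 1) is None
        assert c.variant_class is VariantClass.FRAMESHIFT_INDEL
        assert c.frameshift_codon_index == 2
        assert c.stop_codon_index is None and c.stop_cdna_last_nt is None

    def test_frameshift_new_stop_matches_oracle(self):
        t = make_tx("ATGAAATAACCCTAA", orf_end=15)
        # wild-type codon 3 is TAA already; move ORF so it is not:
        t = make_tx("ATGAAACATAACCCTAA", orf_end=9)
        v = VariantRecord("v", "T1", 5, 5, "", "A")  # insert 1 nt at cDNA 5
        c = derive_consequence(v, t)
        expected = oracle_first_stop(apply_edit(t.cdna_sequence, v), 1)
        assert c.stop_codon_index == expected
        assert c.stop_cdna_last_nt == 3 * expected

    def test_frameshift_without_sequence_errors(self):
        t = TranscriptModel("T1", (GenomeInterval("chr1", 1, 15, "+"),),
                            orf_start=1, orf_end=15)
        v = VariantRecord("v", "T1", 4, 4, "A", "")
        with pytest.raises(SequenceRequiredError):
            derive_consequence(v, t)

    def test_inframe_deletion_span_and_delta(self):
        t = make_tx("ATGAAACCCGGGTTTTAA")
        v = VariantRecord("v", "T1", 7, 12, "CCCGGG", "")
        c = derive_consequence(v, t)
        assert c.variant_class is VariantClass.INFRAME_INDEL
        assert c.inframe_span == (3, 4)
        assert c.inframe_residue_delta == -2
        assert not c.has_premature_stop

    def test_inframe_out_of_register_stop_ignored(self):
        # mid-codon insertion carrying TAA out of register; the in-frame
        # codons read CCT AAG CAA -- no stop is ever in register
        t = make_tx("ATGCAACCCGGGTAA")
        v = VariantRecord("v", "T1", 5, 5, "", "CTAAGC")
        c = derive_consequence(v, t)
        assert c.variant_class is VariantClass.INFRAME_INDEL
        assert not c.has_premature_stop

    def test_inframe_in_register_stop_sets_stop_fields(self):
        t = make_tx("ATGCAACCCGGGTAA")
        v = VariantRecord("v", "T1", 4, 4, "", "TAA")  # before codon 2
        c = derive_consequence(v, t)
        assert c.variant_class is VariantClass.INFRAME_INDEL
        assert c.stop_codon_index == 2
        assert c.stop_cdna_last_nt == 6

    def test_nonsense_stop_equals_codon_of_variant_position(self):
        t = make_tx("ATG" + "CAA" * 20 + "TAA")
        for codon in (2, 5, 13, 21):
            pos = 3 * (codon - 1) + 1  # first base of the codon: C -> T
            v = VariantRecord("v", "T1", pos, pos, "C", "T")
            c = derive_consequence(v, t)
            assert c.stop_codon_index == codon


class TestFrameshiftFuzz:
    def test_agreement_with_translation_oracle(self):
        """1,000 random ORFs with random indels: the reported new stop must
        equal a codon-by-codon walk over the edited sequence."""
        rng = np.random.Generator(np.random.PCG64(7))
        bases = np.array(list("ACGT"))
        stops = {"TAA", "TAG", "TGA"}
        checked = 0
        while checked < 1000:
            n_codons = int(rng.integers(10, 60))
            codons = []
            while len(codons) < n_codons:
                c = "".join(rng.choice(bases, size=3))
                if c not in stops and (codons or c != "ATG"):
                    codons.append(c)
            seq = "ATG" + "".join(codons) + "TAA" + \
                "".join(rng.choice(bases, size=int(rng.integers(0, 60))))
            t = make_tx(seq, orf_start=1, orf_end=3 * (n_codons + 2))
            # random indel strictly inside the ORF
            pos = int(rng.integers(4, 3 * (n_codons + 1)))
            if rng.random() < 0.5:
                dlen = int(rng.integers(1, 5))
                if dlen % 3 == 0 or pos + dlen - 1 > t.orf_end:
                    continue
                v = VariantRecord("v", "T1", pos, pos + dlen - 1,
                                  seq[pos - 1:pos + dlen - 1], "")
            else:
                ilen = int(rng.integers(1, 5))
                if ilen % 3 == 0:
                    continue
                v = VariantRecord("v", "T1", pos, pos,
                                  "", "".join(rng.choice(bases, size=ilen)))
            c = derive_consequence(v, t)
            assert c.variant_class is VariantClass.FRAMESHIFT_INDEL
            edited = apply_edit(seq, v)
            first = oracle_first_stop(edited, 1)
            # stops 5' of the edit belong to the unchanged prefix and cannot
            # exist inside a valid ORF, so the oracle's first stop is the one
            assert c.stop_codon_index == first
            if first is not None:
                assert c.stop_cdna_last_nt == 3 * first
            checked += 1


class TestNormalization:
    @pytest.mark.parametrize("pos,ref,alt,expected", [
        (100, "A", "T", (100, "A", "T")),
        (100, "AT", "A", (101, "T", "")),       # deletion, anchor stripped
        (100, "A", "ATTT", (100, "", "TTT")),   # insertion after pos 100
        (100, "ACGT", "AT", (101, "CG", "")),   # shared prefix+suffix
        (100, "TGGC", "TC", (101, "GG", "")),
    ])
    def test_minimal_representation(self, pos, ref, alt, expected):
        assert normalize_alleles(pos, ref, alt) == expected

    def test_multiallelic_vcf_split(self, tmp_path):
        seq = "ATGCAACCCGGGTTTTAA"
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=100>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t4\trs1\tC\tT,A\t.\tPASS\t.\n")
        t = make_tx(seq)
        recs = read_variants_vcf(vcf, {"T1": t})
        assert len(recs) == 2
        assert {r.alt_allele for r in recs} == {"T", "A"}
        assert {r.id for r in recs} == {"rs1.1", "rs1.2"}


class TestVcfProjection:
    def test_corpus_vcf_projects_back_to_planted_records(self, corpus, truth):
        """Round trip: genomic VCF written by the generator must project to
        exactly the planted cDNA-space records, on both strands."""
        from truncvar.gene_model import read_transcripts_gff3

        transcripts = read_transcripts_gff3(corpus["gff3"], corpus["fasta"])
        recs = {r.id: r for r in read_variants_vcf(corpus["vcf"], transcripts)}
        assert len(recs) == len(truth)
        strands = set()
        for row in truth.itertuples():
            r = recs[row.variant_id]
            assert r.transcript_id == row.transcript_id
            assert (r.cdna_start, r.cdna_end) == (row.cdna_start, row.cdna_end)
            assert r.ref_allele == (row.ref if row.ref != "-" else "")
            assert r.alt_allele == (row.alt if row.alt != "-" else "")
            strands.add(transcripts[row.transcript_id].strand)
        assert strands == {"+", "-"}
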