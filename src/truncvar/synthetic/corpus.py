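"""Generate a complete synthetic input universe with planted ground truth.

Every variant gets its own transcript, engineered so that the variant lands
in one chosen cell of the classifier's decision space (variant class ×
domain region × core exposure × NMD).  The intended label is recorded in a
truth table, which makes the full pipeline testable end to end without any
external database.

Key construction tricks:

* ORFs are built on a ``CAT`` codon background, which contains no stop
  codon in any of the three reading frames.  Planted codons (a ``CAA``
  mutable to ``TAA``, a stop written into the shifted frame downstream of a
  frameshift, distinctive codons around in-frame indels) are therefore the
  only termination signals, and indel representations stay unambiguous
  under VCF normalization.
* The exon–exon junction closest to the 3' end (the NMD reference point) is
  placed to realize an exact planted stop-to-junction distance, including
  the boundary values 50 and 51 nt.
* Domains align proteins onto three shared toy templates (helix bundle,
  sheet sandwich, extended chain) whose buried/exposed residues are known
  by construction.

All randomness flows through one seeded generator; the same seed yields a
byte-identical corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..errors import ValidationError
from ..variant_effects import STOP_CODONS, VariantClass
from .structures import ToyStructure, extended_chain, helix_bundle, \
    sheet_sandwich, write_pdb

__all__ = ["SyntheticSpec", "CellPlant", "generate_corpus"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic corpus.

    Defaults give ~200 variants: 8 per reachable decision cell, plus small
    sets of in-register inserted stops and near-threshold exposure cases.
    """

    n_per_cell: int = 8
    n_inserted_stop: int = 3
    n_near_threshold: int = 6
    exon_count_range: tuple[int, int] = (1, 5)
    intron_length_range: tuple[int, int] = (60, 120)
    protein_length: int = 140          # residues, stop codon excluded
    utr5_length: int = 30
    utr3_length: int = 240
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValidationError("n_per_cell must be >= 1")
        if self.exon_count_range[0] > self.exon_count_range[1] or \
                self.exon_count_range[0] < 1:
            raise ValidationError("invalid exon_count_range")
        if self.protein_length < 100:
            raise ValidationError(
                "protein_length must be >= 100 to fit the domain layouts")

    @property
    def orf_length(self) -> int:
        return 3 * (self.protein_length + 1)

    @property
    def cdna_length(self) -> int:
        return self.utr5_length + self.orf_length + self.utr3_length


# Domain layouts in protein coordinates.  Layout A: helix bundle at 11-70
# plus an extended-chain domain at 91-130; layout B swaps the bundle for the
# sheet sandwich (11-58).  Linkers and termini are the complement.
LAYOUT_A = (("bundle", 11, 70, 1, 60), ("extended", 91, 130, 1, 40))
LAYOUT_B = (("sheet", 11, 58, 1, 48), ("extended", 91, 130, 1, 40))

# Planted NMD distances (nt, junction minus stop-last-nt in the edited
# transcript).  The first entries pin the exact 50/51 boundary.
DIST_NO_NMD = (50, 0, -60, 30, 20, -30, 10, 40)
DIST_NMD = (51, 80, 120, 60, 90, 150, 70, 110)


@dataclass(frozen=True)
class CellPlant:
    """One planted variant: the decision cell it realizes plus the files'
    ground truth."""

    variant_id: str
    transcript_id: str
    variant_class: VariantClass
    cell: str
    codon: int
    region: str
    nmd: bool
    distance: int | None
    cdna_start: int
    cdna_end: int
    ref: str
    alt: str
    expected_label: str
    expected_hold_reason: str
    near_threshold: bool


@dataclass
class _Tx:
    tid: str
    cdna: str
    orf_start: int
    orf_end: int
    junctions: list[int]      # cumulative cDNA positions of exon ends, minus the last exon
    strand: str
    chrom: str
    exon_genomic: list[tuple[int, int]] = field(default_factory=list)
    vcf_pos: int = 0
    vcf_ref: str = ""
    vcf_alt: str = ""


def _scan_first_stop(seq: str, start0: int) -> int | None:
    """Generator-local codon scan (kept independent of the pipeline)."""
    i = start0
    codon = 1
    while i + 3 <= len(seq):
        if seq[i:i + 3] in STOP_CODONS:
            return codon
        i += 3
        codon += 1
    return None


class _CorpusBuilder:
    def __init__(self, spec: SyntheticSpec, out_dir: Path):
        self.spec = spec
        self.out = out_dir
        self.rng = np.random.Generator(np.random.PCG64(spec.seed))
        self.transcripts: list[_Tx] = []
        self.plants: list[CellPlant] = []
        self.domain_rows: list[tuple] = []
        self.templates: dict[str, ToyStructure] = {
            "bundle": helix_bundle(),
            "sheet": sheet_sandwich(),
            "extended": extended_chain(),
        }

    # -- sequence construction ------------------------------------------------

    def _base_orf_codons(self) -> list[str]:
        L = self.spec.protein_length
        return ["ATG"] + ["CAT"] * (L - 1) + ["TAA"]

    def _finish_transcript(self, idx: int, orf_codons: list[str],
                           extra_utr3_plant: dict[int, str] | None = None,
                           ) -> tuple[str, str]:
        """Assemble the cDNA: 5'UTR + ORF + 3'UTR (CAT-pattern, optionally
        with planted bases at 0-based UTR offsets)."""
        sp = self.spec
        utr5 = ("GCC" * (sp.utr5_length // 3 + 1))[:sp.utr5_length]
        utr3 = list(("CAT" * (sp.utr3_length // 3 + 1))[:sp.utr3_length])
        if extra_utr3_plant:
            for off, base in extra_utr3_plant.items():
                utr3[off] = base
        return utr5, "".join(orf_codons) + "".join(utr3)

    # -- NMD junction planning ------------------------------------------------

    def _choose_junction(self, distance_pool: tuple[int, ...], pick: int,
                         stop_edited_last: int | None, delta: int,
                         span: tuple[int, int]) -> tuple[int, int | None]:
        """Pick the penultimate-exon end realizing a planted distance.

        Returns (junction, realized distance).  ``stop_edited_last`` is the
        stop position in the edited transcript; the junction itself lives in
        original coordinates and shifts by ``delta`` when the edit is 5' of
        it.  ``span`` is the cDNA interval the junction must avoid.
        """
        sp = self.spec
        lo, hi = 2, sp.cdna_length - 20
        if stop_edited_last is None:
            # distance irrelevant; put the junction anywhere legal
            for _ in range(50):
                j = int(self.rng.integers(60, hi))
                if not span[0] - 2 <= j <= span[1] + 2:
                    return j, None
            raise ValidationError("could not place a junction")
        pool = tuple(distance_pool[pick % len(distance_pool):]) + distance_pool
        for d in pool:
            j = stop_edited_last + d - delta  # assume edit 5' of junction
            if lo <= j <= hi and j >= span[0] and not span[0] - 2 <= j <= span[1] + 2:
                return j, d
            j = stop_edited_last + d  # junction 5' of the edit: no shift
            if lo <= j <= hi and j < span[0] - 2:
                return j, d
        raise ValidationError(
            f"infeasible NMD plant: no junction realizes any of {distance_pool}")

    def _exon_boundaries(self, junction: int | None,
                         span: tuple[int, int]) -> list[int]:
        """Cumulative cDNA end positions of all exons but the last."""
        sp = self.spec
        if junction is None:
            if sp.exon_count_range[0] > 1:
                raise ValidationError(
                    "single-exon plant requested but exon_count_range excludes 1")
            return []
        if sp.exon_count_range[1] < 2:
            raise ValidationError(
                "infeasible plant: junction-dependent cell requires multi-exon "
                "transcripts but exon_count_range excludes them")
        n_exons = int(self.rng.integers(max(2, sp.exon_count_range[0]),
                                        max(2, sp.exon_count_range[1]) + 1))
        cuts = [junction]
        attempts = 0
        while len(cuts) < n_exons - 1 and attempts < 200:
            attempts += 1
            c = int(self.rng.integers(20, junction - 10)) if junction > 40 else None
            if c is None:
                break
            if any(abs(c - x) < 12 for x in cuts) or span[0] - 2 <= c <= span[1] + 2:
                continue
            cuts.append(c)
        return sorted(cuts)

    # -- genome assembly ------------------------------------------------------

    def _assemble_genome(self) -> dict[str, int]:
        """Place every transcript on a chromosome, build exon genomic
        coordinates and the VCF representation of its variant."""
        sp = self.spec
        chrom_cursor: dict[str, int] = {}
        per_chrom = 24
        for idx, tx in enumerate(self.transcripts):
            chrom = f"chr{idx // per_chrom + 1}"
            tx.chrom = chrom
            tx.strand = "+" if idx % 2 == 0 else "-"
            cursor = chrom_cursor.get(chrom, 0)

            cum = tx.junctions + [len(tx.cdna)]
            exon_spans = []  # cDNA spans
            prev = 0
            for c in cum:
                exon_spans.append((prev + 1, c))
                prev = c
            # sense-orientation pre-genomic string P
            parts = []
            p_offsets = []  # exon sense offsets (1-based) in P
            pos = 0
            for i, (c1, c2) in enumerate(exon_spans):
                seq = tx.cdna[c1 - 1:c2]
                p_offsets.append((pos + 1, pos + len(seq)))
                parts.append(seq)
                pos += len(seq)
                if i < len(exon_spans) - 1:
                    ilen = int(self.rng.integers(sp.intron_length_range[0],
                                                 sp.intron_length_range[1] + 1))
                    mid = "".join(self.rng.choice(list("ACGT"), size=ilen - 4))
                    intron = "GT" + mid + "AG"
                    parts.append(intron)
                    pos += ilen
            P = "".join(parts)
            block_start = cursor + 150 + 1  # leave a gap before the block
            chrom_cursor[chrom] = block_start + len(P) - 1

            def g_of(cdna_pos: int) -> int:
                # genomic position of a cDNA base, via the exon bookkeeping
                for (c1, c2), (a, b) in zip(exon_spans, p_offsets):
                    if c1 <= cdna_pos <= c2:
                        p_off = a + (cdna_pos - c1)
                        if tx.strand == "+":
                            return block_start + p_off - 1
                        return block_start + len(P) - p_off
                raise AssertionError(f"cDNA pos {cdna_pos} not exonic")

            if tx.strand == "+":
                tx.exon_genomic = [(block_start + a - 1, block_start + b - 1)
                                   for a, b in p_offsets]
            else:
                tx.exon_genomic = [(block_start + len(P) - b,
                                    block_start + len(P) - a)
                                   for a, b in p_offsets]

            # VCF representation of this transcript's variant
            plant = self.plants[idx]
            cs, ce, ref, alt = (plant.cdna_start, plant.cdna_end,
                                plant.ref, plant.alt)
            base = tx.cdna
            if ref and alt:  # SNV
                if tx.strand == "+":
                    tx.vcf_pos, tx.vcf_ref, tx.vcf_alt = g_of(cs), ref, alt
                else:
                    tx.vcf_pos = g_of(cs)
                    tx.vcf_ref, tx.vcf_alt = _rc(ref), _rc(alt)
            elif not alt:  # deletion
                if tx.strand == "+":
                    anchor = base[cs - 2]
                    tx.vcf_pos = g_of(cs - 1)
                    tx.vcf_ref, tx.vcf_alt = anchor + ref, anchor
                else:
                    anchor = _rc(base[ce])  # complement of cDNA base ce+1
                    tx.vcf_pos = g_of(ce + 1)
                    tx.vcf_ref, tx.vcf_alt = anchor + _rc(ref), anchor
            else:  # insertion before cs
                if tx.strand == "+":
                    anchor = base[cs - 2]
                    tx.vcf_pos = g_of(cs - 1)
                    tx.vcf_ref, tx.vcf_alt = anchor, anchor + alt
                else:
                    anchor = _rc(base[cs - 1])
                    tx.vcf_pos = g_of(cs)
                    tx.vcf_ref, tx.vcf_alt = anchor, anchor + _rc(alt)
        return {c: chrom_cursor[c] + 200 for c in sorted(chrom_cursor)}

    # -- plant builders -------------------------------------------------------

    def _plant(self, cell: str, vclass: VariantClass, codon: int,
               region: str, layout, pick: int, want_nmd: bool,
               expected_label: str, hold_reason: str = "",
               single_exon: bool = False, read_through: bool = False,
               inframe_codons: int = 1, insert: bool = False,
               insert_seq: str | None = None,
               near_threshold: bool = False) -> None:
        """Engineer one transcript + variant realizing a decision cell."""
        sp = self.spec
        idx = len(self.transcripts)
        tid = f"T{idx + 1:04d}"
        vid = f"v{idx + 1:04d}"
        orf_start = sp.utr5_length + 1
        orf_codons = self._base_orf_codons()
        L = sp.protein_length

        delta = 0
        stop_e_last: int | None = None
        utr3_plant: dict[int, str] = {}

        if vclass is VariantClass.NONSENSE_SNP:
            orf_codons[codon - 1] = "CAA"
            cs = ce = orf_start + 3 * (codon - 1)
            ref, alt = "C", "T"
            stop_e_last = orf_start + 3 * codon - 1

        elif vclass is VariantClass.FRAMESHIFT_INDEL:
            kinds = ("del1", "ins1", "del2", "ins2")
            kind = kinds[pick % 4]
            e0 = 3 * (codon - 1)  # 0-based ORF offset of the edit
            cs = orf_start + e0
            if kind == "del1":
                delta, ref, alt, ce = -1, "C", "", cs
            elif kind == "del2":
                delta, ref, alt, ce = -2, "CA", "", cs + 1
            elif kind == "ins1":
                delta, ref, alt, ce = 1, "", "A", cs
            else:
                delta, ref, alt, ce = 2, "", "AG", cs
            if not read_through:
                m = codon + 15
                # keep the planted shifted-frame stop clear of the native stop
                # codon at original ORF offsets [3L, 3L+2]
                while True:
                    o = 3 * (m - 1) - delta
                    if o + 2 < 3 * L or o > 3 * L + 2:
                        break
                    m += 1
                o_orig = 3 * (m - 1) - delta  # original offset of the stop plant
                for i, b in enumerate("TAA"):
                    off = o_orig + i
                    if off < 3 * (L + 1):
                        c_i, c_off = divmod(off, 3)
                        cd = list(orf_codons[c_i])
                        cd[c_off] = b
                        orf_codons[c_i] = "".join(cd)
                    else:
                        utr3_plant[off - 3 * (L + 1)] = b
                stop_e_last = orf_start + 3 * m - 1

        else:  # in-frame indel
            e0 = 3 * (codon - 1)
            cs = orf_start + e0
            if insert:
                seq = insert_seq if insert_seq is not None else "GCA" * inframe_codons
                ref, alt, ce = "", seq, cs
                delta = len(seq)
                if seq == "TAA":
                    stop_e_last = orf_start + 3 * codon - 1
            else:
                # distinctive codons so the VCF representation is unambiguous
                pool = ("GAA", "GAC", "GCT", "TGC")
                for j in range(inframe_codons):
                    orf_codons[codon - 1 + j] = pool[j % len(pool)]
                ref = "".join(orf_codons[codon - 1:codon - 1 + inframe_codons])
                alt = ""
                ce = cs + 3 * inframe_codons - 1
                delta = -len(ref)

        span = (cs, ce)
        if single_exon:
            if want_nmd:
                raise ValidationError(
                    "infeasible plant: NMD-positive stop on a single-exon "
                    "transcript")
            junction, dist = None, None
        else:
            pool = DIST_NMD if want_nmd else DIST_NO_NMD
            if stop_e_last is None:
                junction, dist = self._choose_junction((), pick, None, delta, span)
            else:
                junction, dist = self._choose_junction(pool, pick, stop_e_last,
                                                       delta, span)

        utr5, rest = self._finish_transcript(idx, orf_codons, utr3_plant)
        cdna = utr5 + rest
        assert len(cdna) == sp.cdna_length

        # generator-local verification of the planted termination structure
        if vclass is VariantClass.FRAMESHIFT_INDEL:
            if ref:
                edited = cdna[:cs - 1] + cdna[ce:]
            else:
                edited = cdna[:cs - 1] + alt + cdna[cs - 1:]
            found = _scan_first_stop(edited, orf_start - 1)
            if read_through:
                assert found is None, f"{vid}: unintended stop at codon {found}"
            else:
                assert found is not None and \
                    orf_start + 3 * found - 1 == stop_e_last, \
                    f"{vid}: planted stop mismatch ({found})"
        elif vclass is VariantClass.NONSENSE_SNP:
            assert cdna[cs - 1] == "C"

        junctions = self._exon_boundaries(junction, span)
        tx = _Tx(tid=tid, cdna=cdna, orf_start=orf_start,
                 orf_end=orf_start + 3 * (L + 1) - 1,
                 junctions=junctions, strand="+", chrom="")
        self.transcripts.append(tx)

        if layout is not None:
            for name, qs, qe, ts, te in layout:
                self.domain_rows.append(
                    (tid, qs, qe, f"{name.upper()}_TPL", ts, te,
                     f"{name}.pdb"))

        nmd_flag = bool(want_nmd) and not single_exon and stop_e_last is not None
        self.plants.append(CellPlant(
            variant_id=vid, transcript_id=tid, variant_class=vclass,
            cell=cell, codon=codon, region=region, nmd=nmd_flag,
            distance=dist if not single_exon else None,
            cdna_start=cs, cdna_end=ce, ref=ref, alt=alt,
            expected_label=expected_label, expected_hold_reason=hold_reason,
            near_threshold=near_threshold))

    # -- cell schedule --------------------------------------------------------

    def build(self) -> None:
        sp = self.spec
        rng = self.rng
        n = sp.n_per_cell
        bundle = self.templates["bundle"]

        def codon_in(lo: int, hi: int) -> int:
            return int(rng.integers(lo, hi + 1))

        for vclass in (VariantClass.NONSENSE_SNP, VariantClass.FRAMESHIFT_INDEL):
            for i in range(n):
                self._plant("no_structure", vclass, codon_in(40, 100),
                            "NO_STRUCTURE", None, i, False,
                            "HOLD", "NO_STRUCTURE")
            for i in range(n):
                self._plant("nmd_true", vclass, codon_in(73, 88), "LINKER",
                            LAYOUT_A, i, True, "DESTABILIZING_RECESSIVE")
            for i in range(n):
                self._plant("upstream", vclass, codon_in(3, 9), "UPSTREAM_ALL",
                            LAYOUT_A, i, False, "DESTABILIZING_RECESSIVE")
            for i in range(n):
                if i % 2 == 0:
                    self._plant("within_exposing", vclass, codon_in(34, 54),
                                "WITHIN_DOMAIN", LAYOUT_A, i, False,
                                "DESTABILIZING_DOMINANT")
                else:
                    self._plant("within_exposing", vclass, codon_in(34, 50),
                                "WITHIN_DOMAIN", LAYOUT_B, i, False,
                                "DESTABILIZING_DOMINANT")
            for i in range(n):
                self._plant("within_not_exposing", vclass, codon_in(101, 120),
                            "WITHIN_DOMAIN", LAYOUT_A, i, False,
                            "HOLD", "OTHER")
            for i in range(n):
                lo, hi = (11, 16) if i % 2 == 0 else (65, 70)
                self._plant("near_edge", vclass, codon_in(lo, hi),
                            "NEAR_DOMAIN_EDGE", LAYOUT_A, i, False,
                            "HOLD", "NEAR_EDGE")
            for i in range(n):
                self._plant("linker", vclass, codon_in(73, 88), "LINKER",
                            LAYOUT_A, i, False, "POSSIBLY_NOT_DESTABILIZING",
                            single_exon=(i in (1, 2)),
                            read_through=(vclass is VariantClass.FRAMESHIFT_INDEL
                                          and i == 3))
            for i in range(n):
                self._plant("downstream", vclass, codon_in(132, 138),
                            "DOWNSTREAM_ALL", LAYOUT_A, i, False,
                            "NOT_DESTABILIZING",
                            read_through=(vclass is VariantClass.FRAMESHIFT_INDEL
                                          and i == 3))

        inf = VariantClass.INFRAME_INDEL
        for i in range(n):
            self._plant("no_structure", inf, codon_in(40, 100), "NO_STRUCTURE",
                        None, i, False, "HOLD", "NO_STRUCTURE")
        for i in range(n):
            self._plant("linker", inf, codon_in(73, 88), "LINKER", LAYOUT_A,
                        i, False, "POSSIBLY_NOT_DESTABILIZING")
        for i in range(n):
            self._plant("upstream", inf, codon_in(3, 8), "UPSTREAM_ALL",
                        LAYOUT_A, i, False, "POSSIBLY_NOT_DESTABILIZING")
        for i in range(n):
            self._plant("downstream", inf, codon_in(132, 136), "DOWNSTREAM_ALL",
                        LAYOUT_A, i, False, "POSSIBLY_NOT_DESTABILIZING")
        for i in range(n):
            self._plant("within_long", inf, codon_in(101, 116), "WITHIN_DOMAIN",
                        LAYOUT_A, i, False, "DESTABILIZING_RECESSIVE",
                        inframe_codons=4, insert=(i % 2 == 1))
        # burial plants avoid helix termini, where even interface-facing
        # side chains stay partly solvent-accessible
        deep = [r for r in bundle.deep_buried_residues
                if 7 <= r <= 25 or 36 <= r <= 52]
        for i in range(n):
            q = 10 + deep[i % len(deep)]
            self._plant("within_buried", inf, q, "WITHIN_DOMAIN", LAYOUT_A,
                        i, False, "DESTABILIZING_RECESSIVE")
        surface = [r for r in bundle.exposed_residues if 9 <= r <= 44]
        for i in range(n):
            q = 10 + surface[int(rng.integers(0, len(surface)))]
            self._plant("within_surface", inf, q, "WITHIN_DOMAIN", LAYOUT_A,
                        i, False, "POSSIBLY_NOT_DESTABILIZING")
        for i in range(n):
            self._plant("near_edge", inf, codon_in(11, 16), "NEAR_DOMAIN_EDGE",
                        LAYOUT_A, i, False, "HOLD", "NEAR_EDGE")
        for i in range(sp.n_inserted_stop):
            self._plant("inserted_stop", inf, codon_in(73, 88), "LINKER",
                        LAYOUT_A, i, False, "POSSIBLY_NOT_DESTABILIZING",
                        insert=True, insert_seq="TAA")
        for i in range(sp.n_inserted_stop):
            self._plant("inserted_stop_nmd", inf, codon_in(73, 88), "LINKER",
                        LAYOUT_A, i, True, "DESTABILIZING_RECESSIVE",
                        insert=True, insert_seq="TAA")
        # near-threshold exposure: truncations removing only the last part of
        # the bundle's second helix straddle the exposure threshold
        for i in range(sp.n_near_threshold):
            t = 50 + i % 5  # template residue 50..54
            label, reason = (("DESTABILIZING_DOMINANT", "") if t <= 51
                             else ("HOLD", "OTHER"))
            self._plant("near_threshold", VariantClass.NONSENSE_SNP, 10 + t,
                        "WITHIN_DOMAIN", LAYOUT_A, i, False, label, reason,
                        near_threshold=True)

    # -- writers --------------------------------------------------------------

    def write(self) -> dict[str, Path]:
        out = self.out
        out.mkdir(parents=True, exist_ok=True)
        (out / "structures").mkdir(exist_ok=True)
        chrom_lengths = self._assemble_genome()

        for name, toy in self.templates.items():
            write_pdb(toy, out / "structures" / f"{name}.pdb")

        # transcript FASTA (mRNA-sense cDNA)
        fasta = out / "transcripts.fa"
        with open(fasta, "w") as fh:
            for tx in self.transcripts:
                fh.write(f">{tx.tid} orf={tx.orf_start}-{tx.orf_end}\n")
                for i in range(0, len(tx.cdna), 70):
                    fh.write(tx.cdna[i:i + 70] + "\n")

        gff = out / "transcripts.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for tx in self.transcripts:
                self._write_gff_transcript(fh, tx)

        vcf = out / "variants.vcf"
        with open(vcf, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in sorted(chrom_lengths,
                            key=lambda x: int(x.replace("chr", ""))):
                fh.write(f"##contig=<ID={c},length={chrom_lengths[c]}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            recs = sorted(zip(self.transcripts, self.plants),
                          key=lambda tp: (int(tp[0].chrom.replace("chr", "")),
                                          tp[0].vcf_pos))
            for tx, plant in recs:
                fh.write(f"{tx.chrom}\t{tx.vcf_pos}\t{plant.variant_id}\t"
                         f"{tx.vcf_ref}\t{tx.vcf_alt}\t.\tPASS\t.\n")

        dom = out / "domains.tsv"
        with open(dom, "w") as fh:
            fh.write("protein_id\tquery_start\tquery_end\tdomain_id\t"
                     "template_start\ttemplate_end\tstructure_path\n")
            for row in self.domain_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")

        truth = out / "truth.tsv"
        cols = ["variant_id", "transcript_id", "variant_class", "cell",
                "codon", "region", "nmd", "distance", "cdna_start",
                "cdna_end", "ref", "alt", "expected_label",
                "expected_hold_reason", "near_threshold"]
        with open(truth, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for p in self.plants:
                fh.write("\t".join(str(x) for x in (
                    p.variant_id, p.transcript_id, p.variant_class.value,
                    p.cell, p.codon, p.region, int(p.nmd),
                    "" if p.distance is None else p.distance,
                    p.cdna_start, p.cdna_end, p.ref or "-", p.alt or "-",
                    p.expected_label, p.expected_hold_reason or "-",
                    int(p.near_threshold))) + "\n")

        return {"gff3": gff, "fasta": fasta, "vcf": vcf, "domains": dom,
                "truth": truth, "structures": out / "structures"}

    def _write_gff_transcript(self, fh, tx: _Tx) -> None:
        exons = tx.exon_genomic  # transcription order
        g_lo = min(a for a, _ in exons)
        g_hi = max(b for _, b in exons)
        st = tx.strand
        fh.write(f"{tx.chrom}\tsynth\tgene\t{g_lo}\t{g_hi}\t.\t{st}\t.\t"
                 f"ID=gene_{tx.tid}\n")
        fh.write(f"{tx.chrom}\tsynth\tmRNA\t{g_lo}\t{g_hi}\t.\t{st}\t.\t"
                 f"ID={tx.tid};Parent=gene_{tx.tid}\n")
        # exon cDNA spans in transcription order
        cum = tx.junctions + [len(tx.cdna)]
        spans = []
        prev = 0
        for c in cum:
            spans.append((prev + 1, c))
            prev = c
        for i, ((c1, c2), (a, b)) in enumerate(zip(spans, exons)):
            fh.write(f"{tx.chrom}\tsynth\texon\t{a}\t{b}\t.\t{st}\t.\t"
                     f"ID={tx.tid}.exon{i + 1};Parent={tx.tid}\n")
        phase_len = 0
        for (c1, c2), (a, b) in zip(spans, exons):
            lo = max(c1, tx.orf_start)
            hi = min(c2, tx.orf_end)
            if lo > hi:
                continue
            if st == "+":
                ga, gb = a + (lo - c1), a + (hi - c1)
            else:
                ga, gb = b - (hi - c1), b - (lo - c1)
            phase = (3 - phase_len % 3) % 3
            fh.write(f"{tx.chrom}\tsynth\tCDS\t{ga}\t{gb}\t.\t{st}\t{phase}\t"
                     f"ID={tx.tid}.cds;Parent={tx.tid}\n")
            phase_len += hi - lo + 1


def generate_corpus(spec: SyntheticSpec, out_dir: str | Path,
                    ) -> dict[str, Path]:
    """Generate the five-file corpus into ``out_dir``; returns the paths.

    Same spec (including seed) ⇒ byte-identical files.
    """
    builder = _CorpusBuilder(spec, Path(out_dir))
    builder.build()
    return builder.write()
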