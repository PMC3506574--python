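# truncvar

Structure-aware annotation of protein-destabilizing nonsense SNPs and
small indels.

Most variant-effect tools focus on missense substitutions. `truncvar`
addresses the more drastic coding variants: nonsense SNVs that introduce a
premature termination codon (PTC), frameshifting indels that scramble the
downstream sequence (usually creating a new stop), and in-frame indels that
insert or delete whole residues. For geneticists triaging such variants in
disease genes, the question is not *whether* the protein changes but *what
kind* of damage results: is the product simply absent (a recessive
loss-of-function), or is a truncated, misfolded protein actually translated
— with an exposed hydrophobic core that can drive toxic aggregation even in
heterozygotes (a dominant mechanism)?

## Method

For each variant the pipeline:

1. **Maps coordinates** — genome → cDNA (via the transcript's exon
   structure) → codon index within the annotated ORF.
2. **Derives the protein consequence** — for a nonsense SNV the stop codon
   position; for a frameshift, the edited cDNA is re-translated from the
   start codon in the shifted frame and the first new stop at or after the
   edit is located (scanning through the former 3′UTR; a frameshift may
   read through to the transcript end); in-frame indels report their
   affected codon span and residue delta.
3. **Locates the damage against structural domains** — homology alignments
   of the protein to template structures (SCOP/PDB-style domain hits,
   supplied as an interval table) classify the truncation point as upstream
   of all domains, within a domain (optionally near a domain edge), in an
   inter-domain linker, or downstream of all domains.
4. **Scores hydrophobic-core exposure** — for an intra-domain truncation,
   the solvent-accessible surface area (Shrake–Rupley, 1.4 Å probe) of
   hydrophobic atoms is computed for the full template and for the
   retained fragment; the difference ΔSASA_hydrophobic is the buried
   hydrophobic surface newly exposed by the truncation. ΔSASA ≥ 200 Å²
   (configurable) calls the core exposed.
5. **Applies the 50-bp NMD rule** — a PTC more than 50 nt upstream of the
   last exon–exon junction targets the mRNA for nonsense-mediated decay,
   so no protein is made at all.

A rule-based classifier combines these into five labels:

| label | meaning |
|---|---|
| `DESTABILIZING_RECESSIVE` | functional protein absent (NMD, or all domains lost) — loss of function, pathogenic mainly when homozygous |
| `DESTABILIZING_DOMINANT` | truncated protein translated (no NMD) with exposed hydrophobic core — aggregation-prone, can act against a normal allele |
| `NOT_DESTABILIZING` | truncation downstream of every domain, no NMD |
| `POSSIBLY_NOT_DESTABILIZING` | at least one complete domain remains (linker cut), or an in-frame change outside any domain core |
| `HOLD` | ambiguous: no aligned structure, cut near a domain edge, or sub-threshold exposure |

An NMD-positive stop overrides every structural consideration (the protein
is never made); in-frame indels within a domain are destabilizing when they
are long (> 3 residues) or hit buried residues (mean relative SASA < 0.2).

## Worked example

The package ships a synthetic-data generator that builds a complete input
universe — multi-exon transcripts (GFF3 + cDNA FASTA), variants (VCF, both
strands), domain alignment tables, and toy template structures (a two-helix
bundle and a sheet sandwich with buried leucine cores, plus a fully exposed
extended chain) — with the intended label planted for every variant:

```bash
truncvar simulate --out corpus --seed 42
truncvar annotate --gff3 corpus/transcripts.gff3 --fasta corpus/transcripts.fa \
    --variants corpus/variants.vcf --domains corpus/domains.tsv \
    --structures corpus/structures --out annotated.tsv
truncvar summarize --table annotated.tsv --out summary.json
```

`annotated.tsv` holds one row per variant:

```
variant_id  transcript_id  variant_class     codon  region         domain_id   delta_hydrophobic_area  nmd  nmd_distance  label                    hold_reason  rationale
v0002       T0002          NONSENSE_SNP      82     LINKER         -                                   1    51            DESTABILIZING_RECESSIVE  -            nmd-degrades-transcript
v0003       T0003          NONSENSE_SNP      5      UPSTREAM_ALL   -                                   0    50            DESTABILIZING_RECESSIVE  -            upstream-of-all-domains
v0004       T0004          NONSENSE_SNP      53     WITHIN_DOMAIN  BUNDLE_TPL  382.04                  0    50            DESTABILIZING_DOMINANT   -            intra-domain-truncation;core-exposed;no-nmd
```

Reading the rows: `v0002`'s stop sits 51 nt upstream of the last junction —
just past the 50-nt boundary — so the transcript is degraded and the call
is recessive regardless of structure. `v0004` truncates codon 53, inside
the aligned helix-bundle domain; removing the downstream helix exposes
382 Å² of previously buried hydrophobic surface (≥ the 200 Å² threshold),
and with the stop only 50 nt from the junction NMD does *not* fire, so a
truncated, aggregation-prone protein is predicted: the dominant class.
On the default corpus (~200 variants) the pipeline recovers 100% of the
planted labels.

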