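# Methods

This note documents the models and procedures implemented in `truncvar`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic tests demonstrate.

## Coordinate model

All coordinates are 1-based inclusive. Genomic intervals follow the GFF3
convention; cDNA positions count exonic nucleotides from the transcription
start; codon indices count from the start codon. Exons are stored in
transcription order, and minus-strand cDNA is kept in mRNA sense (reverse
complement of the genome) so that everything downstream of the projection
step is strand-agnostic. For an ORF starting at cDNA position `s`, a cDNA
position `p` maps to codon `⌈(p − s + 1)/3⌉` with within-codon offset
`((p − s) mod 3) + 1`. The inverse mapping (cDNA → genome) exists purely so
the projection can be property-tested as a bijection.

The ORF is taken from the input annotation (GFF3 CDS features or the BED12
thick interval, stop codon included); ORF correction of aberrant cDNAs is
out of scope. Variants that span an exon junction or the ORF boundary are
rejected with a dedicated error rather than guessed at — input annotation
conventions for such records vary and silently picking one would be worse.

## Variant consequences

Three classes are handled: nonsense SNVs (the substituted codon is TAA,
TAG or TGA; any other substitution is rejected as out of scope),
frameshifting indels (net length change ≢ 0 mod 3) and in-frame indels.
VCF alleles are reduced to a minimal representation (shared suffix then
prefix stripped) before projection, and multi-allelic records are split,
so classification does not depend on the VCF dialect.

Frameshift consequences are derived by editing the cDNA string and
re-translating from the start codon in the new frame. The scan runs to the
end of the transcript — deliberately past the original stop codon, which
the shifted frame ignores — and reports the first stop at or after the
edit. A frameshift with no stop before the transcript end is recorded as a
read-through and treated downstream as a non-NMD truncation at the
frameshift point. In-frame insertions whose inserted sequence contains an
in-register stop triplet truncate translation exactly like a nonsense
variant and have their stop fields populated; out-of-register stop
triplets are invisible to the ribosome and ignored.

## Domain placement

Domain evidence is an interval table: ungapped alignments of protein
segments to template structures (the role homology pipelines against
SCOP/PDB play upstream; alignment generation is not reimplemented here,
and the table is taken at face value). Redundant template hits covering
the same region are collapsed to the longest query interval per overlap
cluster. A position is then upstream of all domains, inside a domain, in a
linker, or downstream of all domains; with overlapping alignments the
domain holding the position deepest (largest distance to its nearest
boundary) wins.

"Near a domain edge" — the genuinely ambiguous zone where a truncation
removes only a few residues of a domain — is operationalized as a
symmetric fractional zone of `edge_fraction` (default 0.1) of the domain
length per side, rounded up. With `edge_fraction = 0` the zone is empty.
A truncation exactly at the domain start still counts as inside the
domain; severity is handled by the exposure score, not by the region call.

## Core exposure

The destabilization signal for intra-domain truncations is quantitative:

    ΔSASA_hydro(k) = SASA_hydro(fragment < k) − SASA_hydro(same atoms, full)

i.e. the solvent-accessible surface area gained by hydrophobic atoms of
the retained fragment when residues ≥ k are deleted. SASA is computed with
the Shrake–Rupley method: each atom's sphere is expanded by the probe
radius (default 1.4 Å, water) and sampled at `n_points` (default 960)
quasi-uniform points from a Fibonacci lattice — fixed, no RNG, so results
are bit-reproducible. Van der Waals radii come from a fixed element table
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, others 1.80 Å). At 960 points the
isolated-atom estimate is exact to < 0.5% of the analytic sphere area, and
the two-sphere case matches the closed-form spherical-cap value to < 2% at
10⁴ points. Occlusion is monotone by construction: adding an atom can only
bury lattice points, never free them, which also makes ΔSASA non-negative.

`core_exposing` is ΔSASA_hydro ≥ `exposure_threshold`, default **200 Å²**.
This threshold is the single most consequential free parameter and is an
explicit surrogate for a visual judgement, not a physical constant. It was
calibrated on the synthetic helix bundle so that mid-domain truncations
(ΔSASA ≈ 380–510 Å²) exceed it while truncations removing only the last
few residues (ΔSASA ≈ 80–190 Å²) do not; truncations removing roughly the
C-terminal quarter of the second helix straddle it (ΔSASA ≈ 185–250 Å²)
and are the corpus's designated near-threshold cases. The hydrophobic set
defaults to {ALA, VAL, LEU, ILE, MET, PHE, TRP, CYS}; both knobs are in
the config and echoed into every run's JSON sidecar.

Positions map to template residues by offset arithmetic on the alignment
interval pair, clamped to the template interval; gapped alignments are out
of scope. HETATM records, waters and altlocs other than blank/'A' are
dropped at PDB parse time, and residues are renumbered sequentially.

For short in-frame indels inside a domain, burial of the affected residues
is measured as mean relative SASA (residue SASA over its theoretical
Gly-X-Gly maximum); `burial_threshold` default 0.2 separates buried from
surface positions.

## NMD

A premature stop triggers nonsense-mediated decay when it lies more than
50 nt upstream of the end of the penultimate exon. Conventions made
explicit here: the stop is measured at its **last** nucleotide, the
junction is the cDNA coordinate of the penultimate exon's final
nucleotide, and the comparison is strict (distance > 50 is a target;
exactly 50 escapes). Measuring at the last stop nucleotide is the
conservative choice — it classifies fewer borderline stops as NMD targets.
Single-exon transcripts are never targets. For frameshift-derived stops
the decayed molecule is the *edited* transcript: the stop position is
taken in edited coordinates and the junction shifts by the indel's net
length when the indel lies 5′ of it. Other NMD determinants (long 3′UTRs,
start-proximal exceptions, uORFs) are out of scope.

## Classifier

Decision order, applied to consequence × region × exposure × NMD:

1. No aligned structure at all → `HOLD/NO_STRUCTURE` (the position cannot
   be located against any domain).
2. Premature stop predicted to trigger NMD → `DESTABILIZING_RECESSIVE`,
   regardless of region: no protein is made.
3. Other truncations (nonsense, frameshift point, in-register inserted
   stop): upstream of all domains → recessive (all domains lost — there is
   no partially built domain to expose a core, so this is loss-of-function,
   not aggregation); within a domain → dominant if core-exposing, else
   `HOLD/OTHER` (a sub-threshold intra-domain cut is precisely the
   ambiguous case, not a clean negative); near a domain edge →
   `HOLD/NEAR_EDGE`; linker → possibly-not (at least one complete domain
   remains); downstream of all domains → not destabilizing.
4. In-frame indels: outside domains → possibly-not; within a domain →
   recessive when long (|Δresidues| > 3) or buried (mean relative
   SASA < 0.2), else possibly-not; near an edge → hold. Both sub-rules are
   individually controlled by config.

One deliberate asymmetry: an in-frame insertion carrying an in-register
stop is routed through the truncation logic (it truncates identically),
but a would-be dominant call is capped to recessive. The dominant /
aggregation class is defined only for the nonsense and frameshift classes
in this scheme, and the cap keeps "non-frameshifting indels are never
dominant" an invariant rather than a statistical accident.

For summaries the five labels collapse to a four-column layout
(recessive / dominant / no / hold): both "not" hedges share the "no"
column, and recessive + dominant together are the "structurally
destabilizing" calls. Percentages are rounded half-up (one decimal for
class shares, nearest integer for coarse ratios).

## Synthetic corpus

The generator builds one transcript per variant, engineered to land in a
chosen cell of the decision space, with the intended label recorded in a
truth table. Defaults: 8 variants per reachable cell plus inserted-stop
and near-threshold extras, ~200 variants total; protein length 140;
transcripts of 1–5 exons (5′UTR 30 nt, 3′UTR 240 nt, introns 60–120 nt
with GT..AG ends) laid alternately on both strands of synthetic
chromosomes. ORFs use a `CAT`-repeat background — stop-free in all three
reading frames — so the only termination signals are the planted ones:
a `CAA` codon mutable to `TAA` for nonsense variants, a `TAA` written into
the shifted frame 15+ codons downstream of each frameshift (or omitted for
read-through plants), and distinctive codons around in-frame indel sites
chosen so that VCF normalization cannot shift the indel against the
repeat background. The penultimate-exon end is placed to realize exact
planted stop-to-junction distances, always including the boundary values
50 and 51 nt.

Structures are three ideal-geometry templates shared by all proteins, with
burial known by construction: an antiparallel two-helix bundle (standard
helix parameters — 1.5 Å rise, 100° twist — at 8.6 Å axis separation,
interface leucines with two-atom side chains, outward alanines), a
two-layer sheet sandwich with leucines filling the inter-layer space, and
a fully extended chain with nothing buried. Residues are reduced to 2–3
pseudo-atoms; burial plants avoid helix termini, where even
interface-facing side chains stay partly accessible. Domain layouts align
each protein to a bundle-or-sheet domain (residues 11–70 / 11–58) and an
extended-chain domain (91–130), leaving defined upstream, linker and
downstream segments.

What the corpus does **not** emulate: real sequence composition and codon
usage, gapped or low-identity alignments, full-atom side-chain packing,
alternative transcripts per gene, and realistic allele frequencies. Tests
passing on this corpus therefore demonstrate the correctness of the
pipeline's logic (coordinate projection on both strands, frame scanning,
boundary handling, rule composition, determinism), not calibration of the
exposure threshold against experimental aggregation data.

## Numerical and degenerate-input choices

* SASA determinism: the Fibonacci lattice is fixed; repeated runs are
  byte-identical, and ΔSASA ≥ 0 holds exactly up to lattice resolution
  (tests allow −10⁻⁶ × total area).
* Truncation at residue 1 retains nothing and raises; the caller treats
  that case as upstream-of-domain. Truncation after the last residue has
  ΔSASA = 0.
* A within-domain truncation whose alignment has no structure file
  available yields `HOLD/OTHER` with an explicit rationale rather than an
  error — the evidence situation matches the no-structure hold.
* Ties in domain deduplication break on (query length, domain id) so the
  result is order-independent.
* The corpus generator asserts its own plants (stop positions by direct
  codon scan, junction arithmetic) at build time, independently of the
  pipeline code under test.

## Problem sizes

Default test and acceptance runs use the ~200-variant corpus, 500–1000
random ORFs for the frameshift oracle comparison, and 960 lattice points
(10⁴ for the two-sphere check); these sizes keep a full run in tens of
seconds while exercising every decision cell at least three times.

## Known limitations

* The exposure threshold and burial threshold are documented surrogates
  for expert visual judgement; absolute values carry no experimental
  calibration.
* Ungapped interval alignments ignore indels in the homology alignment
  itself; positions near alignment gaps would be mapped off by the gap
  length in real data.
* Functional-residue rescue (catalytic/binding sites inside "not
  destabilizing" truncations) is explicitly out of scope, as is any
  disease-database cross-referencing.
* Only the 50-bp junction rule is modeled for NMD; transcripts escaping by
  other mechanisms are not flagged.
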