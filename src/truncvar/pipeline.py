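"""End-to-end annotation: files in, per-variant label table out.

For each variant the pipeline derives the protein-level consequence,
locates the truncation (or indel) against the protein's domain alignments,
computes the core-exposure score on the aligned template structure when the
cut falls inside a domain, applies the 50-bp NMD rule to premature stops,
and runs the rule-based classifier.  Structure work is cached per
(template, residue) so repeated hits on shared templates cost one SASA
evaluation.

The output is deterministic: same inputs and config give a byte-identical
table.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import classifier as _classifier
from .classifier import AnnotationLabel, Label
from .config import PipelineConfig
from .core_exposure import (
    StructureModel,
    exposure_on_truncation,
    map_truncation_to_template,
    read_pdb,
    residue_relative_sasa,
)
from .domain_locator import (
    DomainAlignment,
    Region,
    RegionCall,
    dedupe_overlapping,
    locate,
    read_domains_tsv,
)
from .errors import TruncvarError
from .gene_model import TranscriptModel, last_junction_cdna, read_transcripts_gff3
from .nmd import NmdCall, is_nmd_target
from .variant_effects import (
    ProteinConsequence,
    VariantClass,
    VariantRecord,
    derive_consequence,
    read_variants_tsv,
    read_variants_vcf,
)

__all__ = ["annotate_variant", "annotate", "annotate_files", "OUTPUT_COLUMNS"]

OUTPUT_COLUMNS = ["variant_id", "transcript_id", "variant_class", "codon",
                  "region", "domain_id", "delta_hydrophobic_area", "nmd",
                  "nmd_distance", "label", "hold_reason", "rationale"]


class _StructureCache:
    """Loads template structures lazily and memoizes exposure / burial."""

    def __init__(self, structure_dir: Path | None, config: PipelineConfig):
        self.dir = structure_dir
        self.config = config
        self._structures: dict[str, StructureModel] = {}
        self._exposure: dict[tuple[str, int], object] = {}
        self._burial: dict[tuple[str, tuple[int, ...]], float] = {}

    def structure(self, rel_path: str) -> StructureModel:
        if rel_path not in self._structures:
            path = Path(rel_path)
            if not path.is_absolute() and self.dir is not None:
                path = self.dir / rel_path
            self._structures[rel_path] = read_pdb(path)
        return self._structures[rel_path]

    def exposure(self, rel_path: str, residue: int):
        key = (rel_path, residue)
        if key not in self._exposure:
            cfg = self.config
            self._exposure[key] = exposure_on_truncation(
                self.structure(rel_path), residue,
                hydrophobic_set=cfg.hydrophobic_set,
                probe_radius=cfg.probe_radius, n_points=cfg.n_points,
                threshold=cfg.exposure_threshold)
        return self._exposure[key]

    def burial(self, rel_path: str, residues: tuple[int, ...]) -> float:
        key = (rel_path, residues)
        if key not in self._burial:
            cfg = self.config
            self._burial[key] = residue_relative_sasa(
                self.structure(rel_path), list(residues),
                probe_radius=cfg.probe_radius, n_points=cfg.n_points)
        return self._burial[key]


def _locate_position(c: ProteinConsequence) -> int | None:
    """Protein position at which the variant acts structurally."""
    if c.variant_class is VariantClass.FRAMESHIFT_INDEL:
        return c.frameshift_codon_index
    if c.variant_class is VariantClass.NONSENSE_SNP:
        return c.stop_codon_index
    return c.inframe_span[0] if c.inframe_span else None


def annotate_variant(v: VariantRecord, t: TranscriptModel,
                     domains: list[DomainAlignment],
                     cache: _StructureCache,
                     config: PipelineConfig) -> dict:
    """Annotate one variant; returns one output row."""
    c = derive_consequence(v, t)
    pos = _locate_position(c)
    region = locate(pos, domains, edge_fraction=config.edge_fraction)

    truncating = (c.variant_class is VariantClass.FRAMESHIFT_INDEL
                  or c.has_premature_stop)

    nmd: NmdCall | None = None
    if c.has_premature_stop:
        junction = last_junction_cdna(t)
        shift = 0
        if junction is not None and v.net_length_change and \
                v.cdna_start <= junction:
            shift = v.net_length_change
        nmd = is_nmd_target(c.stop_cdna_last_nt, t, junction_shift=shift,
                            rule_distance=config.nmd_distance)

    exposure = None
    mean_rel_sasa = None
    if region.region is Region.WITHIN_DOMAIN and region.domain is not None \
            and region.domain.structure_available:
        if truncating and not (nmd and nmd.is_target):
            tmpl_res = map_truncation_to_template(pos, region.domain)
            exposure = cache.exposure(region.domain.structure_path, tmpl_res)
        elif not truncating:
            span = c.inframe_span or (pos, pos)
            residues = tuple(sorted({
                map_truncation_to_template(q, region.domain)
                for q in range(span[0], span[1] + 1)
                if region.domain.query_start <= q <= region.domain.query_end}))
            if residues:
                mean_rel_sasa = cache.burial(region.domain.structure_path,
                                             residues)

    if region.region is Region.WITHIN_DOMAIN and exposure is None \
            and mean_rel_sasa is None and truncating \
            and not (nmd and nmd.is_target):
        # aligned domain without an available structure file: evidence is
        # incomplete, mirror the no-structure hold
        ann = AnnotationLabel(Label.HOLD, _classifier.HoldReason.OTHER,
                              rationale=("structure-file-unavailable",))
    else:
        ann = _classifier.classify(c, region, exposure, nmd,
                                   mean_rel_sasa=mean_rel_sasa, config=config)

    return {
        "variant_id": v.id,
        "transcript_id": t.id,
        "variant_class": c.variant_class.value,
        "codon": pos,
        "region": region.region.value,
        "domain_id": region.domain_id or "-",
        "delta_hydrophobic_area": (round(exposure.delta_hydrophobic_area, 2)
                                   if exposure else ""),
        "nmd": int(nmd.is_target) if nmd else 0,
        "nmd_distance": ("" if nmd is None or nmd.distance_to_last_junction is None
                         else nmd.distance_to_last_junction),
        "label": ann.label.value,
        "hold_reason": ann.hold_reason.value if ann.hold_reason else "-",
        "rationale": ";".join(ann.rationale),
    }


def annotate(variants: list[VariantRecord],
             transcripts: dict[str, TranscriptModel],
             domains_by_protein: dict[str, list[DomainAlignment]],
             config: PipelineConfig | None = None,
             structure_dir: str | Path | None = None) -> pd.DataFrame:
    """Annotate a variant list; proteins are keyed by transcript id."""
    config = config or PipelineConfig()
    cache = _StructureCache(Path(structure_dir) if structure_dir else None,
                            config)
    rows = []
    for v in variants:
        t = transcripts.get(v.transcript_id)
        if t is None:
            raise TruncvarError(f"variant {v.id}: unknown transcript "
                                f"{v.transcript_id}")
        doms = dedupe_overlapping(domains_by_protein.get(t.id, []))
        rows.append(annotate_variant(v, t, doms, cache, config))
    return pd.DataFrame(rows, columns=OUTPUT_COLUMNS)


def annotate_files(gff3: str | Path, fasta: str | Path,
                   variants_path: str | Path, domains_tsv: str | Path,
                   structure_dir: str | Path,
                   config: PipelineConfig | None = None) -> pd.DataFrame:
    """File-level entry point: GFF3 + cDNA FASTA + VCF (or cDNA-space TSV)
    + domain table + structure directory."""
    config = config or PipelineConfig()
    transcripts = read_transcripts_gff3(gff3, fasta)
    vp = str(variants_path)
    if vp.endswith((".vcf", ".vcf.gz")):
        variants = read_variants_vcf(vp, transcripts)
    else:
        variants = read_variants_tsv(vp)
    domains = read_domains_tsv(domains_tsv)
    return annotate(variants, transcripts, domains, config=config,
                    structure_dir=structure_dir)


def write_outputs(table: pd.DataFrame, out_tsv: str | Path,
                  config: PipelineConfig) -> None:
    """Write the per-variant TSV plus a JSON sidecar echoing the config."""
    out_tsv = Path(out_tsv)
    table.to_csv(out_tsv, sep="\t", index=False)
    sidecar = out_tsv.with_suffix(out_tsv.suffix + ".config.json")
    sidecar.write_text(json.dumps({"config": config.to_dict(),
                                   "n_variants": int(len(table))},
                                  indent=2) + "\n")
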