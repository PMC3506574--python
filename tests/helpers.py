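"""Shared test helpers: decision-table driving and tiny independent oracles."""

from __future__ import annotations

import csv
from pathlib import Path

from truncvar.classifier import AnnotationLabel, classify
from truncvar.core_exposure import ExposureResult
from truncvar.domain_locator import DomainAlignment, Region, RegionCall
from truncvar.nmd import NmdCall
from truncvar.variant_effects import ProteinConsequence, VariantClass

DATA_DIR = Path(__file__).parent / "data"

STOPS = {"TAA", "TAG", "TGA"}

_DUMMY_DOMAIN = DomainAlignment("P", 10, 60, "D1", 1, 51, "d.pdb")


def load_decision_table() -> list[dict]:
    with open(DATA_DIR / "decision_table.tsv") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def classify_cell(variant_class: str, region: str, flag: int,
                  nmd: int) -> AnnotationLabel:
    """Drive the classifier with one decision-table cell.

    ``flag`` means core-exposing for truncating classes and
    long-or-buried for in-frame indels.
    """
    vclass = VariantClass(variant_class)
    reg = Region(region)
    domain = _DUMMY_DOMAIN if reg in (Region.WITHIN_DOMAIN,
                                      Region.NEAR_DOMAIN_EDGE) else None
    rc = RegionCall(reg, domain=domain,
                    offset_in_domain=20 if domain else None)
    if vclass is VariantClass.INFRAME_INDEL:
        c = ProteinConsequence(vclass, inframe_span=(30, 30),
                               inframe_residue_delta=-1)
        rel_sasa = 0.05 if flag else 0.6
        return classify(c, rc, None, None, mean_rel_sasa=rel_sasa)
    if vclass is VariantClass.NONSENSE_SNP:
        c = ProteinConsequence(vclass, stop_codon_index=30,
                               stop_cdna_last_nt=120)
    else:
        c = ProteinConsequence(vclass, frameshift_codon_index=30,
                               stop_codon_index=45, stop_cdna_last_nt=165)
    exposure = ExposureResult(truncation_residue=21,
                              delta_hydrophobic_area=450.0 if flag else 80.0,
                              core_exposing=bool(flag), threshold=200.0)
    nmd_call = NmdCall(is_target=bool(nmd),
                       distance_to_last_junction=120 if nmd else 10)
    return classify(c, rc, exposure, nmd_call)


def oracle_first_stop(seq: str, orf_start: int) -> int | None:
    """Brute-force codon walk: 1-based index of the first stop codon when
    translating ``seq`` from 1-based ``orf_start`` to the sequence end."""
    codon_index = 1
    for i in range(orf_start - 1, len(seq) - 2, 3):
        if seq[i:i + 3] in STOPS:
            return codon_index
        codon_index += 1
    return None
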