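"""Rule-based destabilization classifier.

Combines the protein-level consequence, the region call against structural
domains, the quantitative core-exposure score and the NMD prediction into a
five-way label:

* ``DESTABILIZING_RECESSIVE`` — functional protein is absent: the mRNA is
  decayed (NMD) or the truncation removes every structural domain.  Harmful
  mainly when homozygous (loss of function).
* ``DESTABILIZING_DOMINANT`` — the truncated protein escapes NMD and its
  partial domain exposes buried hydrophobic core, so toxic aggregation can
  act even against a normal allele.
* ``NOT_DESTABILIZING`` — all domains left intact (truncation downstream of
  every domain, no NMD).
* ``POSSIBLY_NOT_DESTABILIZING`` — at least one complete domain remains
  (linker truncation) or an in-frame change sits outside any domain core.
* ``HOLD`` — evidence insufficient: no aligned structure, truncation near a
  domain edge, or an intra-domain cut below the exposure threshold.

Decision order: the no-structure check precedes everything (without an
alignment the position cannot be located at all); an NMD-positive premature
stop then overrides every structural consideration.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .config import PipelineConfig
from .core_exposure import ExposureResult
from .domain_locator import Region, RegionCall
from .errors import IncompleteEvidenceError
from .nmd import NmdCall
from .variant_effects import ProteinConsequence, VariantClass

__all__ = ["Label", "HoldReason", "AnnotationLabel", "classify"]


class Label(str, Enum):
    DESTABILIZING_RECESSIVE = "DESTABILIZING_RECESSIVE"
    DESTABILIZING_DOMINANT = "DESTABILIZING_DOMINANT"
    NOT_DESTABILIZING = "NOT_DESTABILIZING"
    POSSIBLY_NOT_DESTABILIZING = "POSSIBLY_NOT_DESTABILIZING"
    HOLD = "HOLD"


class HoldReason(str, Enum):
    NO_STRUCTURE = "NO_STRUCTURE"
    NEAR_EDGE = "NEAR_EDGE"
    OTHER = "OTHER"


#: Coarse column used for summary tables: the two "possibly (not)" hedges
#: collapse onto the yes/no/hold trichotomy of the headline table.
SUMMARY_COLUMN = {
    Label.DESTABILIZING_RECESSIVE: "recessive",
    Label.DESTABILIZING_DOMINANT: "dominant",
    Label.NOT_DESTABILIZING: "no",
    Label.POSSIBLY_NOT_DESTABILIZING: "no",
    Label.HOLD: "hold",
}


@dataclass(frozen=True)
class AnnotationLabel:
    label: Label
    hold_reason: HoldReason | None = None
    rationale: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert (self.hold_reason is not None) == (self.label is Label.HOLD)

    @property
    def summary_column(self) -> str:
        return SUMMARY_COLUMN[self.label]


def _classify_truncation(region: RegionCall, exposure: ExposureResult | None,
                         ) -> AnnotationLabel:
    r = region.region
    if r is Region.UPSTREAM_ALL:
        return AnnotationLabel(Label.DESTABILIZING_RECESSIVE,
                               rationale=("upstream-of-all-domains",))
    if r is Region.WITHIN_DOMAIN:
        if exposure is None:
            raise IncompleteEvidenceError(
                "intra-domain truncation needs a core-exposure result",
                missing="exposure")
        if exposure.core_exposing:
            return AnnotationLabel(Label.DESTABILIZING_DOMINANT,
                                   rationale=("intra-domain-truncation",
                                              "core-exposed", "no-nmd"))
        return AnnotationLabel(Label.HOLD, HoldReason.OTHER,
                               rationale=("intra-domain-truncation",
                                          "sub-threshold-exposure"))
    if r is Region.NEAR_DOMAIN_EDGE:
        return AnnotationLabel(Label.HOLD, HoldReason.NEAR_EDGE,
                               rationale=("near-domain-edge",))
    if r is Region.LINKER:
        return AnnotationLabel(Label.POSSIBLY_NOT_DESTABILIZING,
                               rationale=("linker-truncation",
                                          "complete-domain-remains"))
    if r is Region.DOWNSTREAM_ALL:
        return AnnotationLabel(Label.NOT_DESTABILIZING,
                               rationale=("downstream-of-all-domains",))
    raise AssertionError(f"unhandled region {r}")


def _classify_inframe(c: ProteinConsequence, region: RegionCall,
                      mean_rel_sasa: float | None, config: PipelineConfig,
                      ) -> AnnotationLabel:
    r = region.region
    if r in (Region.LINKER, Region.UPSTREAM_ALL, Region.DOWNSTREAM_ALL):
        return AnnotationLabel(Label.POSSIBLY_NOT_DESTABILIZING,
                               rationale=("inframe-outside-domains",))
    if r is Region.NEAR_DOMAIN_EDGE:
        return AnnotationLabel(Label.HOLD, HoldReason.NEAR_EDGE,
                               rationale=("inframe-near-domain-edge",))
    if r is Region.WITHIN_DOMAIN:
        if abs(c.inframe_residue_delta) > config.inframe_length_threshold:
            return AnnotationLabel(Label.DESTABILIZING_RECESSIVE,
                                   rationale=("inframe-in-domain", "long-indel"))
        if mean_rel_sasa is None:
            raise IncompleteEvidenceError(
                "short intra-domain in-frame indel needs relative SASA of the "
                "affected residues", missing="relative-sasa")
        if mean_rel_sasa < config.burial_threshold:
            return AnnotationLabel(Label.DESTABILIZING_RECESSIVE,
                                   rationale=("inframe-in-domain",
                                              "buried-residues"))
        return AnnotationLabel(Label.POSSIBLY_NOT_DESTABILIZING,
                               rationale=("inframe-in-domain",
                                          "short-surface-indel"))
    raise AssertionError(f"unhandled region {r}")


def classify(c: ProteinConsequence, r: RegionCall,
             e: ExposureResult | None = None, n: NmdCall | None = None,
             mean_rel_sasa: float | None = None,
             config: PipelineConfig | None = None) -> AnnotationLabel:
    """Final label for one variant.

    ``e`` is required for intra-domain truncations and ``mean_rel_sasa`` for
    short intra-domain in-frame indels; ``n`` is required whenever the
    consequence carries a premature stop (a frameshift that reads through to
    the transcript end has no stop and is treated as a non-NMD truncation).
    """
    config = config or PipelineConfig()

    if r.region is Region.NO_STRUCTURE:
        return AnnotationLabel(Label.HOLD, HoldReason.NO_STRUCTURE,
                               rationale=("no-aligned-structure",))

    truncating = (c.variant_class is VariantClass.FRAMESHIFT_INDEL
                  or c.has_premature_stop)
    if truncating:
        if c.has_premature_stop:
            if n is None:
                raise IncompleteEvidenceError(
                    "premature stop needs an NMD call", missing="nmd")
            if n.is_target:
                return AnnotationLabel(Label.DESTABILIZING_RECESSIVE,
                                       rationale=("nmd-degrades-transcript",))
        out = _classify_truncation(r, e)
        if (c.variant_class is VariantClass.INFRAME_INDEL
                and out.label is Label.DESTABILIZING_DOMINANT):
            # In-register inserted stops truncate like nonsense variants, but
            # the dominant/aggregation call is reserved for the nonsense and
            # frameshift classes; cap at the recessive call.
            return AnnotationLabel(Label.DESTABILIZING_RECESSIVE,
                                   rationale=out.rationale + ("inframe-capped",))
        return out

    return _classify_inframe(c, r, mean_rel_sasa, config)
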