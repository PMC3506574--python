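"""Place a protein position relative to its structural-domain alignments.

Alignments play the role of homology hits of the query protein against
SCOP/PDB template structures: ungapped interval pairs (query residues ↔
template residues).  ``locate`` gives every residue position exactly one
region call: upstream of all domains, inside a domain (optionally near one
of its edges), in an inter-domain linker, downstream of all domains, or
NO_STRUCTURE when the protein has no alignment at all.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

from .errors import ValidationError

__all__ = [
    "DomainAlignment",
    "Region",
    "RegionCall",
    "locate",
    "dedupe_overlapping",
    "read_domains_tsv",
]


@dataclass(frozen=True)
class DomainAlignment:
    """Ungapped alignment of a query interval to a template structure."""

    protein_id: str
    query_start: int
    query_end: int
    domain_id: str
    template_start: int
    template_end: int
    structure_path: str | None = None

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            raise ValidationError(
                f"{self.protein_id}/{self.domain_id}: query_start > query_end")
        qlen = self.query_end - self.query_start + 1
        tlen = self.template_end - self.template_start + 1
        if not 0.8 * qlen <= tlen <= 1.2 * qlen:
            raise ValidationError(
                f"{self.protein_id}/{self.domain_id}: template interval length "
                f"{tlen} not within ±20% of query length {qlen}")

    @property
    def query_length(self) -> int:
        return self.query_end - self.query_start + 1

    @property
    def structure_available(self) -> bool:
        return bool(self.structure_path)


class Region(str, Enum):
    UPSTREAM_ALL = "UPSTREAM_ALL"
    WITHIN_DOMAIN = "WITHIN_DOMAIN"
    NEAR_DOMAIN_EDGE = "NEAR_DOMAIN_EDGE"
    LINKER = "LINKER"
    DOWNSTREAM_ALL = "DOWNSTREAM_ALL"
    NO_STRUCTURE = "NO_STRUCTURE"


@dataclass(frozen=True)
class RegionCall:
    region: Region
    domain: DomainAlignment | None = None
    offset_in_domain: int | None = None

    @property
    def domain_id(self) -> str | None:
        return self.domain.domain_id if self.domain else None


def locate(pos: int, domains: Sequence[DomainAlignment],
           edge_fraction: float = 0.1) -> RegionCall:
    """Region call for a 1-based protein position.

    The edge zone of a domain spans ``ceil(edge_fraction * length)`` residues
    at each boundary; with ``edge_fraction = 0`` no position is near an edge.
    When overlapping alignments both contain the position, the one holding it
    deepest (largest distance to its nearest boundary) wins.
    """
    if pos < 1:
        raise ValidationError(f"protein position must be >= 1, got {pos}")
    if not 0 <= edge_fraction < 0.5:
        raise ValidationError("edge_fraction must lie in [0, 0.5)")
    if not domains:
        return RegionCall(Region.NO_STRUCTURE)

    containing = [d for d in domains if d.query_start <= pos <= d.query_end]
    if containing:
        best = max(containing,
                   key=lambda d: (min(pos - d.query_start, d.query_end - pos),
                                  d.query_length))
        zone = math.ceil(edge_fraction * best.query_length)
        near = (pos - best.query_start + 1 <= zone or
                best.query_end - pos + 1 <= zone)
        region = Region.NEAR_DOMAIN_EDGE if near else Region.WITHIN_DOMAIN
        return RegionCall(region, domain=best,
                          offset_in_domain=pos - best.query_start)
    if pos < min(d.query_start for d in domains):
        return RegionCall(Region.UPSTREAM_ALL)
    if pos > max(d.query_end for d in domains):
        return RegionCall(Region.DOWNSTREAM_ALL)
    return RegionCall(Region.LINKER)


def dedupe_overlapping(domains: Sequence[DomainAlignment],
                       ) -> list[DomainAlignment]:
    """Collapse redundant template hits: per cluster of mutually overlapping
    query intervals keep the alignment with the longest query interval.

    Homology databases typically report many templates covering the same
    region; one representative per region keeps the region calls unique.
    """
    if not domains:
        return []
    ordered = sorted(domains, key=lambda d: (d.query_start, -d.query_length))
    clusters: list[list[DomainAlignment]] = [[ordered[0]]]
    cluster_end = ordered[0].query_end
    for d in ordered[1:]:
        if d.query_start <= cluster_end:
            clusters[-1].append(d)
            cluster_end = max(cluster_end, d.query_end)
        else:
            clusters.append([d])
            cluster_end = d.query_end
    return [max(c, key=lambda d: (d.query_length, d.domain_id)) for c in clusters]


def read_domains_tsv(path: str | Path) -> dict[str, list[DomainAlignment]]:
    """Read the alignment table (TSV with header: protein_id, query_start,
    query_end, domain_id, template_start, template_end[, structure_path])."""
    out: dict[str, list[DomainAlignment]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            d = DomainAlignment(
                protein_id=row["protein_id"],
                query_start=int(row["query_start"]),
                query_end=int(row["query_end"]),
                domain_id=row["domain_id"],
                template_start=int(row["template_start"]),
                template_end=int(row["template_end"]),
                structure_path=(row.get("structure_path") or None),
            )
            out.setdefault(d.protein_id, []).append(d)
    return out
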