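"""Nonsense-mediated decay prediction under the 50-bp rule.

A transcript with a premature termination codon is degraded by NMD when the
stop lies more than 50 nt upstream of the last exon–exon junction (the end
of the penultimate exon).  The stop is measured at its last nucleotide and
the comparison is strict (> 50): a stop ending exactly 50 nt upstream of
the junction escapes decay.  Single-exon transcripts have no junction and
are never targets.

For stops created by a frameshift the relevant molecule is the *edited*
transcript: the stop position is already in edited coordinates, and the
junction shifts by the indel's net length when the indel lies 5' of it
(``junction_shift``).
"""

from __future__ import annotations

from dataclasses import dataclass

from .gene_model import TranscriptModel, last_junction_cdna

__all__ = ["NmdCall", "is_nmd_target", "NMD_DISTANCE_NT"]

#: Rule boundary: stops more than this many nt upstream of the last junction
#: trigger decay.
NMD_DISTANCE_NT = 50


@dataclass(frozen=True)
class NmdCall:
    is_target: bool
    distance_to_last_junction: int | None  # positive = stop upstream of junction


def is_nmd_target(stop_cdna_last_nt: int, t: TranscriptModel,
                  junction_shift: int = 0,
                  rule_distance: int = NMD_DISTANCE_NT) -> NmdCall:
    """Apply the 50-bp rule to a premature stop.

    ``junction_shift`` moves the junction coordinate into the edited
    transcript's frame of reference (net indel length for an indel 5' of the
    junction, 0 otherwise).
    """
    junction = last_junction_cdna(t)
    if junction is None:
        return NmdCall(is_target=False, distance_to_last_junction=None)
    distance = junction + junction_shift - stop_cdna_last_nt
    return NmdCall(is_target=distance > rule_distance,
                   distance_to_last_junction=distance)
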