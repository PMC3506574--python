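"""Pipeline configuration: every judgement threshold in one place.

The destabilization rules were designed around visual curation; two numbers
operationalize the visual calls and are deliberately exposed rather than
hidden: ``exposure_threshold`` (Å² of newly exposed hydrophobic surface that
counts as "core exposed") and ``burial_threshold`` (mean relative SASA below
which in-frame-affected residues count as buried).  Both are echoed into the
output sidecar of every run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .core_exposure import HYDROPHOBIC_RESIDUES
from .nmd import NMD_DISTANCE_NT


@dataclass(frozen=True)
class PipelineConfig:
    probe_radius: float = 1.4          # Å, water probe
    n_points: int = 960                # sphere points per atom (deterministic lattice)
    exposure_threshold: float = 200.0  # Å² newly exposed hydrophobic area
    hydrophobic_set: frozenset[str] = HYDROPHOBIC_RESIDUES
    edge_fraction: float = 0.1         # fraction of domain length per edge zone
    inframe_length_threshold: int = 3  # residues; larger in-frame indels destabilize
    burial_threshold: float = 0.2      # mean relative SASA below which residues are buried
    nmd_distance: int = NMD_DISTANCE_NT

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hydrophobic_set"] = sorted(self.hydrophobic_set)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if "hydrophobic_set" in d:
            d["hydrophobic_set"] = frozenset(d["hydrophobic_set"])
        return cls(**d)
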