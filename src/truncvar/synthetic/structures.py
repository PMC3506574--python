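"""Toy protein structures built from ideal geometry.

Reduced two-atom-per-residue models (CA on the backbone path, CB for the
side chain; glycine gets CA only).  Three architectures:

* ``helix_bundle`` — an antiparallel two-helix hairpin.  Side chains facing
  the partner helix are leucines and form a buried hydrophobic interface;
  outward-facing positions are alanines.  Truncating between the helices
  strips the partner and exposes the leucine face.
* ``sheet_sandwich`` — two stacked three-strand layers with all side chains
  pointing into the inter-layer space (leucines).  Removing the second layer
  exposes the first layer's face.
* ``extended_chain`` — a straight peptide with alternating, fully exposed
  leucine side chains: hydrophobic but with nothing buried, so truncation
  exposes essentially nothing.

Geometry uses standard helix parameters (1.5 Å rise, 100° twist, CA 2.3 Å
from the axis) and a 9.4 Å helix-axis separation, close enough to pack the
CB atoms against each other but not to clash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..core_exposure import StructureModel, VDW_RADII

__all__ = ["ToyStructure", "helix_bundle", "sheet_sandwich", "extended_chain",
           "write_pdb"]

RISE = 1.5          # Å per residue along the helix axis
TWIST = 100.0       # degrees per residue
CA_RADIUS = 2.3     # Å from helix axis
CB_RADIUS = 3.2
CG_RADIUS = 4.2     # second side-chain atom of interface leucines
AXIS_SEP = 8.6      # Å between the two helix axes


@dataclass
class ToyStructure:
    """A built structure plus the ground-truth residue annotation.

    ``deep_buried_residues`` are the interface positions pointing most
    directly at the packing partner — the ones a burial threshold should
    always catch.
    """

    name: str
    structure: StructureModel
    buried_residues: list[int] = field(default_factory=list)
    exposed_residues: list[int] = field(default_factory=list)
    deep_buried_residues: list[int] = field(default_factory=list)
    atom_names: list[str] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return self.structure.last_residue


class _Builder:
    def __init__(self, chain_id: str = "A"):
        # rows: (residue index, residue name, atom name, x, y, z)
        self.rows: list[tuple[int, str, str, float, float, float]] = []
        self.chain_id = chain_id

    def add(self, res_idx: int, resname: str, atom_positions: dict[str, tuple]):
        for name, (x, y, z) in atom_positions.items():
            self.rows.append((res_idx, resname, name, x, y, z))

    def build(self) -> StructureModel:
        res_idx = np.array([r[0] for r in self.rows], dtype=int)
        resname = np.array([r[1] for r in self.rows], dtype=object)
        element = np.array([r[2][0] for r in self.rows], dtype=object)
        coords = np.array([r[3:] for r in self.rows], dtype=float)
        radii = np.array([VDW_RADII.get(e, 1.8) for e in element])
        return StructureModel(self.chain_id, res_idx, resname, element,
                              coords, radii)

    def atom_names(self) -> list[str]:
        return [r[2] for r in self.rows]


def _helix_residue(i_in_helix: int, axis_x: float, z0: float, dz: float,
                   phase_deg: float) -> tuple[dict, float]:
    """Atom coordinates (radial CA/CB/CG directions) and side-chain azimuth
    cosine for one helical residue."""
    theta = math.radians(phase_deg + i_in_helix * TWIST)
    z = z0 + i_in_helix * dz
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    atoms = {
        "CA": (axis_x + CA_RADIUS * cos_t, CA_RADIUS * sin_t, z),
        "CB": (axis_x + CB_RADIUS * cos_t, CB_RADIUS * sin_t, z),
        "CG": (axis_x + CG_RADIUS * cos_t, CG_RADIUS * sin_t, z),
    }
    return atoms, cos_t


def helix_bundle(n_helix: int = 28, n_turn: int = 4) -> ToyStructure:
    """Antiparallel two-helix hairpin (default 60 residues).

    Helix 1: residues ``1..n_helix`` rising along +z at x = 0; turn:
    ``n_helix+1..n_helix+n_turn`` (glycines); helix 2: the remainder,
    descending along z at x = AXIS_SEP.  Residues whose side chain points
    toward the partner axis (|cos azimuth| > 0.5 in the right direction)
    are leucines; they are the planted buried core.
    """
    b = _Builder()
    buried, exposed, deep = [], [], []
    top_z = (n_helix - 1) * RISE

    def add_helix(start_res: int, axis_x: float, z0: float, dz: float,
                  phase: float, inward_sign: int) -> None:
        for i in range(n_helix):
            res = start_res + i
            atoms, c = _helix_residue(i, axis_x, z0, dz, phase)
            inward = c * inward_sign > 0.5
            if inward:
                resname = "LEU"
                buried.append(res)
                if c * inward_sign > 0.85:
                    deep.append(res)
            else:
                resname = "ALA"
                exposed.append(res)
                atoms = {k: v for k, v in atoms.items() if k != "CG"}
            b.add(res, resname, atoms)

    add_helix(1, 0.0, 0.0, RISE, 0.0, +1)
    for j in range(n_turn):  # connecting turn, no side chains
        res = n_helix + j + 1
        t = (j + 1) / (n_turn + 1)
        b.add(res, "GLY",
              {"CA": (AXIS_SEP * t, 0.0, top_z + 2.5 + 2.0 * math.sin(math.pi * t))})
    add_helix(n_helix + n_turn + 1, AXIS_SEP, top_z, -RISE, 180.0, -1)

    return ToyStructure("bundle", b.build(), buried, exposed, deep,
                        b.atom_names())


def sheet_sandwich(strand_len: int = 8, strands_per_layer: int = 3,
                   layer_sep: float = 7.0) -> ToyStructure:
    """Two stacked sheet layers (default 48 residues), leucine side chains
    filling the inter-layer space."""
    b = _Builder()
    res = 0
    buried = []
    for layer, (z_ca, z_cb) in enumerate([(0.0, -1.4),
                                          (-layer_sep, -layer_sep + 1.4)]):
        for s in range(strands_per_layer):
            y = 4.8 * s
            xs = range(strand_len) if s % 2 == 0 else range(strand_len - 1, -1, -1)
            for xi in xs:
                res += 1
                x = 3.4 * xi
                b.add(res, "LEU", {"CA": (x, y, z_ca), "CB": (x, y, z_cb)})
                buried.append(res)
    return ToyStructure("sheet", b.build(), buried, [], [], b.atom_names())


def extended_chain(n_res: int = 40) -> ToyStructure:
    """Fully extended peptide; every side chain solvent-exposed."""
    b = _Builder()
    for i in range(n_res):
        res = i + 1
        x = 3.8 * i
        y_cb = 1.5 if i % 2 == 0 else -1.5
        b.add(res, "LEU", {"CA": (x, 0.0, 0.0), "CB": (x, y_cb, 0.0)})
    return ToyStructure("extended", b.build(), [], list(range(1, n_res + 1)),
                        [], b.atom_names())


def write_pdb(toy: ToyStructure, path: str | Path) -> None:
    """Write ATOM records (minimal but standard-conformant PDB)."""
    s = toy.structure
    lines = []
    for i in range(s.n_atoms):
        lines.append(
            "ATOM  {serial:>5}  {name:<3}{alt}{res:>3} {chain}{resseq:>4}{icode}"
            "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2}".format(
                serial=i + 1,
                name=toy.atom_names[i],
                alt=" ",
                res=s.residue_name[i],
                chain=s.chain_id,
                resseq=int(s.residue_index[i]),
                icode=" ",
                x=s.coords[i, 0], y=s.coords[i, 1], z=s.coords[i, 2],
                occ=1.0, b=0.0,
                elem=s.element[i],
            ))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
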