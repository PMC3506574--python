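"""Quantitative hydrophobic-core exposure on truncation.

A premature termination inside a structural domain removes the C-terminal
part of the fold; hydrophobic side chains that packed against the removed
part become solvent-exposed, which drives misfolding and aggregation.  This
module turns that judgement into a number: the solvent-accessible surface
area (SASA) gained by hydrophobic atoms of the retained fragment when the
downstream residues are deleted,

    delta = SASA_hydrophobic(fragment) - SASA_hydrophobic(same atoms, full),

with a configurable call threshold (default 200 Å² of newly exposed
hydrophobic area).

SASA uses the Shrake–Rupley sphere-point method with a deterministic
Fibonacci lattice (no RNG), a 1.4 Å water probe and a fixed per-element
van der Waals radius table, so results are bit-reproducible across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyFragmentError, ValidationError
from .domain_locator import DomainAlignment

__all__ = [
    "StructureModel",
    "ExposureResult",
    "VDW_RADII",
    "HYDROPHOBIC_RESIDUES",
    "MAX_RESIDUE_SASA",
    "fibonacci_sphere",
    "compute_sasa",
    "exposure_on_truncation",
    "residue_relative_sasa",
    "map_truncation_to_template",
    "read_pdb",
]

#: Fixed van der Waals radii (Å) by element; unknown elements get 1.80 Å.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_RADIUS = 1.80

#: Residues counted as hydrophobic when summing newly exposed area.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "CYS"})

#: Theoretical maximum accessible surface area per residue (Å², Gly-X-Gly
#: tripeptide scale), used to express residue SASA as a relative value.
MAX_RESIDUE_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass
class StructureModel:
    """Flat atom-array representation of one protein chain.

    ``residue_index`` renumbers residues 1..n sequentially along the chain,
    which is the coordinate system domain alignments refer to.
    """

    chain_id: str
    residue_index: np.ndarray  # (n_atoms,) int, 1-based, non-decreasing
    residue_name: np.ndarray   # (n_atoms,) str, 3-letter codes
    element: np.ndarray        # (n_atoms,) str
    coords: np.ndarray         # (n_atoms, 3) float, Å
    radii: np.ndarray          # (n_atoms,) float, Å

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        n = len(self.residue_index)
        if self.coords.shape != (n, 3):
            raise ValidationError("coords must be (n_atoms, 3)")
        if n and np.any(np.diff(self.residue_index) < 0):
            raise ValidationError("residue indices must be non-decreasing")
        if n and not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        if n and np.any(self.radii <= 0):
            raise ValidationError("radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.residue_index)

    @property
    def last_residue(self) -> int:
        return int(self.residue_index.max()) if self.n_atoms else 0

    def select(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(self.chain_id, self.residue_index[mask],
                              self.residue_name[mask], self.element[mask],
                              self.coords[mask], self.radii[mask])


@dataclass(frozen=True)
class ExposureResult:
    """Newly exposed hydrophobic area after truncation.

    ``truncation_residue`` is the first residue removed; ``core_exposing``
    is ``delta_hydrophobic_area >= threshold``.
    """

    truncation_residue: int
    delta_hydrophobic_area: float
    core_exposing: bool
    threshold: float


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors (golden-angle spiral lattice)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def compute_sasa(s: StructureModel, probe_radius: float = 1.4,
                 n_points: int = 960) -> np.ndarray:
    """Per-atom Shrake–Rupley SASA (Å²).

    For each atom, test points on the sphere of radius ``r_atom + probe``;
    a point is accessible when it lies outside every other atom's expanded
    sphere.  SASA is the accessible fraction times the expanded sphere area.
    """
    if n_points < 100:
        raise ValidationError("n_points must be >= 100")
    if probe_radius <= 0:
        raise ValidationError("probe_radius must be positive")
    n = s.n_atoms
    if n == 0:
        return np.zeros(0)
    unit = fibonacci_sphere(n_points)
    expanded = s.radii + probe_radius
    tree = cKDTree(s.coords)
    max_exp = expanded.max()
    out = np.empty(n)
    for i in range(n):
        r_i = expanded[i]
        neighbors = tree.query_ball_point(s.coords[i], r_i + max_exp)
        neighbors = [j for j in neighbors if j != i and
                     np.linalg.norm(s.coords[j] - s.coords[i]) < r_i + expanded[j]]
        area = 4.0 * math.pi * r_i * r_i
        if not neighbors:
            out[i] = area
            continue
        pts = s.coords[i] + unit * r_i  # (n_points, 3)
        nb_coords = s.coords[neighbors]  # (m, 3)
        nb_r2 = expanded[neighbors] ** 2
        d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
        buried = (d2 < nb_r2[None, :]).any(axis=1)
        out[i] = area * (1.0 - buried.mean())
    return out


def exposure_on_truncation(s: StructureModel, truncation_residue: int,
                           hydrophobic_set: frozenset[str] | set[str] = HYDROPHOBIC_RESIDUES,
                           probe_radius: float = 1.4, n_points: int = 960,
                           threshold: float = 200.0) -> ExposureResult:
    """Hydrophobic SASA gained by the fragment retained before
    ``truncation_residue`` (the first residue removed).

    Each retained atom can only gain accessibility when downstream atoms are
    removed, so the delta is non-negative up to lattice resolution.
    """
    last = s.last_residue
    if truncation_residue <= 1:
        raise EmptyFragmentError(
            f"truncation at residue {truncation_residue} retains nothing")
    if truncation_residue > last + 1:
        raise ValidationError(
            f"truncation residue {truncation_residue} beyond chain end {last}")
    keep = s.residue_index < truncation_residue
    hydro = np.array([rn in hydrophobic_set for rn in s.residue_name])
    full_sasa = compute_sasa(s, probe_radius, n_points)
    if truncation_residue == last + 1:
        delta = 0.0
    else:
        frag = s.select(keep)
        frag_sasa = compute_sasa(frag, probe_radius, n_points)
        frag_hydro = hydro[keep]
        delta = float(frag_sasa[frag_hydro].sum() - full_sasa[keep][hydro[keep]].sum()) \
            if frag_hydro.any() else 0.0
    return ExposureResult(truncation_residue=truncation_residue,
                          delta_hydrophobic_area=delta,
                          core_exposing=delta >= threshold,
                          threshold=threshold)


def residue_relative_sasa(s: StructureModel, residues: list[int] | np.ndarray,
                          probe_radius: float = 1.4, n_points: int = 960,
                          ) -> float:
    """Mean relative SASA of the given residue indices in the full structure.

    Relative SASA is the residue's summed atom SASA divided by its
    theoretical maximum; values near 0 mean buried, near 1 fully exposed.
    """
    sasa = compute_sasa(s, probe_radius, n_points)
    vals = []
    for r in residues:
        mask = s.residue_index == r
        if not mask.any():
            continue
        resname = s.residue_name[mask][0]
        ref = MAX_RESIDUE_SASA.get(resname, 200.0)
        vals.append(float(sasa[mask].sum()) / ref)
    if not vals:
        raise ValidationError("no requested residue present in the structure")
    return float(np.mean(vals))


def map_truncation_to_template(pos: int, d: DomainAlignment) -> int:
    """Template residue for a query position, via the ungapped interval pair
    (offset arithmetic, clamped to the template interval)."""
    raw = d.template_start + (pos - d.query_start)
    return min(max(raw, d.template_start), d.template_end)


def read_pdb(path: str | Path, chain: str | None = None) -> StructureModel:
    """Read ATOM records of one chain from a PDB file.

    HETATM records (waters, ligands) are dropped, as are altloc records
    other than blank/'A'.  Residues are renumbered 1..n sequentially.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(Path(path).stem, str(path))
    model = next(structure.get_models())
    chains = list(model.get_chains())
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise ValidationError(f"chain {chain!r} not found in {path}")
    ch = chains[0]
    res_idx, res_name, element, coords, radii = [], [], [], [], []
    seq_index = 0
    for residue in ch.get_residues():
        if residue.id[0] != " ":  # skip HETATM / waters
            continue
        seq_index += 1
        for atom in residue.get_atoms():
            if atom.get_altloc() not in (" ", "A"):
                continue
            elem = (atom.element or atom.get_name()[0]).upper()
            res_idx.append(seq_index)
            res_name.append(residue.get_resname())
            element.append(elem)
            coords.append(atom.coord)
            radii.append(VDW_RADII.get(elem, DEFAULT_RADIUS))
    return StructureModel(chain_id=ch.id,
                          residue_index=np.array(res_idx, dtype=int),
                          residue_name=np.array(res_name, dtype=object),
                          element=np.array(element, dtype=object),
                          coords=np.array(coords, dtype=float).reshape(-1, 3),
                          radii=np.array(radii, dtype=float))
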