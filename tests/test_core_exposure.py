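"""Shrake–Rupley SASA engine and truncation exposure scoring.

Analytic oracles: an isolated sphere has exactly its expanded-sphere area;
for two intersecting identical spheres the buried part is a spherical cap
with closed-form area 2*pi*R*h.
"""

import math

import numpy as np
import pytest

from truncvar.core_exposure import (
    StructureModel,
    compute_sasa,
    exposure_on_truncation,
    fibonacci_sphere,
    map_truncation_to_template,
    read_pdb,
    residue_relative_sasa,
)
from truncvar.domain_locator import DomainAlignment
from truncvar.errors import EmptyFragmentError, ValidationError
from truncvar.synthetic import extended_chain, helix_bundle, sheet_sandwich, \
    write_pdb

PROBE = 1.4
R_C = 1.7  # carbon vdW


def carbons(coords, residue_index=None, resname="LEU"):
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    ri = np.asarray(residue_index if residue_index is not None
                    else np.arange(1, n + 1))
    return StructureModel(
        chain_id="A", residue_index=ri,
        residue_name=np.array([resname] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        coords=coords, radii=np.full(n, R_C))


class TestComputeSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        s = carbons([[0, 0, 0]])
        sasa = compute_sasa(s, PROBE, 960)[0]
        exact = 4 * math.pi * (R_C + PROBE) ** 2  # ~120.76
        assert sasa == pytest.approx(exact, rel=0.005)
        assert exact == pytest.approx(120.76, abs=0.01)

    def test_distant_atoms_are_fully_exposed(self):
        sep = 2 * (R_C + PROBE) + 0.1
        s = carbons([[0, 0, 0], [sep, 0, 0]])
        exact = 4 * math.pi * (R_C + PROBE) ** 2
        assert compute_sasa(s, PROBE, 960) == pytest.approx([exact, exact],
                                                            rel=0.005)

    def test_two_spheres_match_spherical_cap_formula(self):
        # identical expanded spheres of radius R at distance d: each loses a
        # cap of height h = R - d/2, area 2*pi*R*h
        d = 2.0
        R = R_C + PROBE
        s = carbons([[0, 0, 0], [d, 0, 0]])
        sasa = compute_sasa(s, PROBE, 10_000)
        expected = 4 * math.pi * R * R - 2 * math.pi * R * (R - d / 2)
        assert sasa == pytest.approx([expected, expected], rel=0.02)

    def test_sasa_bounds_and_monotone_occlusion(self):
        rng = np.random.Generator(np.random.PCG64(11))
        coords = rng.uniform(0, 8, size=(12, 3))
        cap = 4 * math.pi * (R_C + PROBE) ** 2
        prev = compute_sasa(carbons(coords[:1]), PROBE, 960)
        for k in range(2, 13):
            cur = compute_sasa(carbons(coords[:k]), PROBE, 960)
            assert np.all(cur >= 0) and np.all(cur <= cap + 1e-9)
            # adding an atom never increases any existing atom's SASA
            assert np.all(cur[:k - 1] <= prev + 1e-9)
            prev = cur

    def test_empty_structure(self):
        s = carbons(np.zeros((0, 3)))
        assert compute_sasa(s, PROBE, 960).shape == (0,)

    def test_point_lattice_is_deterministic_and_unit(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.array_equal(pts, fibonacci_sphere(960))

    def test_parameter_validation(self):
        s = carbons([[0, 0, 0]])
        with pytest.raises(ValidationError):
            compute_sasa(s, PROBE, 50)
        with pytest.raises(ValidationError):
            compute_sasa(s, -1.0, 960)


class TestExposureOnTruncation:
    def test_truncating_after_last_residue_changes_nothing(self):
        toy = helix_bundle()
        res = exposure_on_truncation(toy.structure, toy.n_residues + 1)
        assert res.delta_hydrophobic_area == 0.0
        assert not res.core_exposing

    def test_empty_fragment_rejected(self):
        with pytest.raises(EmptyFragmentError):
            exposure_on_truncation(helix_bundle().structure, 1)
        with pytest.raises(ValidationError):
            exposure_on_truncation(helix_bundle().structure, 200)

    def test_delta_nonnegative_for_every_truncation_point(self):
        toy = sheet_sandwich()
        total = compute_sasa(toy.structure).sum()
        for k in range(2, toy.n_residues + 2, 3):
            res = exposure_on_truncation(toy.structure, k)
            assert res.delta_hydrophobic_area >= -1e-6 * total

    def test_mid_bundle_truncation_exposes_core(self):
        toy = helix_bundle()
        res = exposure_on_truncation(toy.structure, 30)
        assert res.core_exposing
        assert res.delta_hydrophobic_area > 400

    def test_removing_last_three_residues_does_not(self):
        toy = helix_bundle()
        res = exposure_on_truncation(toy.structure, toy.n_residues - 2)
        assert not res.core_exposing

    def test_extended_chain_never_exposes(self):
        toy = extended_chain()
        for k in (5, 15, 25, 35):
            res = exposure_on_truncation(toy.structure, k)
            assert not res.core_exposing
            assert res.delta_hydrophobic_area < 60
        # nothing is buried: every residue is at least moderately exposed
        for r in (1, 10, 20, 39):
            assert residue_relative_sasa(toy.structure, [r]) > 0.2

    def test_bundle_interface_is_buried_and_faces_are_not(self):
        toy = helix_bundle()
        deep = [r for r in toy.deep_buried_residues if 7 <= r <= 25]
        out = [r for r in toy.exposed_residues if 7 <= r <= 25]
        assert residue_relative_sasa(toy.structure, deep) < 0.2
        assert residue_relative_sasa(toy.structure, out) > 0.2


class TestTemplateMapping:
    def test_offset_arithmetic_and_clamp(self):
        d = DomainAlignment("P", 10, 60, "D", 1, 51, None)
        assert map_truncation_to_template(10, d) == 1
        assert map_truncation_to_template(35, d) == 26
        short = DomainAlignment("P", 10, 60, "D", 1, 45, None)
        assert map_truncation_to_template(60, short) == 45  # clamped


class TestPdbReader:
    def test_round_trip_preserves_atoms(self, tmp_path):
        toy = helix_bundle()
        p = tmp_path / "bundle.pdb"
        write_pdb(toy, p)
        s = read_pdb(p)
        assert s.n_atoms == toy.structure.n_atoms
        assert np.allclose(s.coords, toy.structure.coords, atol=1e-3)
        assert list(s.residue_name) == list(toy.structure.residue_name)
        assert s.last_residue == toy.n_residues

    def test_hetatm_and_altloc_filtered(self, tmp_path):
        p = tmp_path / "f.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CB AALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CB BALA A   1       1.200   0.000   0.000  1.00  0.00           C\n"
            "HETATM    4  O   HOH A   2       5.000   0.000   0.000  1.00  0.00           O\n"
            "END\n")
        s = read_pdb(p)
        assert s.n_atoms == 2  # altloc B and the water dropped

    def test_total_sasa_agrees_with_independent_implementation(self, tmp_path):
        biotite_struct = pytest.importorskip("biotite.structure")
        import biotite.structure.io.pdb as bpdb

        toy = helix_bundle()
        p = tmp_path / "bundle.pdb"
        write_pdb(toy, p)
        ours = compute_sasa(read_pdb(p), PROBE, 960).sum()
        arr = bpdb.PDBFile.read(str(p)).get_structure(model=1)
        theirs = biotite_struct.sasa(arr, probe_radius=PROBE, point_number=960,
                                     vdw_radii="Single").sum()
        assert ours == pytest.approx(theirs, rel=0.05)
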