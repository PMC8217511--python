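"""PDB I/O, superposition, screw extraction, interfaces and SASA."""

import math

import numpy as np
import pytest

from cartwheel import geometry as g
from cartwheel import structure, synthetic
from conftest import random_screw

TWO_ATOM_PDB = """\
ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00  0.00           C
ATOM      2  CA  GLY A   2       9.400   4.500   3.250  1.00  0.00           C
END
"""


@pytest.fixture
def ring_structure(tmp_path):
    pdb = tmp_path / "ring.pdb"
    synthetic.make_polymer_pdb(40.0, 0.0, 9, str(pdb))
    return structure.read_structure(str(pdb))


class TestIO:
    def test_two_atom_file(self):
        st = structure.read_structure(TWO_ATOM_PDB)
        atoms = structure.select_atoms(st, "A", atom_names=None)
        assert len(atoms) == 2
        assert np.allclose(atoms[0][3], [11.104, 6.134, -6.504])

    def test_writer_reader_round_trip(self, ring_structure, tmp_path):
        out = tmp_path / "rt.pdb"
        structure.write_structure(ring_structure, str(out))
        st2 = structure.read_structure(str(out))
        for chain in ("A", "E", "I"):
            a1 = structure.select_atoms(ring_structure, chain, atom_names=None)
            a2 = structure.select_atoms(st2, chain, atom_names=None)
            p1 = np.array([p for _, _, _, p, _ in a1])
            p2 = np.array([p for _, _, _, p, _ in a2])
            assert np.allclose(p1, p2, atol=5e-4)  # 3-decimal PDB precision

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            structure.read_structure("END\n")

    def test_selection_parsing(self):
        sel = structure.UnitSelection("A:10-50, B")
        assert sel.parts() == [("A", 10, 50), ("B", None, None)]


class TestKabsch:
    def test_self_rmsd_zero(self, ring_structure):
        sup = structure.kabsch_superpose(ring_structure, "A", ring_structure, "A",
                                         atom_names=None)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_applied_rigid_motion(self, rng):
        P = rng.normal(scale=10.0, size=(40, 3))
        T = random_screw(rng).matrix()
        Q = g.apply_transform(T, P)
        sup = structure.kabsch(P, Q)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(sup.matrix(), T, atol=1e-8)

    def test_rmsd_invariant_to_rigid_premotion(self, rng):
        P = rng.normal(scale=10.0, size=(30, 3))
        Q = P + rng.normal(scale=0.5, size=P.shape)
        base = structure.kabsch(P, Q).rmsd
        for _ in range(5):
            C = random_screw(rng).matrix()
            moved = structure.kabsch(g.apply_transform(C, P), Q).rmsd
            assert moved == pytest.approx(base, abs=1e-9)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            structure.kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRelativeTransform:
    def test_ring_neighbours_give_native_bend(self, ring_structure):
        screw = structure.relative_transform(ring_structure, "A", "B",
                                             atom_names=None)
        assert screw.rotation_angle == pytest.approx(40.0, abs=0.1)
        assert abs(screw.rise) / 10.0 < 0.01  # angstrom -> nm

    def test_helix_neighbours_give_twist_and_rise(self, tmp_path):
        pdb = tmp_path / "helix.pdb"
        synthetic.make_polymer_pdb(90.0, 6.5, 12, str(pdb))
        st = structure.read_structure(str(pdb))
        screw = structure.relative_transform(st, "A", "B", atom_names=None)
        assert screw.rotation_angle == pytest.approx(90.0, abs=0.1)
        assert abs(screw.rise) / 10.0 == pytest.approx(6.5, abs=0.01)

    def test_identical_units_give_identity(self, ring_structure):
        screw = structure.relative_transform(ring_structure, "C", "C",
                                             atom_names=None)
        assert screw.rotation_angle == pytest.approx(0.0, abs=1e-6)

    def test_random_steps_recovered_within_tolerance(self, tmp_path, rng):
        """Generator fixtures round-trip through PDB at 0.1 deg / 0.01 nm."""
        for i in range(100):
            rot = float(rng.uniform(20.0, 120.0))
            rise = float(rng.uniform(0.0, 6.0))
            pdb = tmp_path / f"case{i}.pdb"
            synthetic.make_polymer_pdb(rot, rise, 3, str(pdb))
            st = structure.read_structure(str(pdb))
            screw = structure.relative_transform(st, "A", "B", atom_names=None)
            assert screw.rotation_angle == pytest.approx(rot, abs=0.1)
            assert abs(screw.rise) / 10.0 == pytest.approx(rise, abs=0.01)


class TestDomainTilt:
    @staticmethod
    def _two_domain_structure(tilt_deg):
        """Elongated 'coiled-coil' along z plus a 'head' domain along x,
        rotated about z by tilt_deg in the mobile copy."""
        rng = np.random.default_rng(7)
        cc = np.column_stack([rng.normal(0, 0.8, 60), rng.normal(0, 0.8, 60),
                              np.linspace(0, 60, 60)])
        head = np.column_stack([np.linspace(5, 25, 40), rng.normal(0, 1.0, 40),
                                rng.normal(0, 1.0, 40) + 65.0])
        R = g._axis_angle_matrix(np.array([0.0, 0.0, 1.0]), tilt_deg)
        head_tilted = (head - [0, 0, 65]) @ R.T + [0, 0, 65]
        return (_coords_to_structure({"A": cc, "B": head}),
                _coords_to_structure({"A": cc, "B": head_tilted}))

    def test_zero_for_reference_vs_itself(self):
        ref, _ = self._two_domain_structure(45.0)
        assert structure.domain_tilt(ref, "B", "A", ref) == pytest.approx(0.0, abs=1e-6)

    def test_recovers_45_degree_head_rotation(self):
        ref, tilted = self._two_domain_structure(45.0)
        tilt = structure.domain_tilt(tilted, "B", "A", ref)
        assert tilt == pytest.approx(45.0, abs=0.5)

    def test_warns_on_isotropic_domain(self):
        rng = np.random.default_rng(3)
        blob = rng.normal(size=(50, 3))
        cc = np.column_stack([np.zeros((60, 2)), np.linspace(0, 60, 60)])
        st = _coords_to_structure({"A": cc, "B": blob})
        with pytest.warns(RuntimeWarning, match="isotropic"):
            structure.domain_tilt(st, "B", "A", st)


class TestInterfaces:
    @staticmethod
    def _atoms_at(positions_by_chain):
        return _coords_to_structure(positions_by_chain)

    def test_cutoff_inclusive_boundary(self):
        st = self._atoms_at({"A": [[0, 0, 0]], "B": [[3.9, 0, 0]]})
        assert len(structure.interface_residues(st, "A", "B", 4.0)) == 1
        st = self._atoms_at({"A": [[0, 0, 0]], "B": [[4.1, 0, 0]]})
        assert len(structure.interface_residues(st, "A", "B", 4.0)) == 0

    def test_symmetric_and_counts_constructed_contacts(self, rng):
        k = 7
        a = np.column_stack([np.zeros(k), np.arange(k) * 8.0, np.zeros(k)])
        b = a + [3.5, 0, 0]
        st = self._atoms_at({"A": a, "B": b})
        ab = structure.interface_residues(st, "A", "B")
        ba = structure.interface_residues(st, "B", "A")
        assert len(ab) == k
        assert {(y, x) for x, y in ab} == set(ba)


class TestSASA:
    def test_single_sphere_matches_closed_form(self):
        for el, r in (("C", 1.70), ("O", 1.52)):
            area = structure.shrake_rupley_sasa(np.zeros((1, 3)), [el])
            assert area == pytest.approx(4 * math.pi * (r + 1.4) ** 2, rel=1e-3)

    def test_far_apart_atoms_bury_nothing(self):
        st = _coords_to_structure({"A": [[0, 0, 0]], "B": [[50, 0, 0]]})
        res = structure.buried_interface_area(st, "A", "B")
        assert res["per_side"] == pytest.approx(0.0, abs=1e-9)

    def test_buried_area_symmetric_and_bounded(self, rng):
        a = rng.normal(scale=3.0, size=(20, 3))
        b = a + [4.0, 0, 0]
        st = _coords_to_structure({"A": a, "B": b})
        ab = structure.buried_interface_area(st, "A", "B")
        ba = structure.buried_interface_area(st, "B", "A")
        assert ab["per_side"] == pytest.approx(ba["per_side"], rel=1e-9)
        sasa_a = structure.shrake_rupley_sasa(a, ["C"] * 20)
        assert 0 < ab["total"] < 2 * sasa_a

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="XX"):
            structure.shrake_rupley_sasa(np.zeros((1, 3)), ["XX"])

    def test_agrees_with_independent_implementation(self, rng):
        """Cross-check against biotite's Shrake-Rupley on a random cluster."""
        import biotite.structure as bst

        coords = rng.normal(scale=4.0, size=(30, 3))
        ours = structure.shrake_rupley_sasa(coords, ["C"] * 30, 1.4, 960)
        arr = bst.AtomArray(30)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * 30)
        arr.atom_name = np.array(["C"] * 30)
        arr.res_name = np.array(["UNK"] * 30)
        arr.res_id = np.arange(1, 31)
        arr.chain_id = np.array(["A"] * 30)
        theirs = float(np.nansum(bst.sasa(
            arr, probe_radius=1.4, point_number=960,
            vdw_radii="Single", atom_filter=None)))
        assert ours == pytest.approx(theirs, rel=0.02)


class TestEndToEnd:
    def test_propagate_write_read_recover(self, tmp_path):
        """Geometry -> PDB -> structure analysis round trip."""
        pdb = tmp_path / "e2e.pdb"
        manifest = synthetic.make_polymer_pdb(40.0, 0.0, 9, str(pdb),
                                              str(pdb) + ".json")
        st = structure.read_structure(str(pdb))
        screw = structure.relative_transform(st, "D", "E", atom_names=None)
        truth = manifest.parameters
        assert screw.rotation_angle == pytest.approx(truth["rotation_deg"], abs=0.1)
        assert abs(screw.rise) / 10.0 == pytest.approx(truth["rise_nm"], abs=0.01)


def _coords_to_structure(positions_by_chain):
    import gemmi

    st = gemmi.Structure()
    model = gemmi.Model("1")
    for chain_id, coords in positions_by_chain.items():
        chain = gemmi.Chain(chain_id)
        for i, xyz in enumerate(np.atleast_2d(np.asarray(coords, float))):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    return st
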