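import numpy as np
import pytest

from mdpost.interactions import (GraphAtom, GraphBond, HBondCriteria, MolecularGraph,
                                 contact_residues, detect_hbonds, distance_series,
                                 hbond_capacity, hbond_count_series, lipinski_check,
                                 molecular_weight, occupancy, read_molecular_graph,
                                 resveratrol, rotatable_bond_count,
                                 write_molecular_graph)
from mdpost.trajio import Atom, Selection, Topology, Trajectory
from conftest import make_ca_trajectory


def graph_from_smiles(smiles: str) -> MolecularGraph:
    """Convert an rdkit molecule into our connection-table representation
    (test-only bridge; rdkit is the independent oracle, never a runtime
    dependency of the descriptors)."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    atoms = [GraphAtom(a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
             for a in kek.GetAtoms()]
    bonds = [GraphBond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                       int(b.GetBondTypeAsDouble()))
             for b in kek.GetBonds()]
    return MolecularGraph(atoms, bonds)


class TestDescriptors:
    def test_resveratrol_reference_values(self):
        g = resveratrol()
        assert molecular_weight(g) == pytest.approx(228.25)
        assert rotatable_bond_count(g) == 2
        assert hbond_capacity(g) == (3, 3, 6)
        passed, props = lipinski_check(g)
        assert passed and props["hbond_donors"] == 3

    def test_formula_parsing(self):
        assert molecular_weight("C14H12O3") == pytest.approx(228.25)
        assert molecular_weight("H2") == pytest.approx(2.02)
        with pytest.raises(ValueError):
            molecular_weight("")
        with pytest.raises(ValueError):
            molecular_weight("Xx3")

    @pytest.mark.parametrize("smiles, rot, donors, acceptors", [
        ("CC", 0, 0, 0),                        # ethane: terminal atoms only
        ("CCCC", 1, 0, 0),                      # n-butane: one internal C-C
        ("CCCCC", 2, 0, 0),                     # n-pentane
        ("Oc1ccccc1", 0, 1, 1),                 # phenol
        ("CCc1ccccc1", 1, 0, 0),                # ethylbenzene
        ("C=Cc1ccccc1", 1, 0, 0),               # styrene
        ("c1ccc(-c2ccccc2)cc1", 1, 0, 0),       # biphenyl
        ("OCCO", 1, 2, 2),                      # ethylene glycol
        ("CCOCC", 2, 0, 1),                     # diethyl ether
        ("Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1", 2, 3, 3),  # resveratrol
    ])
    def test_descriptors_agree_with_cheminformatics_toolkit(
            self, smiles, rot, donors, acceptors):
        from rdkit import Chem
        from rdkit.Chem import Descriptors, Lipinski

        g = graph_from_smiles(smiles)
        mol = Chem.MolFromSmiles(smiles)
        # independent toolkit values double-check the frozen expectations
        assert Lipinski.NumRotatableBonds(mol) == rot
        assert Lipinski.NumHDonors(mol) == donors
        assert Lipinski.NumHAcceptors(mol) == acceptors
        assert rotatable_bond_count(g) == rot
        d, a, _ = hbond_capacity(g)
        assert (d, a) == (donors, acceptors)
        assert molecular_weight(g) == pytest.approx(Descriptors.MolWt(mol), abs=0.02)

    def test_methane_capacity_zero(self):
        g = MolecularGraph([GraphAtom("C", 0, 4)], [])
        assert hbond_capacity(g) == (0, 0, 0)

    def test_lipinski_fails_heavy_molecule(self):
        # a 43-carbon chain is over 500 Da
        atoms = [GraphAtom("C", 0, 2)] * 43
        bonds = [GraphBond(i, i + 1) for i in range(42)]
        passed, props = lipinski_check(MolecularGraph(atoms, bonds))
        assert not passed and props["molecular_weight"] > 500

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            lipinski_check(MolecularGraph([], []))

    def test_connection_table_round_trip(self, tmp_path):
        g = resveratrol()
        p = tmp_path / "res.graph"
        write_molecular_graph(g, p)
        back = read_molecular_graph(p)
        assert molecular_weight(back) == molecular_weight(g)
        assert rotatable_bond_count(back) == rotatable_bond_count(g)
        assert hbond_capacity(back) == hbond_capacity(g)


def _hbond_system(o_o_distance: float, angle_deg: float = 180.0):
    """Donor O-H pointing at an acceptor O, with a configurable D-H···A
    geometry: donor at origin, H on the x axis, acceptor placed so that the
    O···O distance and D-H-A angle match the arguments."""
    d_oh = 0.96
    theta = np.radians(180.0 - angle_deg)
    # H->A direction makes the requested D-H-A angle with the H->D direction
    ha_dir = np.array([np.cos(theta), np.sin(theta), 0.0])
    # choose |H-A| so that |D-A| = o_o_distance
    h = np.array([d_oh, 0.0, 0.0])
    # solve |h + t*ha_dir| = o_o_distance for t > 0
    b = 2 * np.dot(h, ha_dir)
    c = np.dot(h, h) - o_o_distance ** 2
    t = (-b + np.sqrt(b * b - 4 * c)) / 2
    acceptor = h + t * ha_dir
    atoms = (
        Atom(1, "OG", "O", "SER", 1, "A"),
        Atom(2, "HG", "H", "SER", 1, "A"),
        Atom(3, "O", "O", "THR", 2, "A"),
    )
    coords = np.array([[0.0, 0, 0], h, acceptor])
    return Topology(atoms), coords


class TestHBonds:
    def test_linear_short_contact_detected(self):
        top, frame = _hbond_system(2.8, angle_deg=180.0)
        recs = detect_hbonds(frame, top, Selection([0]), Selection([2]))
        assert len(recs) == 1
        assert recs[0].distance_ha == pytest.approx(2.8 - 0.96, abs=1e-6)

    def test_long_contact_not_detected(self):
        top, frame = _hbond_system(5.0, angle_deg=180.0)
        assert detect_hbonds(frame, top, Selection([0]), Selection([2])) == []

    def test_bent_contact_not_detected(self):
        top, frame = _hbond_system(2.8, angle_deg=90.0)
        assert detect_hbonds(frame, top, Selection([0]), Selection([2])) == []

    def test_angle_threshold_is_inclusive_floor(self):
        top, frame = _hbond_system(2.8, angle_deg=140.0)
        crit = HBondCriteria(d_max=3.5, angle_min=135.0)
        assert len(detect_hbonds(frame, top, Selection([0]), Selection([2]), crit)) == 1

    def test_donor_without_hydrogen_is_error(self):
        top, frame = _hbond_system(2.8)
        with pytest.raises(ValueError, match="THR2"):
            # the acceptor oxygen has no attached H, so it cannot donate
            detect_hbonds(frame, top, Selection([2]), Selection([0]))

    def test_detection_invariant_under_rigid_transform(self, rng):
        from scipy.spatial.transform import Rotation
        top, frame = _hbond_system(2.9, angle_deg=160.0)
        moved = Rotation.random(1, rng=rng).apply(frame) + np.array([5.0, -3.0, 2.0])
        a = detect_hbonds(frame, top, Selection([0]), Selection([2]))
        b = detect_hbonds(moved, top, Selection([0]), Selection([2]))
        assert len(a) == len(b) == 1
        assert a[0].distance_ha == pytest.approx(b[0].distance_ha, abs=1e-9)

    def test_count_series_and_occupancy(self):
        top, bonded = _hbond_system(2.8)
        _, unbonded = _hbond_system(6.0)
        coords = np.stack([bonded, unbonded, bonded, bonded])
        traj = Trajectory(top, coords)
        counts, records = hbond_count_series(traj, Selection([0]), Selection([2]))
        np.testing.assert_array_equal(counts, [1, 0, 1, 1])
        assert occupancy((0, 2), records, 4) == pytest.approx(0.75)
        assert occupancy((0, 1), records, 4) == 0.0
        with pytest.raises(ValueError):
            occupancy((0, 2), records, 0)


class TestDistanceSeries:
    def test_constant_pair(self):
        coords = np.zeros((5, 2, 3))
        coords[:, 1, 0] = 2.0
        top = Topology((Atom(1, "O1", "O", "LIG", 1, "A"),
                        Atom(2, "O2", "O", "LIG", 1, "B")))
        series, stats = distance_series(Trajectory(top, coords), 0, 1)
        np.testing.assert_allclose(series, 2.0)
        assert stats.sd == 0.0

    def test_planted_normal_recovered(self, rng):
        planted_mean, planted_sd = 1.77, 0.12
        n = 5000
        dist = rng.normal(planted_mean, planted_sd, size=n)
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 0] = dist
        traj = make_ca_trajectory(coords)
        _, stats = distance_series(traj, 0, 1)
        assert stats.mean == pytest.approx(planted_mean, rel=0.03)
        assert stats.sd == pytest.approx(planted_sd, rel=0.03)

    def test_same_atom_rejected(self):
        with pytest.raises(ValueError):
            distance_series(make_ca_trajectory(np.zeros((2, 3, 3))), 1, 1)

    def test_single_frame_flagged_n1(self):
        traj = make_ca_trajectory(np.array([[[0.0, 0, 0], [1, 0, 0]]]))
        _, stats = distance_series(traj, 0, 1)
        assert stats.n == 1 and stats.sd == 0.0


class TestContacts:
    def _system(self, separation: float):
        atoms = (
            Atom(1, "C1", "C", "LIG", 900, "L"),
            Atom(2, "H1", "H", "LIG", 900, "L"),
            Atom(3, "CB", "C", "LEU", 126, "A"),
            Atom(4, "CG", "C", "TYR", 183, "A"),
        )
        coords = np.array([
            [0.0, 0, 0],
            [0.5, 0, 0],
            [separation, 0, 0],
            [50.0, 0, 0],
        ])
        return Topology(atoms), coords

    def test_far_ligand_gives_empty(self):
        top, frame = self._system(50.0)
        assert contact_residues(frame, top, Selection([0, 1])) == []

    @pytest.mark.parametrize("sep, expected", [(3.5, True), (4.5, False)])
    def test_cutoff_boundary(self, sep, expected):
        top, frame = self._system(sep)
        hits = contact_residues(frame, top, Selection([0, 1]), cutoff=4.0)
        assert (("A", 126, "LEU") in hits) is expected

    def test_hydrogens_do_not_count(self):
        # hydrogen within cutoff of the ligand but its heavy atoms outside
        atoms = (
            Atom(1, "C1", "C", "LIG", 900, "L"),
            Atom(2, "HB", "H", "LEU", 126, "A"),
            Atom(3, "CB", "C", "LEU", 126, "A"),
        )
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]])
        assert contact_residues(coords, Topology(atoms), Selection([0])) == []
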