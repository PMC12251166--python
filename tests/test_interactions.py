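"""Hydrogen bonds, contacts, SASA, pocket hydrophobicity, pocket waters."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from umamidyn.interactions import (
    contact_residues, count_pocket_waters, detect_hbonds, hbond_occupancy,
    pocket_hydrophobicity, sasa,
)
from umamidyn.structure import StructureModel, Trajectory
from umamidyn.synthetic import make_hbond_trajectory, make_water_shell

from conftest import make_hbond_triad, simple_model


class TestHbondCriteria:
    @pytest.mark.parametrize("distance,angle,expected", [
        (3.4, 150.0, True),    # both criteria met
        (3.6, 170.0, False),   # distance fails
        (3.0, 120.0, False),   # angle fails
        (2.9, 180.0, True),    # ideal linear bond
    ])
    def test_boundary_geometries(self, distance, angle, expected):
        triad = make_hbond_triad(distance, angle)
        bonds = detect_hbonds(triad)
        assert bool(bonds) is expected
        if expected:
            assert bonds[0].distance == pytest.approx(distance, abs=1e-6)
            assert bonds[0].angle == pytest.approx(angle, abs=1e-3)

    def test_rigid_motion_invariance(self):
        triad = make_hbond_triad(3.2, 160.0)
        rot = Rotation.from_euler("xyz", [30, 60, 45], degrees=True)
        moved = triad.with_coords(rot.apply(triad.coords) + 7.0)
        assert len(detect_hbonds(moved)) == len(detect_hbonds(triad)) == 1

    def test_donor_without_hydrogen_skipped(self, caplog):
        # lone N and O, no hydrogen anywhere
        model = simple_model(np.array([[0, 0, 0], [3.0, 0, 0.0]]),
                             elements=["N", "O"], names=["N", "O"])
        with caplog.at_level("WARNING"):
            bonds = detect_hbonds(model, donors=[0])
        assert bonds == []
        assert "no attached hydrogen" in caplog.text


class TestOccupancy:
    def test_planted_half_occupancy_retained(self):
        traj, _ = make_hbond_trajectory(0.50, 100, seed=1)
        table = hbond_occupancy(traj)
        assert list(table.filtered().values()) == [0.50]

    def test_below_threshold_excluded(self):
        traj, _ = make_hbond_trajectory(0.40, 100, seed=1)
        table = hbond_occupancy(traj)
        assert table.filtered() == {}
        assert list(table.fractions.values()) == [0.40]

    def test_zero_threshold_lists_everything(self):
        traj, _ = make_hbond_trajectory(0.01, 100, seed=1)
        assert len(hbond_occupancy(traj).filtered(0.0)) == 1


class TestContacts:
    def _pocket(self):
        # receptor: one serine-like OH (H-bond donor) and one leucine carbon
        receptor = StructureModel(
            serials=[1, 2, 3], names=["OG", "HG", "CD1"],
            elements=["O", "H", "C"], res_names=["SER", "SER", "LEU"],
            res_numbers=[1, 1, 2], chains=["A", "A", "A"],
            coords=np.array([[0.0, 0.0, 0.0], [0.95, 0.0, 0.0],
                             [0.0, 8.0, 0.0]]))
        # ligand: an acceptor O in line with the donor O-H, plus a C near LEU
        ligand = simple_model(
            np.array([[2.9, 0.0, 0.0], [0.0, 11.5, 0.0]]),
            elements=["O", "C"], names=["O1", "C1"],
            res_names=["LIG", "LIG"], res_numbers=[10, 10], chains=["B", "B"])
        return receptor, ligand

    def test_far_ligand_empty(self):
        receptor, _ = self._pocket()
        ligand = simple_model(np.array([[50.0, 50.0, 50.0]]), elements=["C"])
        assert contact_residues(receptor, ligand, 4.0) == []

    def test_classes_assigned(self):
        receptor, ligand = self._pocket()
        rows = contact_residues(receptor, ligand, 4.0)
        classes = {r["residue_name"]: r["interaction"] for r in rows}
        assert classes == {"SER": "hydrogen-bonding", "LEU": "hydrophobic"}

    def test_rigid_motion_invariance(self):
        receptor, ligand = self._pocket()
        rot = Rotation.from_euler("y", 73, degrees=True)
        rec2 = receptor.with_coords(rot.apply(receptor.coords) + 3.0)
        lig2 = ligand.with_coords(rot.apply(ligand.coords) + 3.0)
        a = contact_residues(receptor, ligand, 4.0)
        b = contact_residues(rec2, lig2, 4.0)
        assert [(r["residue_name"], r["interaction"]) for r in a] == \
               [(r["residue_name"], r["interaction"]) for r in b]


class TestSasa:
    def test_isolated_sphere(self):
        model = simple_model(np.zeros((1, 3)), vdw=[1.7])
        _, total = sasa(model, probe=1.4, n_points=960)
        assert total == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=0.01)

    def test_distant_atoms_additive(self):
        model = simple_model(np.array([[0.0, 0, 0], [50.0, 0, 0]]),
                             vdw=[1.7, 1.5])
        areas, total = sasa(model, probe=1.4)
        assert areas[0] == pytest.approx(4 * np.pi * 3.1 ** 2, rel=0.01)
        assert areas[1] == pytest.approx(4 * np.pi * 2.9 ** 2, rel=0.01)

    def test_overlapping_spheres_match_cap_formula(self):
        # equal spheres radius R at distance d: buried cap area 2*pi*R*(R-d/2)
        R, d = 2.0, 1.5
        model = simple_model(np.array([[0.0, 0, 0], [d, 0, 0]]), vdw=[R, R])
        areas, _ = sasa(model, probe=0.0, n_points=960)
        expected = 4 * np.pi * R ** 2 - 2 * np.pi * R * (R - d / 2)
        assert areas[0] == pytest.approx(expected, rel=0.01)
        assert areas[1] == pytest.approx(expected, rel=0.01)

    def test_burial_monotonic_on_approach(self):
        prev = np.inf
        for d in (6.0, 4.0, 3.0, 2.0, 1.0):
            model = simple_model(np.array([[0.0, 0, 0], [d, 0, 0]]),
                                 vdw=[1.7, 1.7])
            areas, _ = sasa(model, probe=1.4)
            assert areas[0] <= prev + 1e-9
            prev = areas[0]


class TestPocketHydrophobicity:
    @staticmethod
    def _ring(res_names):
        n = len(res_names)
        theta = 2 * np.pi * np.arange(n) / n
        coords = np.column_stack([6 * np.cos(theta), 6 * np.sin(theta),
                                  np.zeros(n)])
        return simple_model(coords, names=["CA"] * n, res_names=res_names,
                            res_numbers=np.arange(1, n + 1))

    def test_hydrophobic_pocket_positive(self):
        model = self._ring(["ILE", "LEU", "VAL", "ILE"])
        assert pocket_hydrophobicity(model, np.arange(4)) > 0

    def test_acidic_pocket_negative(self):
        model = self._ring(["ASP", "GLU", "ASP", "GLU"])
        assert pocket_hydrophobicity(model, np.arange(4)) < 0

    def test_ordering_matches_mean_hydropathy(self):
        # uniform geometry -> uniform SASA -> score equals mean hydropathy
        a = self._ring(["ALA", "ALA", "GLY", "GLY"])
        b = self._ring(["ILE", "ILE", "VAL", "VAL"])
        assert pocket_hydrophobicity(b, np.arange(4)) > \
            pocket_hydrophobicity(a, np.arange(4))


class TestPocketWaters:
    def _traj_with_waters(self, n_near, n_far, n_frames=1):
        pocket = simple_model(np.zeros((1, 3)), names=["CA"],
                              res_names=["GLY"], res_numbers=[1])
        waters, _ = make_water_shell(np.zeros(3), n_near, n_far, seed=2)
        n = 1 + waters.n_atoms
        topo = StructureModel(
            serials=np.arange(1, n + 1),
            names=pocket.names + waters.names,
            elements=pocket.elements + waters.elements,
            res_names=pocket.res_names + waters.res_names,
            res_numbers=np.concatenate([pocket.res_numbers,
                                        waters.res_numbers]),
            chains=pocket.chains + waters.chains,
            coords=np.vstack([pocket.coords, waters.coords]))
        coords = np.repeat(topo.coords[None], n_frames, axis=0)
        return Trajectory(topology=topo, coords=coords), np.array([0])

    def test_near_waters_counted(self):
        traj, pocket = self._traj_with_waters(3, 50)
        counts, tail = count_pocket_waters(traj, pocket, cutoff=5.0)
        assert counts.tolist() == [3]
        assert tail == 3.0

    def test_tiny_cutoff_counts_nothing(self):
        traj, pocket = self._traj_with_waters(3, 50)
        counts, _ = count_pocket_waters(traj, pocket, cutoff=0.1)
        assert counts.tolist() == [0]

    def test_planted_decay_tail_mean(self):
        # water count decays linearly from 30 to 10 over 20 frames
        pocket = simple_model(np.zeros((1, 3)), names=["CA"],
                              res_names=["GLY"], res_numbers=[1])
        waters, _ = make_water_shell(np.zeros(3), 30, 0, seed=3)
        n = 1 + waters.n_atoms
        topo = StructureModel(
            serials=np.arange(1, n + 1), names=pocket.names + waters.names,
            elements=pocket.elements + waters.elements,
            res_names=pocket.res_names + waters.res_names,
            res_numbers=np.concatenate([pocket.res_numbers,
                                        waters.res_numbers]),
            chains=pocket.chains + waters.chains,
            coords=np.vstack([pocket.coords, waters.coords]))
        frames = []
        planted = np.linspace(30, 10, 20).round().astype(int)
        for k, keep in enumerate(planted):
            c = topo.coords.copy()
            c[1 + keep:, :] += 100.0  # move the rest far out of the pocket
            frames.append(c)
        traj = Trajectory(topology=topo, coords=np.stack(frames))
        counts, tail = count_pocket_waters(traj, np.array([0]), cutoff=5.0)
        assert counts.tolist() == planted.tolist()
        assert abs(tail - planted[-5:].mean()) <= 1.0

    def test_no_waters_warns(self, caplog):
        model = simple_model(np.zeros((2, 3)), names=["CA", "CB"],
                             res_names=["GLY", "GLY"], res_numbers=[1, 1])
        traj = Trajectory(topology=model, coords=model.coords[None])
        with caplog.at_level("WARNING"):
            counts, _ = count_pocket_waters(traj, np.array([0]))
        assert counts.tolist() == [0]
        assert "no water" in caplog.text
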