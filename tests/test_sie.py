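"""SIE scoring: Coulomb, Lennard-Jones, generalized Born, score arithmetic."""

import numpy as np
import pytest

from umamidyn.params import COULOMB_CONSTANT
from umamidyn.sie import (
    SIEParams, SIETerms, compute_terms, coulomb_interaction, delta_msa,
    ensemble_sie, gb_polarization, reaction_field_change, sie_score,
    vdw_interaction,
)
from umamidyn.structure import Trajectory

from conftest import simple_model


def _charged_pair(distance, q1=1.0, q2=-1.0):
    a = simple_model(np.zeros((1, 3)), elements=["N"], charges=[q1])
    b = simple_model(np.array([[distance, 0.0, 0.0]]), elements=["O"],
                     charges=[q2])
    return a, b


class TestCoulomb:
    def test_unit_charges_hand_value(self):
        # k_e / r with r = k_e / 100 gives exactly -100 kcal/mol
        a, b = _charged_pair(3.320636)
        assert coulomb_interaction(a, b, d_in=1.0) == pytest.approx(-100.0,
                                                                    abs=1e-3)

    def test_dielectric_scaling(self):
        a, b = _charged_pair(3.320636)
        e1 = coulomb_interaction(a, b, d_in=1.0)
        assert coulomb_interaction(a, b, d_in=2.25) == pytest.approx(e1 / 2.25)

    def test_neutral_ligand_zero(self):
        a, b = _charged_pair(3.0, q2=0.0)
        assert coulomb_interaction(a, b) == 0.0

    def test_overlapping_atoms_rejected(self):
        a, b = _charged_pair(0.05)
        with pytest.raises(ValueError, match="overlapping"):
            coulomb_interaction(a, b)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(11)
        rec = simple_model(rng.normal(size=(6, 3)) * 3.0, elements=["C"] * 6,
                           charges=rng.normal(size=6) * 0.3)
        lig = simple_model(rng.normal(size=(4, 3)) * 3.0 + 8.0,
                           elements=["O"] * 4, charges=rng.normal(size=4) * 0.3)
        expected = sum(
            COULOMB_CONSTANT / 2.25 * rec.charges[i] * lig.charges[j]
            / np.linalg.norm(rec.coords[i] - lig.coords[j])
            for i in range(6) for j in range(4))
        assert coulomb_interaction(rec, lig, 2.25) == pytest.approx(expected,
                                                                    abs=1e-4)


class TestLennardJones:
    TABLE = {"C": (0.11, 3.4), "O": (0.21, 3.0)}

    def _pair(self, r):
        a = simple_model(np.zeros((1, 3)), elements=["C"])
        b = simple_model(np.array([[r, 0.0, 0.0]]), elements=["C"])
        return a, b

    def test_zero_at_sigma(self):
        a, b = self._pair(3.4)
        assert vdw_interaction(a, b, self.TABLE) == pytest.approx(0.0,
                                                                  abs=1e-10)

    def test_minimum_at_rmin(self):
        a, b = self._pair(2 ** (1 / 6) * 3.4)
        assert vdw_interaction(a, b, self.TABLE) == pytest.approx(-0.11,
                                                                  abs=1e-9)

    def test_three_atom_hand_sum(self):
        rec = simple_model(np.array([[0.0, 0, 0], [4.0, 0, 0]]),
                           elements=["C", "O"])
        lig = simple_model(np.array([[2.0, 3.0, 0.0]]), elements=["C"])

        def lj(eps, sig, r):
            return 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)

        r1 = np.linalg.norm(rec.coords[0] - lig.coords[0])
        r2 = np.linalg.norm(rec.coords[1] - lig.coords[0])
        expected = (lj(0.11, 3.4, r1)
                    + lj(np.sqrt(0.11 * 0.21), (3.4 + 3.0) / 2, r2))
        assert vdw_interaction(rec, lig, self.TABLE) == pytest.approx(
            expected, abs=1e-6)

    def test_missing_type_named(self):
        a = simple_model(np.zeros((1, 3)), elements=["ZN"])
        b = simple_model(np.array([[3.0, 0, 0.0]]), elements=["C"])
        with pytest.raises(KeyError, match="ZN"):
            vdw_interaction(a, b)


class TestGeneralizedBorn:
    def test_single_ion_matches_born_formula(self):
        q, a_radius, rho, d_in = 1.0, 2.0, 1.1, 2.25
        ion = simple_model(np.zeros((1, 3)), elements=["N"], charges=[q],
                           vdw=[a_radius])
        expected = (-0.5 * COULOMB_CONSTANT * (1 / d_in - 1 / 78.5)
                    * q ** 2 / (rho * a_radius))
        assert gb_polarization(ion, d_in, rho) == pytest.approx(expected,
                                                                abs=1e-6)

    def test_uncharged_species_zero(self):
        rng = np.random.default_rng(1)
        rec = simple_model(rng.normal(size=(5, 3)) * 4.0, elements=["C"] * 5,
                           charges=np.zeros(5))
        lig = simple_model(rng.normal(size=(3, 3)) * 4.0 + 10.0,
                           elements=["O"] * 3, charges=np.zeros(3))
        assert reaction_field_change(rec, lig) == 0.0

    def test_far_separation_additive_limit(self):
        # neutral fragments: the screened cross term decays as 1/r^3
        rec = simple_model(np.array([[0.0, 0, 0], [1.5, 0, 0.0]]),
                           elements=["N", "O"], charges=[0.5, -0.5])
        lig = simple_model(np.array([[100.0, 0, 0], [101.5, 0, 0.0]]),
                           elements=["N", "O"], charges=[-0.5, 0.5])
        assert abs(reaction_field_change(rec, lig)) < 0.05

    def test_born_radius_grows_with_neighbor_burial(self):
        # a neighbor descreens solvent: polarization becomes less negative
        lone = simple_model(np.zeros((1, 3)), elements=["N"], charges=[1.0])
        g_lone = gb_polarization(lone)
        paired = simple_model(np.array([[0.0, 0, 0], [2.5, 0, 0.0]]),
                              elements=["N", "C"], charges=[1.0, 0.0])
        assert gb_polarization(paired) > g_lone


class TestScore:
    def test_zero_terms_gives_calibration_constant(self):
        total, _ = sie_score(SIETerms())
        assert total == pytest.approx(-2.89)

    def test_vdw_only_arithmetic(self):
        total, _ = sie_score(SIETerms(e_vdw=-10.0))
        assert total == pytest.approx(-2.89 + 0.1048 * (-10.0), abs=1e-9)

    def test_gamma_scales_only_cavity_term(self):
        terms = SIETerms(e_coulomb=-5.0, dg_reaction_field=3.0, e_vdw=-8.0,
                         delta_msa=-100.0)
        base, comp = sie_score(terms)
        doubled, comp2 = sie_score(terms, SIEParams(gamma=2 * 0.0129))
        assert comp2["cavity"] == pytest.approx(2 * comp["cavity"])
        assert doubled - base == pytest.approx(0.1048 * comp["cavity"])

    def test_affine_in_each_term(self):
        params = SIEParams()
        base, _ = sie_score(SIETerms(), params)
        for kwargs, coeff in [
            (dict(e_coulomb=1.0), params.alpha),
            (dict(dg_reaction_field=1.0), params.alpha),
            (dict(e_vdw=1.0), params.alpha),
            (dict(delta_msa=1.0), params.alpha * params.gamma),
        ]:
            total, _ = sie_score(SIETerms(**kwargs), params)
            assert total - base == pytest.approx(coeff, abs=1e-12)

    def test_printed_bracketing_variant(self):
        terms = SIETerms(e_coulomb=-5.0, dg_reaction_field=3.0, e_vdw=-8.0,
                         delta_msa=-100.0)
        total, _ = sie_score(terms, printed_bracketing=True)
        expected = (0.1048 * -5.0 + 3.0 - 8.0 + 0.0129 * -100.0 - 2.89)
        assert total == pytest.approx(expected)

    def test_nonfinite_terms_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            sie_score(SIETerms(e_vdw=np.inf))


class TestComplexTerms:
    def _complex(self):
        rng = np.random.default_rng(21)
        theta = 2 * np.pi * np.arange(6) / 6
        rec = simple_model(
            np.column_stack([6.5 * np.cos(theta), 6.5 * np.sin(theta),
                             np.zeros(6)]),
            elements=["C"] * 6, charges=rng.normal(size=6) * 0.1)
        lig = simple_model(rng.normal(size=(4, 3)) * 0.8, elements=["C"] * 4,
                           res_numbers=[10, 11, 12, 13],
                           charges=rng.normal(size=4) * 0.1, chains=["L"] * 4)
        return rec, lig

    def test_surface_burial_negative(self):
        rec, lig = self._complex()
        assert delta_msa(rec, lig) < 0.0

    def test_ensemble_identical_frames(self):
        rec, lig = self._complex()
        n_r, n_l = rec.n_atoms, lig.n_atoms
        merged = simple_model(
            np.vstack([rec.coords, lig.coords]),
            elements=rec.elements + lig.elements,
            res_numbers=np.concatenate([rec.res_numbers, lig.res_numbers]),
            chains=rec.chains + lig.chains,
            charges=np.concatenate([rec.charges, lig.charges]))
        traj = Trajectory(topology=merged,
                          coords=np.repeat(merged.coords[None], 6, axis=0))
        mean, sd, table = ensemble_sie(traj, np.arange(n_r),
                                       np.arange(n_r, n_r + n_l), n_frames=4)
        assert sd == 0.0
        terms = compute_terms(rec, lig)
        single, _ = sie_score(terms)
        assert mean == pytest.approx(single, abs=1e-9)
        assert len(table) == 3  # frames from the second half of 6

    def test_empty_window_rejected(self):
        rec, lig = self._complex()
        merged = simple_model(
            np.vstack([rec.coords, lig.coords]),
            elements=rec.elements + lig.elements,
            res_numbers=np.concatenate([rec.res_numbers, lig.res_numbers]),
            chains=rec.chains + lig.chains,
            charges=np.concatenate([rec.charges, lig.charges]))
        traj = Trajectory(topology=merged, coords=merged.coords[None])
        with pytest.raises(ValueError, match="empty"):
            ensemble_sie(traj, np.arange(rec.n_atoms),
                         np.arange(rec.n_atoms, merged.n_atoms),
                         window=(1.0, 1.0))
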