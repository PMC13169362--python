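"""MM terms, FD-PB solver, GB, SASA, quasi-harmonic entropy, decomposition."""

import math

import numpy as np
import pytest

from bindfe.core import GeometryError, EstimationError, SnapshotEnsemble, ThermoContext
from bindfe.endpoint import (
    _AMU_KG,
    _A2_M2,
    _HBAR_J_S,
    _KB_J_PER_K,
    _ho_entropy_per_mode,
    born_energy,
    debye_kappa,
    gb_born_radii,
    gb_polar_energy,
    mm_interaction_energy,
    mmpbsa_decompose,
    nonpolar_energy,
    pb_polar_energy,
    pb_polar_energy_richardson,
    quasiharmonic_entropy,
    sasa,
)
from bindfe.synthetic import build_toy_complex, perturb_ensemble
from conftest import make_solute


class TestMMInteraction:
    def _pair(self, r, q=(1.0, 1.0), sig=(3.0, 3.0), eps=(0.1, 0.1)):
        return make_solute([[0, 0, 0], [r, 0, 0]], charges=list(q),
                           sigmas=list(sig), epsilons=list(eps))

    def test_coulomb_at_calibrated_distance(self, ctx):
        """Two unit charges at C/100 Å give exactly 100 kcal/mol."""
        s = self._pair(ctx.coulomb_constant / 100.0)
        elec, _ = mm_interaction_energy(s, np.array([True, False]),
                                        np.array([False, True]), ctx)
        assert elec == pytest.approx(100.0, rel=1e-12)

    def test_zero_charges_zero_elec(self, ctx):
        s = self._pair(3.0, q=(0.0, 0.0))
        elec, _ = mm_interaction_energy(s, np.array([True, False]),
                                        np.array([False, True]), ctx)
        assert elec == 0.0

    def test_lj_minimum_depth(self, ctx):
        sig = 3.0
        s = self._pair(sig * 2 ** (1 / 6), q=(0, 0), eps=(0.2, 0.2))
        _, vdw = mm_interaction_energy(s, np.array([True, False]),
                                       np.array([False, True]), ctx)
        assert vdw == pytest.approx(-0.2, rel=1e-12)

    def test_overlapping_atoms_rejected(self, ctx):
        s = self._pair(0.05)
        with pytest.raises(GeometryError):
            mm_interaction_energy(s, np.array([True, False]),
                                  np.array([False, True]), ctx)


class TestPoissonBoltzmann:
    def test_born_ion_richardson_within_3pct(self, ctx, born_ion):
        exact = born_energy(1.0, 2.0, 1.0, 80.0, ctx)
        e = pb_polar_energy_richardson(born_ion, h_coarse=0.8, h_fine=0.4,
                                       eps_in=1.0, eps_out=80.0, ctx=ctx)
        assert abs(e - exact) / abs(exact) < 0.03

    def test_screened_born_within_5pct(self, ctx, born_ion):
        kappa = debye_kappa(0.15, 80.0, ctx)
        exact = born_energy(1.0, 2.0, 1.0, 80.0, ctx, kappa=kappa)
        e = pb_polar_energy_richardson(born_ion, h_coarse=0.8, h_fine=0.4,
                                       eps_in=1.0, eps_out=80.0,
                                       ionic_strength=0.15, ctx=ctx)
        assert abs(e - exact) / abs(exact) < 0.05

    def test_debye_length_at_150mM(self, ctx):
        # physiological saline has a ~8 Å Debye screening length
        assert 1.0 / debye_kappa(0.15, 80.0, ctx) == pytest.approx(7.95, abs=0.1)

    def test_grid_refinement_reduces_error(self, ctx, born_ion):
        exact = born_energy(1.0, 2.0, 1.0, 80.0, ctx)
        e_c = pb_polar_energy(born_ion, h=0.8, eps_in=1.0, eps_out=80.0, ctx=ctx)
        e_f = pb_polar_energy(born_ion, h=0.4, eps_in=1.0, eps_out=80.0, ctx=ctx)
        assert abs(e_f - exact) < abs(e_c - exact)

    def test_zero_charge_is_exactly_zero(self, ctx):
        s = make_solute([[0, 0, 0]], charges=[0.0], radii=[2.0])
        assert pb_polar_energy(s, h=0.8, ctx=ctx) == 0.0

    def test_charged_solute_solvation_is_negative(self, ctx):
        s = make_solute([[0, 0, 0], [2.5, 0, 0]], charges=[0.6, 0.4],
                        radii=[1.8, 1.6])
        assert pb_polar_energy(s, h=0.6, eps_in=1.0, eps_out=80.0, ctx=ctx) < 0


class TestGeneralizedBorn:
    def test_single_sphere_equals_born_formula(self, ctx, born_ion):
        gb = gb_polar_energy(born_ion, 1.0, 80.0, ctx)
        exact = born_energy(1.0, 2.0, 1.0, 80.0, ctx)
        assert gb == pytest.approx(exact, rel=1e-10)

    def test_single_atom_radius_is_intrinsic(self, born_ion):
        assert gb_born_radii(born_ion)[0] == pytest.approx(2.0, rel=1e-12)

    def test_self_term_uses_born_radius(self, ctx):
        """At zero distance f_GB reduces to R_i, the Born self energy."""
        s = make_solute([[0, 0, 0]], charges=[0.5], radii=[1.5])
        gb = gb_polar_energy(s, 1.0, 80.0, ctx)
        assert gb == pytest.approx(born_energy(0.5, 1.5, 1.0, 80.0, ctx), rel=1e-10)

    def test_three_atom_toy_agrees_with_pb(self, ctx):
        s = make_solute([[0, 0, 0], [2.4, 0, 0], [1.2, 1.8, 0]],
                        charges=[0.4, -0.5, 0.3], radii=[1.7, 1.5, 1.6])
        gb = gb_polar_energy(s, 1.0, 80.0, ctx)
        pb = pb_polar_energy(s, h=0.35, eps_in=1.0, eps_out=80.0, ctx=ctx)
        assert abs(gb - pb) / abs(pb) < 0.15

    def test_buried_atom_radius_grows(self):
        """Descreening by neighbours must enlarge the effective radius."""
        lone = make_solute([[0, 0, 0]], radii=[1.5])
        buried = make_solute([[0, 0, 0], [2.5, 0, 0], [-2.5, 0, 0]],
                             radii=[1.5, 1.8, 1.8])
        assert gb_born_radii(buried)[0] > gb_born_radii(lone)[0]


class TestSasa:
    def test_single_sphere_closed_form(self):
        s = make_solute([[0, 0, 0]], radii=[1.5])
        _, total = sasa(s, probe=1.4, n_points=960)
        assert total == pytest.approx(4 * np.pi * 2.9 ** 2, rel=1e-12)

    def test_distant_spheres_additive(self):
        s = make_solute([[0, 0, 0], [20.0, 0, 0]], radii=[1.5, 1.8])
        _, total = sasa(s, probe=1.4, n_points=500)
        assert total == pytest.approx(4 * np.pi * (2.9 ** 2 + 3.2 ** 2), rel=1e-12)

    def test_two_overlapping_spheres_match_cap_formula(self):
        r1, r2, d = 1.5 + 1.4, 1.8 + 1.4, 2.0
        s = make_solute([[0, 0, 0], [d, 0, 0]], radii=[1.5, 1.8])
        areas, _ = sasa(s, probe=1.4, n_points=4000)
        h1 = r1 - (d * d + r1 * r1 - r2 * r2) / (2 * d)
        h2 = r2 - (d * d + r2 * r2 - r1 * r1) / (2 * d)
        exp1 = 4 * math.pi * r1 * r1 - 2 * math.pi * r1 * h1
        exp2 = 4 * math.pi * r2 * r2 - 2 * math.pi * r2 * h2
        assert areas[0] == pytest.approx(exp1, rel=0.01)
        assert areas[1] == pytest.approx(exp2, rel=0.01)

    def test_monotone_decrease_on_approach(self):
        totals = []
        for d in (8.0, 5.0, 3.0, 2.0, 1.0):
            s = make_solute([[0, 0, 0], [d, 0, 0]], radii=[1.5, 1.5])
            totals.append(sasa(s, n_points=500)[1])
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_too_few_points_rejected(self):
        s = make_solute([[0, 0, 0]], radii=[1.5])
        with pytest.raises(EstimationError):
            sasa(s, n_points=16)


class TestNonpolar:
    def test_linear_surface_tension_model(self):
        assert nonpolar_energy(0.0, b=0.0) == 0.0
        assert nonpolar_energy(1000.0, gamma=0.00542, b=0.92) == pytest.approx(6.34)
        assert nonpolar_energy(200.0, 0.005, 0.0) == pytest.approx(
            2 * nonpolar_energy(100.0, 0.005, 0.0))


class TestQuasiharmonicEntropy:
    def test_identical_frames_zero_entropy(self, ctx):
        s = make_solute([[0, 0, 0]])
        ens = SnapshotEnsemble(solute=s, frames=np.zeros((10, 1, 3)))
        assert quasiharmonic_entropy(ens, ctx) == 0.0

    def test_gaussian_cloud_matches_ho_entropy(self, ctx, single_particle_ensemble):
        ens, sigma = single_particle_ensemble
        s_qha = quasiharmonic_entropy(ens, ctx)
        lam = 12.0 * sigma ** 2 * _AMU_KG * _A2_M2
        kT = _KB_J_PER_K * 300.0
        u = _HBAR_J_S * np.sqrt(kT / lam) / kT
        s_exact = ctx.gas_constant * 3 * _ho_entropy_per_mode(np.array([u]))[0]
        assert s_qha == pytest.approx(s_exact, rel=0.02)

    def test_entropy_increases_with_temperature(self, ctx, single_particle_ensemble):
        ens, _ = single_particle_ensemble
        hot = ThermoContext(temperature=600.0)
        assert quasiharmonic_entropy(ens, hot) > quasiharmonic_entropy(ens, ctx)

    def test_too_few_frames_rejected(self, ctx):
        s = make_solute([[0, 0, 0], [2, 0, 0]])
        ens = SnapshotEnsemble(solute=s, frames=np.random.default_rng(0)
                               .normal(size=(5, 2, 3)))
        with pytest.raises(EstimationError):
            quasiharmonic_entropy(ens, ctx)


class TestDecomposition:
    @pytest.fixture
    def toy_ensemble(self):
        solute, _ = build_toy_complex(n_residues=4, n_ligand_atoms=3,
                                      shell_radius=7.0, ligand_charge=-1.0,
                                      protein_charge=1.0, seed=3)
        ens, _ = perturb_ensemble(solute, 0.05, 3, seed=4)
        lm = solute.mask(chain="L")
        return ens, ~lm, lm

    def test_ghost_ligand_contributes_nothing(self, ctx):
        solute, _ = build_toy_complex(n_residues=4, n_ligand_atoms=2,
                                      shell_radius=7.0, seed=3)
        lm = solute.mask(chain="L")
        ghost = solute  # zero ligand charge by construction
        ghost.lj_epsilons[lm] = 0.0
        ens, _ = perturb_ensemble(ghost, 0.0, 2, seed=1)
        d = mmpbsa_decompose(ens, ~lm, lm, ctx, solvent="GB", entropy=False)
        assert d.dE_MM == pytest.approx(0.0, abs=1e-10)

    def test_terms_match_hand_summation(self, ctx, toy_ensemble):
        """The frame-averaged decomposition equals an independent per-frame
        recomputation of every term."""
        ens, pm, lm = toy_ensemble
        d = mmpbsa_decompose(ens, pm, lm, ctx, solvent="GB", entropy=False,
                             sasa_points=240)
        elec, vdw, pol, npol = [], [], [], []
        for i in range(ens.n_frames):
            fr = ens.frame(i)
            e, v = mm_interaction_energy(fr, pm, lm, ctx)
            elec.append(e)
            vdw.append(v)
            pol.append(gb_polar_energy(fr, 1.0, 80.0, ctx)
                       - gb_polar_energy(fr.subset(pm), 1.0, 80.0, ctx)
                       - gb_polar_energy(fr.subset(lm), 1.0, 80.0, ctx))
            npol.append(nonpolar_energy(sasa(fr, n_points=240)[1])
                        - nonpolar_energy(sasa(fr.subset(pm), n_points=240)[1])
                        - nonpolar_energy(sasa(fr.subset(lm), n_points=240)[1]))
        assert d.dE_elec == pytest.approx(np.mean(elec), rel=1e-12)
        assert d.dE_vdw == pytest.approx(np.mean(vdw), rel=1e-12)
        assert d.dG_polar == pytest.approx(np.mean(pol), rel=1e-12)
        assert d.dG_nonpolar == pytest.approx(np.mean(npol), rel=1e-12)

    def test_entropy_toggle_identity(self, ctx):
        solute, _ = build_toy_complex(n_residues=4, n_ligand_atoms=3,
                                      shell_radius=7.0, seed=3)
        lm = solute.mask(chain="L")
        ens, _ = perturb_ensemble(solute, 0.08, 80, seed=9)
        on = mmpbsa_decompose(ens, ~lm, lm, ctx, solvent="GB", entropy=True)
        off = mmpbsa_decompose(ens, ~lm, lm, ctx, solvent="GB", entropy=False)
        assert on.total - off.total == pytest.approx(on.minus_TdS, abs=1e-10)
        assert off.minus_TdS == 0.0

    def test_bookkeeping_identity_exact(self, ctx, toy_ensemble):
        ens, pm, lm = toy_ensemble
        d = mmpbsa_decompose(ens, pm, lm, ctx, solvent="GB", entropy=False)
        assert d.total == d.dE_MM + d.dG_polar + d.dG_nonpolar + d.minus_TdS
        assert d.dG_solvation == d.dG_polar + d.dG_nonpolar
        assert d.dH == d.dE_MM

    def test_pb_route_runs_on_toy_complex(self, ctx):
        solute, _ = build_toy_complex(n_residues=3, n_ligand_atoms=2,
                                      shell_radius=6.5, ligand_charge=-0.5,
                                      seed=3)
        lm = solute.mask(chain="L")
        ens, _ = perturb_ensemble(solute, 0.0, 1, seed=0)
        d = mmpbsa_decompose(ens, ~lm, lm, ctx, solvent="PB", entropy=False,
                             pb_h=0.8, pb_padding=6.0)
        assert np.isfinite(d.total)
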