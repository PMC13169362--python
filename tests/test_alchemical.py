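"""EXP and MBAR estimators, overlap diagnostics, cycle assembly, bootstrap."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import expit

from bindfe.alchemical import (
    FreeEnergyEstimate,
    LambdaSchedule,
    LambdaState,
    ReducedPotentialMatrix,
    bootstrap_uncertainty,
    cycle_binding_dG,
    exp_estimate,
    harmonic_restraint_correction,
    mbar_overlap,
    mbar_solve,
    statistical_inefficiency,
)
from bindfe.core import ConvergenceError, EstimationError, InvalidContextError, ThermoContext
from bindfe.synthetic import gaussian_work_samples, harmonic_ladder_ensemble


def bar_solve_oracle(w_forward: np.ndarray, w_reverse: np.ndarray) -> float:
    """Independent Bennett-acceptance-ratio solve by 1D root finding.

    Finds df such that sum_F fermi(M + w_F - df) = sum_R fermi(-M + w_R + df)
    with M = ln(N_F / N_R); fermi(x) = 1/(1+e^x).
    """
    m = np.log(len(w_forward) / len(w_reverse))

    def residual(df):
        return (expit(-(m + w_forward - df)).sum()
                - expit(-(-m + w_reverse + df)).sum())

    return brentq(residual, -100, 100, xtol=1e-12)


class TestExpEstimate:
    def test_identical_states_give_zero(self, ctx):
        est = exp_estimate(np.zeros(100), ctx, n_boot=10)
        assert est.value == 0.0

    def test_constant_shift_recovered_exactly(self, ctx):
        est = exp_estimate(np.full(50, 2.5), ctx, n_boot=10)
        assert est.value / ctx.kT == pytest.approx(2.5, abs=1e-12)

    def test_gaussian_closed_form(self, ctx):
        """For Normal(m, s^2) work the exponential average gives m - s^2/2,
        verified against numerical quadrature of the defining integral."""
        w, truth = gaussian_work_samples(2.0, 1.0, 100_000, seed=7)
        est = exp_estimate(w, ctx, n_boot=200, seed=3)
        beta_dg = est.value / ctx.kT
        sd = est.uncertainty / ctx.kT
        assert truth.payload["beta_dG"] == 1.5
        # quadrature oracle for the closed form itself
        integral = quad(lambda x: np.exp(-((x - 2.0) ** 2) / 2) / np.sqrt(2 * np.pi)
                        * np.exp(-x), -20, 20)[0]
        assert -np.log(integral) == pytest.approx(1.5, abs=1e-9)
        assert abs(beta_dg - 1.5) < 3 * sd

    def test_no_overflow_for_large_work(self, ctx):
        est = exp_estimate(np.array([700.0, 699.0, 698.0]), ctx, n_boot=0, n_blocks=3)
        assert np.isfinite(est.value)

    def test_empty_input_rejected(self, ctx):
        with pytest.raises(EstimationError):
            exp_estimate(np.array([]), ctx)


class TestMbar:
    def test_identical_rows_give_zero_df(self, ctx):
        rng = np.random.default_rng(0)
        row = rng.normal(size=200)
        m = ReducedPotentialMatrix(u=np.vstack([row, row]), counts=[100, 100])
        est = mbar_solve(m, ctx=ctx)
        assert est.per_interval[1] == pytest.approx(0.0, abs=1e-10)

    def test_harmonic_ladder_recovers_gaussian_partition_functions(self, ctx):
        m, truth = harmonic_ladder_ensemble(np.array([1.0, 4.0]), 2000, seed=11)
        est = mbar_solve(m)
        exact = 0.5 * np.log(4.0)
        # analytic SD of the two-state estimate at this n is well below 0.05
        assert est.per_interval[1] == pytest.approx(exact, abs=3 * 0.05)
        assert np.allclose(truth.payload["f"], [0.0, exact])

    def test_two_state_mbar_equals_bar_oracle(self):
        m, _ = harmonic_ladder_ensemble(np.array([1.0, 4.0]), 2000, seed=13)
        est = mbar_solve(m, tol=1e-12)
        n = 2000
        w_f = m.u[1, :n] - m.u[0, :n]          # forward work from state 0
        w_r = m.u[0, n:] - m.u[1, n:]          # reverse work from state 1
        assert est.per_interval[1] == pytest.approx(bar_solve_oracle(w_f, w_r), abs=1e-6)

    def test_gauge_invariance_per_sample_constant(self):
        """Adding a constant to every state's evaluation of one sample is a
        gauge transformation: all free energies are unchanged."""
        m, _ = harmonic_ladder_ensemble(np.array([1.0, 2.0, 4.0]), 500, seed=5)
        f0 = mbar_solve(m, tol=1e-12).per_interval
        u2 = m.u.copy()
        u2[:, 17] += 123.4
        u2[:, 300] -= 55.0
        f1 = mbar_solve(ReducedPotentialMatrix(u=u2, counts=m.counts), tol=1e-12).per_interval
        assert np.allclose(f0, f1, atol=1e-10)

    def test_state_duplication_invariance(self):
        """Splitting one state's samples into two duplicate states leaves
        every free-energy difference unchanged."""
        m, _ = harmonic_ladder_ensemble(np.array([1.0, 4.0]), 1000, seed=21)
        f_ref = mbar_solve(m, tol=1e-12).per_interval[1]
        u_dup = np.vstack([m.u[0], m.u[0], m.u[1]])
        counts = [500, 500, 1000]
        f_dup = mbar_solve(ReducedPotentialMatrix(u=u_dup, counts=counts),
                           tol=1e-12).per_interval
        assert f_dup[1] == pytest.approx(0.0, abs=1e-6)
        assert f_dup[2] == pytest.approx(f_ref, abs=1e-6)

    def test_exp_forward_reverse_bracket_mbar(self):
        """Seed-averaged forward/reverse EXP estimates bracket MBAR on
        two-state oscillator ladders: the poorly-overlapping direction is
        biased low, the well-overlapping one (slightly) high (20 seeds)."""
        ctx = ThermoContext()
        fwd, rev, mbar = [], [], []
        for seed in range(20):
            m, _ = harmonic_ladder_ensemble(np.array([1.0, 6.0]), 400, seed=seed)
            n = 400
            mbar.append(mbar_solve(m).per_interval[1])
            fwd.append(exp_estimate(m.u[1, :n] - m.u[0, :n], ctx, n_boot=0).value / ctx.kT)
            rev.append(-exp_estimate(m.u[0, n:] - m.u[1, n:], ctx, n_boot=0).value / ctx.kT)
        sem = np.std(fwd, ddof=1) / np.sqrt(len(fwd))
        assert np.mean(rev) - 3 * sem <= np.mean(mbar) <= np.mean(fwd) + 3 * sem
        # the bad-overlap direction is distinctly biased low
        assert np.mean(rev) < np.mean(mbar) - 0.05

    def test_zero_sample_perturbation_state_flagged(self):
        m, _ = harmonic_ladder_ensemble(np.array([1.0, 4.0]), 500, seed=2)
        u3 = np.vstack([m.u, 0.5 * 2.0 * (np.concatenate([
            np.random.default_rng(2).normal(0, 1, 500),
            np.random.default_rng(3).normal(0, 0.5, 500)]) ** 2)])
        est = mbar_solve(ReducedPotentialMatrix(u=u3, counts=[500, 500, 0]))
        assert any("perturbation target" in f for f in est.flags)

    def test_nonconvergence_raises_with_residual(self):
        m, _ = harmonic_ladder_ensemble(np.array([1.0, 4.0]), 200, seed=1)
        with pytest.raises(ConvergenceError) as err:
            mbar_solve(m, tol=1e-14, max_iter=2)
        assert err.value.residual is not None

    def test_counts_must_sum_to_samples(self):
        with pytest.raises(EstimationError):
            ReducedPotentialMatrix(u=np.zeros((2, 10)), counts=[4, 4])


class TestOverlap:
    def test_identical_states_uniform_overlap(self):
        rng = np.random.default_rng(8)
        row = rng.normal(size=300)
        m = ReducedPotentialMatrix(u=np.vstack([row] * 3), counts=[100, 100, 100])
        est = mbar_solve(m)
        ov = mbar_overlap(m, est)
        assert np.allclose(ov.matrix, 1.0 / 3.0, atol=1e-8)

    def test_far_separated_oscillators_near_zero_overlap(self):
        rng = np.random.default_rng(4)
        k = 50.0
        x0 = rng.normal(-10, 1 / np.sqrt(k), 500)
        x1 = rng.normal(+10, 1 / np.sqrt(k), 500)
        x = np.concatenate([x0, x1])
        u = np.vstack([0.5 * k * (x + 10) ** 2, 0.5 * k * (x - 10) ** 2])
        m = ReducedPotentialMatrix(u=u, counts=[500, 500])
        est = mbar_solve(m, max_iter=100000)
        ov = mbar_overlap(m, est)
        assert ov.matrix[0, 1] < 1e-3 and ov.matrix[1, 0] < 1e-3

    def test_rows_sum_to_one_on_random_input(self):
        for seed in range(5):
            m, _ = harmonic_ladder_ensemble(np.array([1.0, 2.0, 4.0, 8.0]), 200, seed=seed)
            ov = mbar_overlap(m, mbar_solve(m))
            assert np.allclose(ov.matrix.sum(axis=1), 1.0, atol=1e-10)

    def test_requires_solved_estimate(self):
        m, _ = harmonic_ladder_ensemble(np.array([1.0, 4.0]), 100, seed=0)
        bad = FreeEnergyEstimate(value=0.0, uncertainty=0.0, method="EXP")
        with pytest.raises(EstimationError):
            mbar_overlap(m, bad)


class TestRestraintCorrection:
    def test_volume_match_gives_zero(self, ctx):
        k0 = 2 * np.pi * ctx.kT / ctx.standard_volume ** (2 / 3)
        assert harmonic_restraint_correction(k0, ctx) == pytest.approx(0.0, abs=1e-12)

    def test_matches_3d_quadrature(self, ctx):
        from scipy.integrate import quad as q
        k = 10.0
        vol = q(lambda r: 4 * np.pi * r * r * np.exp(-0.5 * k * r * r / ctx.kT),
                0, np.inf)[0]
        expected = -ctx.kT * np.log(ctx.standard_volume / vol)
        assert harmonic_restraint_correction(k, ctx) == pytest.approx(expected, rel=1e-10)

    def test_doubling_standard_volume_shifts_by_kT_ln2(self, ctx):
        big = ThermoContext(temperature=300.0, standard_volume=2 * ctx.standard_volume)
        d = harmonic_restraint_correction(5.0, big) - harmonic_restraint_correction(5.0, ctx)
        assert d == pytest.approx(-ctx.kT * np.log(2), rel=1e-12)

    def test_nonpositive_k_rejected(self, ctx):
        with pytest.raises(EstimationError):
            harmonic_restraint_correction(0.0, ctx)


class TestCycle:
    def _leg(self, v, sd=0.0, T=300.0):
        return FreeEnergyEstimate(value=v, uncertainty=sd, method="MBAR", temperature=T)

    def test_equal_legs_zero(self):
        assert cycle_binding_dG(self._leg(3.0), self._leg(3.0)).value == 0.0

    def test_leg_swap_antisymmetry(self):
        a, b = self._leg(5.0), self._leg(2.0)
        assert cycle_binding_dG(a, b).value == -cycle_binding_dG(b, a).value

    def test_analytic_ladder_cycle(self, ctx):
        """Both legs built from analytic oscillator ladders recover the
        closed-form cycle value."""
        mc, tc = harmonic_ladder_ensemble(np.array([1.0, 8.0]), 4000, seed=31)
        ms, ts = harmonic_ladder_ensemble(np.array([1.0, 2.0]), 4000, seed=32)
        leg_c = mbar_solve(mc, ctx=ctx)
        leg_s = mbar_solve(ms, ctx=ctx)
        got = cycle_binding_dG(leg_c, leg_s).value / ctx.kT
        exact = -(tc.payload["f"][1] - ts.payload["f"][1])
        assert got == pytest.approx(exact, abs=0.1)

    def test_temperature_mismatch_rejected(self):
        with pytest.raises(InvalidContextError):
            cycle_binding_dG(self._leg(1.0, T=300), self._leg(1.0, T=310))

    def test_uncertainty_quadrature(self):
        est = cycle_binding_dG(self._leg(1.0, 0.3), self._leg(0.0, 0.4))
        assert est.uncertainty == pytest.approx(0.5)


class TestBootstrap:
    def test_constant_series_zero_sd(self):
        assert bootstrap_uncertainty(np.ones(100), np.mean, n_boot=50, seed=1) == 0.0

    def test_iid_normal_matches_clt(self):
        # 50 blocks: with only a handful of blocks the empirical block-mean
        # variance is itself too noisy for a tight CLT comparison
        rng = np.random.default_rng(12)
        x = rng.normal(size=5000)
        sd = bootstrap_uncertainty(x, np.mean, n_blocks=50, n_boot=500, seed=4)
        assert sd == pytest.approx(1 / np.sqrt(5000), rel=0.30)

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=200)
        a = bootstrap_uncertainty(x, np.std, n_boot=100, seed=77)
        b = bootstrap_uncertainty(x, np.std, n_boot=100, seed=77)
        assert a == b

    def test_too_short_series_rejected(self):
        with pytest.raises(EstimationError):
            bootstrap_uncertainty(np.arange(3), np.mean, n_blocks=5)


class TestLambdaSchedule:
    def test_valid_two_stage_schedule(self):
        states = [LambdaState(1.0, 1.0), LambdaState(0.5, 1.0), LambdaState(0.0, 1.0),
                  LambdaState(0.0, 0.5, "vdw"), LambdaState(0.0, 0.0, "vdw")]
        LambdaSchedule(states=states)

    def test_vdw_stage_must_be_discharged(self):
        with pytest.raises(ValueError):
            LambdaSchedule(states=[LambdaState(1.0, 1.0),
                                   LambdaState(0.5, 0.5, "vdw")])


def test_statistical_inefficiency_detects_correlation():
    rng = np.random.default_rng(15)
    white = rng.normal(size=4000)
    ar1 = np.empty(4000)
    ar1[0] = white[0]
    for i in range(1, 4000):
        ar1[i] = 0.9 * ar1[i - 1] + white[i]
    assert statistical_inefficiency(white) < 2.0
    assert statistical_inefficiency(ar1) > 5.0
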