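"""Adaptive Dormand-Prince integration, dense output, and the RK4 oracle."""

import math

import numpy as np
import pytest

import seirkit as sk
from seirkit.errors import DomainError, IntegrationError

from conftest import DAILY_GRID, scaled_max_deviation


def decay(t, y):
    return -y


class TestDp45Step:
    def test_zero_rhs_is_exact(self):
        st = sk.dp45_step(lambda t, y: np.zeros_like(y), 0.0,
                          np.array([3.0, -1.0]), h=0.5)
        np.testing.assert_array_equal(st.y_high, [3.0, -1.0])
        np.testing.assert_array_equal(st.y_low, [3.0, -1.0])
        assert st.error_norm == 0.0

    def test_constant_rhs_is_exact(self):
        st = sk.dp45_step(lambda t, y: np.ones_like(y), 0.0,
                          np.array([2.0]), h=0.25)
        assert st.y_high[0] == pytest.approx(2.25, abs=1e-15)
        assert st.error_norm == pytest.approx(0.0, abs=1e-12)

    def test_observed_order_at_least_five(self):
        """Halving h on y'=-y shrinks the one-step error ~2^6 (order >= 5)."""
        errs = []
        for h in (0.2, 0.1, 0.05):
            st = sk.dp45_step(decay, 0.0, np.array([1.0]), h)
            errs.append(abs(st.y_high[0] - math.exp(-h)))
        orders = [math.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert all(o >= 5.0 for o in orders)

    def test_embedded_solution_is_lower_order(self):
        st = sk.dp45_step(decay, 0.0, np.array([1.0]), 0.1)
        assert abs(st.y_low[0] - math.exp(-0.1)) > abs(st.y_high[0] - math.exp(-0.1))

    def test_invalid_step_size(self):
        with pytest.raises(DomainError):
            sk.dp45_step(decay, 0.0, np.array([1.0]), h=0.0)

    def test_nonfinite_stage_signals_failure(self):
        def blowup(t, y):
            return np.array([np.inf]) if t > 0 else -y
        with pytest.raises(IntegrationError):
            sk.dp45_step(blowup, 0.0, np.array([1.0]), h=0.2)


class TestIntegrate:
    def test_zero_rhs_constant_trajectory(self):
        traj = sk.integrate(lambda t, y: np.zeros_like(y), [5.0, 7.0], 0.0, 10.0)
        assert np.all(traj.states == [5.0, 7.0])
        assert traj.times[0] == 0.0 and traj.times[-1] == 10.0

    def test_scalar_decay_tight_tolerance(self):
        traj = sk.integrate(decay, [1.0], 0.0, 1.0,
                            config=sk.SolverConfig(rel_tol=1e-8))
        assert traj.states[-1, 0] == pytest.approx(0.3678794412, abs=1e-7)

    def test_terminates_exactly_at_t_max(self, seir_model, code_default, y0_seir):
        traj = sk.integrate(seir_model, y0_seir, 0.0, 119.5, params=code_default)
        assert traj.times[-1] == 119.5

    def test_matches_rk4_oracle_on_seir(self, dp45_daily, rk4_daily):
        dev = scaled_max_deviation(dp45_daily.states, rk4_daily.states)
        assert np.all(dev < 1e-3)

    def test_tolerance_monotonicity(self, seir_model, code_default, y0_seir,
                                    rk4_daily):
        """Tightening rel_tol 1e-5 -> 1e-8 strictly reduces the oracle gap."""
        devs = {}
        for rtol in (1e-5, 1e-8):
            dense = sk.integrate(seir_model, y0_seir, 0.0, 120.0,
                                 params=code_default,
                                 config=sk.SolverConfig(rel_tol=rtol))
            daily = sk.sample(dense, DAILY_GRID)
            devs[rtol] = scaled_max_deviation(daily.states, rk4_daily.states).max()
        assert devs[1e-8] < devs[1e-5]

    def test_closed_population_is_conserved(self):
        """No recruitment/mortality: S+E+I+R drifts < 1e-6 relative in 120 d."""
        params = sk.ParameterSet(transmission=0.3, progression=0.3, recovery=0.1)
        dense = sk.integrate(sk.get_model("seir"), [1000, 0, 1, 0], 0.0, 120.0,
                             params=params)
        totals = dense.states.sum(axis=1)
        assert np.max(np.abs(totals - 1001.0)) / 1001.0 < 1e-6

    @pytest.mark.parametrize("set_name", ["code_default", "table1"])
    def test_compartments_stay_nonnegative(self, set_name, seir_model, y0_seir):
        dense = sk.integrate(seir_model, y0_seir, 0.0, 120.0,
                             params=sk.get_parameter_set(set_name))
        assert dense.states.min() >= -1e-9

    def test_monotone_compartments(self, y0_seir):
        """Without recruitment S never rises; without mortality R never falls."""
        params = sk.ParameterSet(transmission=0.3, progression=0.3,
                                 recovery=0.1, disease_death=0.003286)
        dense = sk.integrate(sk.get_model("seir"), y0_seir, 0.0, 120.0,
                             params=params)
        daily = sk.sample(dense, DAILY_GRID)
        assert np.all(np.diff(daily.column("S")) <= 1e-9)
        assert np.all(np.diff(daily.column("R")) >= -1e-9)

    def test_scipy_rk45_cross_check(self, seir_model, code_default, y0_seir,
                                    dp45_daily):
        """Independent implementation of the same pair agrees closely."""
        from scipy.integrate import solve_ivp

        f = seir_model.bind(code_default, n_ref=float(y0_seir.sum()))
        sol = solve_ivp(f, (0.0, 120.0), y0_seir, method="RK45",
                        t_eval=DAILY_GRID, rtol=1e-8, atol=1e-8)
        dev = scaled_max_deviation(dp45_daily.states, sol.y.T)
        assert np.all(dev < 1e-3)

    def test_step_budget_enforced(self, seir_model, code_default, y0_seir):
        with pytest.raises(IntegrationError, match="max_accepted_steps"):
            sk.integrate(seir_model, y0_seir, 0.0, 120.0, params=code_default,
                         config=sk.SolverConfig(max_accepted_steps=3))

    def test_invalid_span(self, seir_model, code_default, y0_seir):
        with pytest.raises(DomainError):
            sk.integrate(seir_model, y0_seir, 10.0, 10.0, params=code_default)

    def test_solver_config_validation(self):
        with pytest.raises(DomainError):
            sk.SolverConfig(rel_tol=0.0)
        with pytest.raises(DomainError):
            sk.SolverConfig(min_step=1.0, max_step=0.1)
        with pytest.raises(DomainError):
            sk.SolverConfig(step_growth_clamp=(1.5, 5.0))


class TestSample:
    def test_node_times_reproduced_exactly(self, seir_model, code_default,
                                           y0_seir):
        dense = sk.integrate(seir_model, y0_seir, 0.0, 120.0,
                             params=code_default)
        resampled = sk.sample(dense, dense.times)
        np.testing.assert_array_equal(resampled.states, dense.states)

    def test_linear_solution_interpolated_exactly(self):
        """Constant rhs: the Hermite interpolant reproduces the exact line."""
        c = np.array([2.0, -0.5])
        dense = sk.integrate(lambda t, y: c.copy(), [0.0, 1.0], 0.0, 10.0)
        grid = np.linspace(0.3, 9.7, 17)
        out = sk.sample(dense, grid)
        expected = np.array([0.0, 1.0]) + np.outer(grid, c)
        np.testing.assert_allclose(out.states, expected, atol=1e-9)

    def test_daily_decay_error_within_tolerance_order(self):
        rel_tol = 1e-5
        dense = sk.integrate(decay, [1.0], 0.0, 10.0,
                             config=sk.SolverConfig(rel_tol=rel_tol))
        daily = sk.sample(dense, np.arange(11.0))
        err = np.abs(daily.states[:, 0] - np.exp(-daily.times))
        assert err.max() <= 10 * rel_tol

    def test_grid_outside_span_rejected(self):
        dense = sk.integrate(decay, [1.0], 0.0, 1.0)
        with pytest.raises(DomainError, match="outside"):
            sk.sample(dense, np.array([0.5, 1.5]))

    def test_unsorted_grid_rejected(self):
        dense = sk.integrate(decay, [1.0], 0.0, 1.0)
        with pytest.raises(DomainError):
            sk.sample(dense, np.array([0.5, 0.2]))


class TestRk4Reference:
    def test_zero_rhs_constant(self):
        traj = sk.rk4_reference(lambda t, y: np.zeros_like(y), [4.0], 0.0, 1.0,
                                h=0.1)
        assert np.all(traj.states == 4.0)
        assert len(traj) == 11

    def test_fourth_order_convergence(self):
        """Halving h cuts the endpoint error on y'=-y by ~16."""
        errs = []
        for h in (0.1, 0.05):
            traj = sk.rk4_reference(decay, [1.0], 0.0, 1.0, h=h)
            errs.append(abs(traj.states[-1, 0] - math.exp(-1)))
        assert errs[0] / errs[1] == pytest.approx(16.0, rel=0.15)

    def test_self_consistency_on_seir(self, seir_model, code_default, y0_seir,
                                      rk4_daily):
        """Halving the oracle's own step changes it by < 1e-8 relative."""
        dense = sk.rk4_reference(seir_model, y0_seir, 0.0, 120.0, h=5e-4,
                                 params=code_default)
        fine = sk.sample(dense, DAILY_GRID)
        dev = scaled_max_deviation(fine.states, rk4_daily.states)
        assert np.all(dev < 1e-8)

    def test_step_must_divide_span(self):
        with pytest.raises(DomainError, match="divide"):
            sk.rk4_reference(decay, [1.0], 0.0, 1.0, h=0.3)
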