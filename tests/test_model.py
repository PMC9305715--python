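"""Core model relations: conductance, flow, unloading, Cf root, integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from fruitdd import (
    DDMParameters,
    IntegrationError,
    InvalidParameterError,
    SimulationConfig,
    SourceModel,
    conductance,
    flow,
    simulate_growth,
    sink_concentration,
    source_concentration,
    unloading,
)


def bisection_cf(C, n, s, params):
    """Independent bracketing root of flow(Cf) = unloading(Cf) on (0, C).

    Same bracketing family as bisection; brentq's relative tolerance is used
    because the root can sit many orders of magnitude below C.
    """
    k = conductance(params.kappa, params.alpha, n)

    def balance(cf):
        return flow(C, cf, k) - unloading(n, s, cf, params.Vm, params.Km)

    return brentq(balance, 1e-300, C, xtol=1e-300, rtol=4 * np.finfo(float).eps)


class TestConductance:
    @pytest.mark.parametrize(
        "kappa, alpha, n, expected",
        [
            (5.0, 0.0, 1000.0, 5.0),  # size-independent pathway
            (2.0, 1.0, 10.0, 20.0),  # proportional to population size
            (3.0, 0.5, 4.0, 6.0),
        ],
    )
    def test_power_law(self, kappa, alpha, n, expected):
        assert conductance(kappa, alpha, n) == pytest.approx(expected, rel=1e-12)

    def test_log_space_branch_matches_direct_power(self):
        # huge n takes the log-space path; it must agree with the direct power
        n = 5.7e6
        assert conductance(2.0, 0.3, n) == pytest.approx(2.0 * n**0.3, rel=1e-12)

    @pytest.mark.parametrize("kwargs", [dict(kappa=0.0), dict(kappa=-1.0), dict(n=0.5)])
    def test_invalid_inputs(self, kwargs):
        args = dict(kappa=1.0, alpha=0.5, n=10.0)
        args.update(kwargs)
        with pytest.raises(InvalidParameterError):
            conductance(**args)


class TestSourceConcentration:
    def test_constant_mode_ignores_n(self):
        model = SourceModel(mode="constant", C0=0.1)
        assert source_concentration(model, 1e7) == 0.1

    def test_logistic_midpoint_is_half(self):
        model = SourceModel(mode="logistic", C0=0.1, b=0.01, d=1200.0)
        assert source_concentration(model, 1200.0) == pytest.approx(0.05, rel=1e-12)

    def test_zero_steepness_collapses_to_half(self):
        model = SourceModel(mode="logistic", C0=0.1, b=0.0, d=123.0)
        assert source_concentration(model, 5.0) == pytest.approx(0.05, rel=1e-12)

    def test_logistic_bounded_and_decreasing(self):
        model = SourceModel(mode="logistic", C0=0.1, b=0.004, d=1300.0)
        ns = np.linspace(1, 5000, 50)
        cs = np.array([source_concentration(model, n) for n in ns])
        assert np.all((cs > 0) & (cs < 0.1))
        assert np.all(np.diff(cs) < 0)


class TestFlowUnloading:
    def test_no_gradient_no_flow(self):
        assert flow(0.1, 0.1, 7.0) == 0.0

    def test_flow_value(self):
        assert flow(0.1, 0.05, 10.0) == pytest.approx(0.05)
        assert flow(0.1, 0.0, 1.0) == pytest.approx(0.01)

    def test_unloading_zero_substrate(self):
        assert unloading(5.0, 2.0, 0.0, 1e-3, 1e-2) == 0.0

    def test_unloading_half_saturation_at_km(self):
        n, s, Vm, Km = 4.0, 2.0, 3e-3, 1e-2
        assert unloading(n, s, Km, Vm, Km) == pytest.approx(n * s * Vm / 2, rel=1e-12)

    def test_unloading_saturates_at_ns_vm(self):
        n, s, Vm, Km = 4.0, 2.0, 3e-3, 1e-5
        u = unloading(n, s, 0.09, Vm, Km)  # Cf >> Km
        assert u / n == pytest.approx(s * Vm, rel=1e-3)


class TestSinkConcentration:
    def test_balances_flow_and_unloading(self, ref_params):
        C, n, s = 0.1, 50.0, 2.0
        cf = sink_concentration(C, n, s, ref_params)
        k = conductance(ref_params.kappa, ref_params.alpha, n)
        f = flow(C, cf, k)
        u = unloading(n, s, cf, ref_params.Vm, ref_params.Km)
        assert f == pytest.approx(u, rel=1e-10)
        assert 0 < cf < C

    def test_alpha_one_removes_population_dependence(self):
        p = DDMParameters(kappa=0.5, alpha=1.0, Vm=2e-3, Km=0.01)
        cf1 = sink_concentration(0.1, 1.0, 3.0, p)
        cf50 = sink_concentration(0.1, 50.0, 3.0, p)
        assert cf50 == pytest.approx(cf1, rel=1e-12)

    def test_against_bracketing_oracle(self):
        p = DDMParameters(kappa=1.0, alpha=0.5, Vm=0.002, Km=0.01)
        cf = sink_concentration(0.1, 4.0, 3.0, p)
        oracle = bisection_cf(0.1, 4.0, 3.0, p)
        assert cf == pytest.approx(oracle, rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        log_kappa=st.floats(-6, 3),
        alpha=st.floats(0, 1),
        n=st.sampled_from([1.0, 10.0, 1e4, 1e7]),
        log_vm=st.floats(-4, -2),
        log_km=st.floats(-5, -1),
        log_s=st.floats(-7, 3),
    )
    def test_oracle_equivalence_randomized(self, log_kappa, alpha, n, log_vm, log_km, log_s):
        """Closed-form root matches the bracketing oracle across 9+ decades."""
        p = DDMParameters(
            kappa=10.0**log_kappa, alpha=alpha, Vm=10.0**log_vm, Km=10.0**log_km
        )
        s = 10.0**log_s
        cf = sink_concentration(0.1, n, s, p)
        assert 0.0 < cf < 0.1
        oracle = bisection_cf(0.1, n, s, p)
        assert abs(cf - oracle) <= 1e-8 * abs(oracle)


class TestSimulateGrowth:
    def test_negligible_unloading_keeps_mass_constant(self, constant_source):
        p = DDMParameters(kappa=0.5, alpha=0.2, Vm=1e-15, Km=0.01)
        cfg = SimulationConfig(n=5.0, s0=3.0, duration=600.0)
        traj = simulate_growth(p, constant_source, cfg)
        assert traj.s[-1] == pytest.approx(3.0, rel=1e-9)

    def test_alpha_one_identical_growth_across_n(self, constant_source):
        p = DDMParameters(kappa=0.5, alpha=1.0, Vm=2e-3, Km=0.01)
        t2 = simulate_growth(p, constant_source, SimulationConfig(n=2.0, s0=3.0, duration=1200.0))
        t20 = simulate_growth(p, constant_source, SimulationConfig(n=20.0, s0=3.0, duration=1200.0))
        np.testing.assert_allclose(t2.s, t20.s, rtol=1e-12)

    def test_exponential_limit_when_km_negligible(self, constant_source):
        # supply non-limiting and Km << Cf: per-individual unloading ~ s*Vm
        p = DDMParameters(kappa=1e3, alpha=0.0, Vm=2e-3, Km=1e-12, r=0.16)
        cfg = SimulationConfig(n=5.0, s0=3.0, duration=1200.0)
        traj = simulate_growth(p, constant_source, cfg)
        closed_form = 3.0 * math.exp((1 - 0.16) * 2e-3 * 1200.0)
        assert traj.s[-1] == pytest.approx(closed_form, rel=0.01)
        assert np.all(p.Km / traj.Cf < 1e-3)

    def test_trajectory_invariants(self, ref_params, constant_source):
        cfg = SimulationConfig(n=10.0, s0=3.0, duration=1200.0)
        traj = simulate_growth(ref_params, constant_source, cfg)
        assert np.all(np.diff(traj.s) > 0)  # strictly growing: Vm > 0, C > 0
        assert np.all((traj.Cf > 0) & (traj.Cf < traj.C))
        np.testing.assert_array_equal(traj.M, traj.s / ref_params.DMC)
        np.testing.assert_array_equal(traj.TM, cfg.n * traj.M)
        assert len(traj.times) == cfg.n_steps + 1
        assert traj.times[0] == cfg.t0

    def test_mass_balance_is_bit_exact(self, ref_params, constant_source):
        cfg = SimulationConfig(n=7.0, s0=3.0, duration=600.0)
        traj = simulate_growth(ref_params, constant_source, cfg)
        assert traj.mass_balance_gap() == 0.0

    def test_halving_dt_barely_moves_final_mass(self, ref_params, constant_source):
        finals = {}
        for dt in (1.0, 0.5):
            cfg = SimulationConfig(n=20.0, s0=3.0, duration=1200.0, dt=dt)
            finals[dt] = simulate_growth(ref_params, constant_source, cfg).final_dry_mass
        assert finals[0.5] == pytest.approx(finals[1.0], rel=0.01)

    def test_duration_not_multiple_of_dt_rejected(self):
        with pytest.raises(InvalidParameterError):
            SimulationConfig(n=1.0, s0=1.0, duration=10.5, dt=1.0)

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(InvalidParameterError):
            SimulationConfig(n=0.0, s0=1.0, duration=10.0)
        with pytest.raises(InvalidParameterError):
            SimulationConfig(n=2.0, s0=-1.0, duration=10.0)
        with pytest.raises(InvalidParameterError):
            DDMParameters(kappa=1.0, alpha=0.2, Vm=1e-3, Km=1e-2, r=1.0)
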