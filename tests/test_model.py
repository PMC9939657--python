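import numpy as np
import pytest
from hypothesis import given, strategies as st

import hergfit as hf
from hergfit.errors import SimulationInfeasibleError
from hergfit.model import EXP_GUARD, GateState, PhysicalConstants, equilibrium_state


def make_theta(**overrides):
    base = dict(g_kr=1000.0, p1=0.226, p2=69.9, p3=0.0345, p4=54.62,
                p5=87.3, p6=8.91, p7=5.15, p8=31.58)
    base.update(overrides)
    return hf.ChannelParams(**base)


class TestNernstPotential:
    def test_default_constants(self):
        # (R T / z F) ln(4/110) with the standard room-temperature constants
        assert hf.nernst_potential() == pytest.approx(-0.08515, abs=5e-5)

    def test_equal_concentrations_zero(self):
        c = PhysicalConstants(K_out=50.0, K_in=50.0)
        assert hf.nernst_potential(c) == 0.0

    def test_antisymmetric_in_concentrations(self):
        a = hf.nernst_potential(PhysicalConstants(K_out=4.0, K_in=110.0))
        b = hf.nernst_potential(PhysicalConstants(K_out=110.0, K_in=4.0))
        assert a == pytest.approx(-b, rel=1e-12)

    @pytest.mark.parametrize("bad", [
        PhysicalConstants(K_out=0.0), PhysicalConstants(K_in=-1.0),
        PhysicalConstants(T=0.0), PhysicalConstants(z=0),
    ])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            hf.nernst_potential(bad)


class TestTransitionRates:
    def test_zero_voltage_returns_prefactors(self):
        th = make_theta()
        r = hf.transition_rates(th, 0.0)
        assert (r.k1, r.k2, r.k3, r.k4) == (th.p1, th.p3, th.p5, th.p7)

    def test_scalar_example(self):
        th = make_theta(p1=1.0, p2=100.0)
        r = hf.transition_rates(th, 0.06)
        assert r.k1 == pytest.approx(np.exp(6.0), rel=1e-12)

    def test_monotonic_in_voltage(self):
        th = make_theta()
        grid = np.linspace(-0.12, 0.06, 25)
        k1 = [hf.transition_rates(th, v).k1 for v in grid]
        k2 = [hf.transition_rates(th, v).k2 for v in grid]
        assert np.all(np.diff(k1) > 0) and np.all(np.diff(k2) < 0)

    def test_overflow_is_infeasibility(self):
        th = make_theta(p2=400.0)
        with pytest.raises(SimulationInfeasibleError):
            hf.transition_rates(th, (EXP_GUARD + 1) / 400.0)


class TestGateEquilibria:
    @pytest.mark.parametrize("rates, expect", [
        (hf.RateSet(2.0, 2.0, 5.0, 1.0), (0.5, None, None, None)),
        (hf.RateSet(5.0, 1.0, 3.0, 3.0), (None, 0.5, None, None)),
        (hf.RateSet(3.0, 1.0, 1.0, 1.0), (0.75, 0.5, 0.25, 0.5)),
    ])
    def test_examples(self, rates, expect):
        got = hf.gate_equilibria(rates)
        for g, e in zip(got, expect):
            if e is not None:
                assert g == pytest.approx(e, rel=1e-12)

    def test_ranges(self):
        a_inf, r_inf, ta, tr = hf.gate_equilibria(hf.RateSet(0.1, 9.0, 400.0, 2.0))
        assert 0 < a_inf < 1 and 0 < r_inf < 1 and ta > 0 and tr > 0

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            hf.gate_equilibria(hf.RateSet(0.0, 1.0, 1.0, 1.0))


class TestGateState:
    @given(a=st.floats(0, 1), r=st.floats(0, 1))
    def test_state_probabilities_sum_to_one(self, a, r):
        probs = GateState(a=a, r=r).state_probabilities()
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-15)
        assert all(-1e-15 <= p <= 1 + 1e-15 for p in probs.values())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            GateState(a=1.2, r=0.5)


class TestInstantaneousCurrent:
    def test_zero_driving_force(self):
        st8 = GateState(a=0.9, r=0.9)
        assert hf.instantaneous_current(make_theta(), st8, -0.05, -0.05) == 0.0

    @pytest.mark.parametrize("state", [GateState(0.0, 0.7), GateState(0.7, 0.0)])
    def test_closed_gate(self, state):
        assert hf.instantaneous_current(make_theta(), state, 0.02, -0.085) == 0.0

    def test_scalar_example(self):
        th = make_theta(g_kr=1000.0)
        i = hf.instantaneous_current(th, GateState(0.5, 0.5), 0.02, -0.08515)
        assert i == pytest.approx(1000 * 0.25 * 0.10515, rel=1e-10)


class TestSimulateCurrent:
    def test_steady_state_after_long_hold(self):
        """After a step held >> tau, the current reaches g*a_inf*r_inf*(V-E_K)."""
        th = make_theta()
        E_K = hf.nernst_potential()
        V = 0.0
        eq = equilibrium_state(th, V)
        _, _, ta, tr = hf.gate_equilibria(hf.transition_rates(th, V))
        hold = 12 * max(ta, tr, 0.1)
        proto = hf.VoltageProtocol(((1.0, -0.08), (hold, V)))
        trace = hf.simulate_current(th, proto, sample_rate=200.0 / (1.0 + hold))
        expected = th.g_kr * eq.a * eq.r * (V - E_K)
        assert trace.values[-1] == pytest.approx(expected, rel=1e-3)

    def test_linear_in_conductance(self, staircase):
        th1 = make_theta(g_kr=500.0)
        th2 = make_theta(g_kr=1000.0)
        t1 = hf.simulate_current(th1, staircase, 100.0)
        t2 = hf.simulate_current(th2, staircase, 100.0)
        np.testing.assert_allclose(t2.values, 2.0 * t1.values, rtol=1e-12)

    def test_zero_current_not_representable_but_tiny_g(self, staircase):
        # g must be strictly positive; the smallest prior g still scales linearly
        th = make_theta(g_kr=1e-6)
        trace = hf.simulate_current(th, staircase, 100.0)
        assert np.max(np.abs(trace.values)) < 1e-6 * 0.2  # |V-E_K| < 0.2 V, gates <= 1

    def test_ode_backend_matches_analytic(self, staircase, lit_theta):
        a = hf.simulate_current(lit_theta, staircase, 100.0)
        o = hf.simulate_current(lit_theta, staircase, 100.0, method="ode")
        rel = np.sqrt(np.mean((a.values - o.values) ** 2)) / np.std(a.values)
        assert rel < 1e-4

    def test_refining_tolerances_stable(self, staircase, lit_theta):
        o1 = hf.simulate_current(lit_theta, staircase, 50.0, method="ode",
                                 abs_tol=1e-8, rel_tol=1e-10)
        o2 = hf.simulate_current(lit_theta, staircase, 50.0, method="ode",
                                 abs_tol=1e-10, rel_tol=1e-12)
        rel = np.sqrt(np.mean((o1.values - o2.values) ** 2)) / np.std(o1.values)
        assert rel < 1e-4

    def test_gates_stay_in_unit_interval(self, staircase):
        for seed in range(5):
            th = hf.sample_params(n=1, seed=seed)[0]
            gates = hf.model.simulate_gates(th, staircase, np.linspace(0, 15.39, 500))
            assert gates.min() >= 0.0 and gates.max() <= 1.0

    def test_prior_draws_all_simulable(self, staircase):
        for th in hf.sample_params(n=100, seed=31):
            trace = hf.simulate_current(th, staircase, 100.0)
            assert np.all(np.isfinite(trace.values))

    def test_decimation_equals_coarse_sampling(self, staircase, lit_theta):
        fine = hf.simulate_current(lit_theta, staircase, 5000.0)
        coarse = hf.simulate_current(lit_theta, staircase, 100.0)
        np.testing.assert_array_equal(fine.values[::50], coarse.values)
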