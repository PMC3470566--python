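"""Gating kinetics, Markov schemes and the fast-Na conductance rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionshift import channels as ch
from ionshift.errors import StateCorruptionError
from ionshift.params import default_params


@pytest.fixture(scope="module")
def na_rates():
    return default_params()["channels"]["na"]["rates"]


class TestSlowNaFraction:
    @pytest.mark.parametrize("distance,expected", [
        (0.0, 0.0),        # soma: 5-state only
        (125.0, 0.5),      # midpoint of the linear ramp
        (250.0, 1.0),
        (300.0, 1.0),      # saturated beyond 250 um
    ])
    def test_piecewise_linear(self, distance, expected):
        assert ch.slow_na_fraction(distance) == pytest.approx(expected)

    @given(st.floats(0.0, 1000.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_monotone(self, d):
        f = ch.slow_na_fraction(d)
        assert 0.0 <= f <= 1.0
        assert ch.slow_na_fraction(d + 10.0) >= f

    def test_negative_distance_rejected(self):
        with pytest.raises(Exception):
            ch.slow_na_fraction(-1.0)


class TestNaConductance:
    def test_mixing_rule_arithmetic(self):
        # somatic g_bar with fraction 0: only the 5-state open fraction counts
        g = ch.na_conductance(0.014, 0.0, 0.2, 0.9)
        assert g == pytest.approx(0.014 * 0.2)

    def test_zero_occupancy_zero_conductance(self):
        assert ch.na_conductance(0.1, 0.5, 0.0, 0.0) == 0.0

    def test_fraction_one_ignores_5state(self):
        g1 = ch.na_conductance(0.014, 1.0, 0.3, 0.6)
        g2 = ch.na_conductance(0.014, 1.0, 0.9, 0.6)
        assert g1 == g2 == pytest.approx(0.014 * 0.6)

    def test_occupancy_out_of_range_rejected(self):
        with pytest.raises(StateCorruptionError):
            ch.na_conductance(0.014, 0.5, 1.4, 0.2)

    def test_never_exceeds_gbar(self):
        rng = np.random.default_rng(0)
        f, o5, o6 = rng.random((3, 1000))
        g = ch.na_conductance(0.014, f, o5, o6)
        assert np.all(g >= 0) and np.all(g <= 0.014)


class TestMarkovImplicit:
    def two_state(self, k12=0.3, k21=0.1):
        def q(v, ligand=0.0):
            return np.array([[[-k12, k12], [k21, -k21]]])
        return ch.MarkovScheme("toy", ("A", "B"), ("B",), q)

    def test_zero_rates_identity(self):
        scheme = ch.MarkovScheme(
            "frozen", ("A", "B"), ("B",),
            lambda v, ligand=0.0: np.zeros((1, 2, 2)))
        p = np.array([0.3, 0.7])
        np.testing.assert_allclose(
            ch.markov_step_implicit(scheme, p, -60.0, 0.0, 0.5), p,
            atol=1e-14)

    def test_two_state_matches_linear_algebra_oracle(self):
        # frozen expected value from the closed-form 2x2 solve
        # (I - dt*Q^T)^-1 p with k12=0.3, k21=0.1, dt=0.5, p=(1,0)
        k12, k21, dt = 0.3, 0.1, 0.5
        a = np.eye(2) - dt * np.array([[-k12, k12], [k21, -k21]]).T
        expected = np.linalg.solve(a, np.array([1.0, 0.0]))
        expected /= expected.sum()
        got = ch.markov_step_implicit(self.two_state(), np.array([1.0, 0.0]),
                                      -60.0, 0.0, dt)
        np.testing.assert_allclose(got, expected, rtol=1e-12)
        # and the hand-reduced closed form of that inverse
        det = (1 + dt * k12) * (1 + dt * k21) - dt ** 2 * k12 * k21
        p_a = (1 + dt * k21) / det
        assert got[0] == pytest.approx(p_a / (p_a + dt * k12 / det), rel=1e-12)

    def test_simplex_conservation_many_random_steps(self, na_rates):
        # bulk randomized sweep over voltage and step size
        rng = np.random.default_rng(42)
        scheme = ch.na_scheme_6state(na_rates)
        total = 0
        for _ in range(10):
            n = 100_000
            v = rng.uniform(-120.0, 60.0, n)
            p = rng.dirichlet(np.ones(6), size=n)
            dt = rng.uniform(1e-3, 1.0)
            p_new = ch.markov_step_implicit(scheme, p, v, 0.0, dt)
            np.testing.assert_allclose(p_new.sum(axis=1), 1.0, atol=1e-12)
            assert (p_new >= 0).all()
            total += n
        assert total == 10 ** 6

    @pytest.mark.parametrize("v", [-120.0, -66.0, 0.0, 60.0])
    def test_a_stability_at_huge_step(self, na_rates, v):
        # dt = 1 ms is 50x the production step; implicit update stays on
        # the simplex
        scheme = ch.na_scheme_5state(na_rates)
        p = scheme.initial_distribution(-66.0)
        for _ in range(100):
            p = ch.markov_step_implicit(scheme, p, v, 0.0, 1.0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p >= 0).all()

    def test_corrupted_occupancy_rejected(self, na_rates):
        scheme = ch.na_scheme_5state(na_rates)
        bad = np.array([1.5, -0.5, 0.0, 0.0, 0.0])
        with pytest.raises(StateCorruptionError):
            ch.markov_step_implicit(scheme, bad, -66.0, 0.0, 0.02)

    def test_stationary_distribution_is_fixed_point(self, na_rates):
        scheme = ch.na_scheme_6state(na_rates)
        p = scheme.initial_distribution(-66.0)
        p_new = ch.markov_step_implicit(scheme, p, -66.0, 0.0, 0.02)
        np.testing.assert_allclose(p_new, p, atol=1e-9)


class TestDualNaStep:
    def test_matches_generic_markov_path(self, na_rates):
        rng = np.random.default_rng(1)
        v = rng.uniform(-80, 20, 7)
        p5 = rng.dirichlet(np.ones(5), size=7)
        p6 = rng.dirichlet(np.ones(6), size=7)
        s5 = ch.na_scheme_5state(na_rates)
        s6 = ch.na_scheme_6state(na_rates)
        q5, q6 = ch.na_dual_step(p5.copy(), p6.copy(), v, 0.02, na_rates)
        np.testing.assert_allclose(
            q5, ch.markov_step_implicit(s5, p5, v, 0.0, 0.02), rtol=1e-12)
        np.testing.assert_allclose(
            q6, ch.markov_step_implicit(s6, p6, v, 0.0, 0.02), rtol=1e-12)

    def test_slow_inactivation_accumulates_under_depolarization(self, na_rates):
        # hold depolarized: the 6-state scheme drains into S, monotonically
        s6 = ch.na_scheme_6state(na_rates)
        p6 = np.atleast_2d(s6.initial_distribution(-66.0))
        p5 = np.atleast_2d(ch.na_scheme_5state(na_rates).initial_distribution(-66.0))
        s_occ = [p6[0, 5]]
        for _ in range(200):
            p5, p6 = ch.na_dual_step(p5, p6, np.array([-20.0]), 0.5, na_rates)
            s_occ.append(p6[0, 5])
        diffs = np.diff(s_occ)
        assert (diffs >= -1e-12).all()
        assert s_occ[-1] > 0.1


class TestHHGating:
    def make_gate(self, tau=2.0):
        return ch.GatingVariableSpec("n", 1, -30.0, 8.0, "const",
                                     {"value": tau})

    def test_current_zero_at_reversal(self):
        chan = ch.HHChannel("kdr", "k", [self.make_gate()])
        i, _ = ch.hh_current(chan, {"n": np.array([0.5])}, -90.0, -90.0,
                             0.01, 0.02)
        assert float(np.asarray(i).ravel()[0]) == pytest.approx(0.0)

    def test_gate_fixed_point_at_steady_state(self):
        gate = self.make_gate()
        chan = ch.HHChannel("kdr", "k", [gate])
        x = gate.steady_state(-40.0)
        new = ch.advance_gates(chan, {"n": x}, -40.0, 0.02)
        assert new["n"] == pytest.approx(x, rel=1e-12)

    def test_relaxation_matches_exponential(self):
        # analytic first-order ODE oracle after a voltage step
        gate = self.make_gate(tau=2.5)
        chan = ch.HHChannel("kdr", "k", [gate])
        v = 0.0
        x = gate.steady_state(-80.0)
        x0, xinf = float(x), float(gate.steady_state(v))
        dt = 0.02
        vals = {"n": np.atleast_1d(x)}
        ts = np.arange(1, 501) * dt
        errs = []
        for t in ts:
            vals = ch.advance_gates(chan, vals, v, dt)
            exact = xinf + (x0 - xinf) * np.exp(-t / 2.5)
            errs.append(abs(vals["n"][0] - exact))
        assert max(errs) < 0.01 * abs(xinf - x0)

    def test_gates_clipped_to_unit_interval(self):
        gate = ch.GatingVariableSpec("m", 1, -30.0, 8.0, "const",
                                     {"value": 0.005})
        chan = ch.HHChannel("fast", "k", [gate])
        # overshooting explicit step gets clipped
        new = ch.advance_gates(chan, {"m": np.array([0.0])}, 20.0, 0.02)
        assert 0.0 <= new["m"][0] <= 1.0

    @given(v=st.floats(-120.0, 60.0))
    @settings(max_examples=50, deadline=None)
    def test_steady_state_in_unit_interval(self, v):
        gate = self.make_gate()
        assert 0.0 <= float(gate.steady_state(v)) <= 1.0
        assert float(gate.time_constant(v)) > 0


def test_density_rules_by_radius_and_region(default_params):
    from ionshift import morphology
    model = morphology.make_fixture("branched")
    cfg = default_params["channels"]["na"]
    dens = ch.channel_density("na", cfg, model)
    soma = model.region == "soma"
    thick = (~soma) & (model.radius > 0.6)
    thin = (~soma) & (model.radius <= 0.6)
    assert (dens[soma] == cfg["densities"]["soma"]).all()
    assert (dens[thick] == cfg["densities"]["dendrite_thick"]).all()
    assert (dens[thin] == cfg["densities"]["dendrite_thin"]).all()
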