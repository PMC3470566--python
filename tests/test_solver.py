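"""Cable solve, operator splitting, clamping and axial currents."""

import numpy as np
import pytest

from ionshift import morphology, solver
from ionshift.errors import ConfigurationError
from ionshift.params import default_params
from ionshift.solver import (Drive, Simulation, SolverConfig, dense_tree_matrix,
                             detect_spikes, hines_solve, measure_axial_current)

from conftest import passive_membrane


@pytest.fixture(scope="module")
def params():
    return default_params()


class TestHinesSolve:
    @pytest.mark.parametrize("kind,kw", [
        ("ball_and_stick", {"n_segments": 6}),
        ("branched", {}),
    ])
    def test_tree_solve_equals_dense_solve(self, kind, kw):
        model = morphology.make_fixture(kind, **kw)
        rng = np.random.default_rng(2)
        g = model.axial_conductance(150.0)
        diag = rng.uniform(1.0, 3.0, model.n)
        parent = model.parent_index
        edges = parent >= 0
        diag[edges] += g[edges]
        np.add.at(diag, parent[edges], g[edges])
        rhs = rng.uniform(-1, 1, model.n)
        v_tree = hines_solve(diag, g, parent, rhs)
        a = dense_tree_matrix(diag, g, parent)
        v_dense = np.linalg.solve(a, rhs)
        np.testing.assert_allclose(v_tree, v_dense, rtol=1e-12, atol=1e-12)


class TestPassiveDynamics:
    def make_sim(self, dt=0.02, g_leak=1e-4):
        model = morphology.make_fixture("single", radius=10.0, length=20.0)
        p = default_params()
        membrane = passive_membrane(model, p, g_leak_k=g_leak)
        return model, membrane, Simulation(
            model, membrane, SolverConfig(dt=dt, record_stride=1))

    @staticmethod
    def resting_e_k(params):
        from ionshift.constants import rt_over_f
        c = params["initial_concentrations"]
        return float(rt_over_f() * np.log(c["k_o"] / c["k_i"]))

    def test_rc_step_response_matches_analytic(self, params):
        # single passive compartment, frozen concentrations:
        # V(t) = E_K + I R (1 - exp(-t/tau)), tau = c_m / g_leak = 10 ms
        model, membrane, sim = self.make_sim()
        e_k = self.resting_e_k(params)
        state = sim.init_state(e_k)
        i0 = 0.01e-6                        # 10 pA in mA
        traces, _ = sim.run(60.0, Drive(
            injected_current=lambda t: np.array([i0]),
            freeze_concentrations=True), state=state, record=("v",))
        area_cm2 = model.area[0] * 1e-8
        r_tot = 1.0 / (1e-4 * area_cm2)     # Ohm
        tau = 1.0 / (1e-4 / (1.0 * 1e-3))   # ms, c_m/g
        t = traces.time
        exact = e_k + i0 * r_tot * (1.0 - np.exp(-t / tau))
        err = np.abs(traces["v"][0] - exact).max()
        assert err / (i0 * r_tot) < 1e-3    # within 0.1 % of the step

    def test_equilibrium_is_exact_fixed_point(self, params):
        model, membrane, sim = self.make_sim()
        e_k = self.resting_e_k(params)
        state = sim.init_state(e_k)
        traces, _ = sim.run(20.0, Drive(freeze_concentrations=True),
                            state=state, record=("v",))
        assert np.abs(traces["v"] - e_k).max() < 1e-12

    def test_unconditional_stability_at_dt_1ms(self):
        model, membrane, sim = self.make_sim(dt=1.0)
        state = sim.init_state(-66.0)
        traces, _ = sim.run(500.0, Drive(freeze_concentrations=True),
                            state=state, record=("v",))
        assert np.isfinite(traces["v"]).all()
        assert np.abs(traces["v"]).max() < 150.0


class TestVoltageClamp:
    def test_clamp_at_rest_needs_no_current(self, bas_model, bas_membrane):
        sim = Simulation(bas_model, bas_membrane,
                         SolverConfig(dt=0.02, record_stride=10))
        clamp = bas_model.region == "soma"
        traces, _ = sim.run(30.0, Drive(clamp_mask=clamp,
                                        clamp_command=lambda t: -66.0),
                            record=("v", "i_clamp"))
        soma = bas_model.root
        assert np.abs(traces["i_clamp"][soma]).max() < 1e-9   # mA
        assert np.abs(traces["v"][soma] + 66.0).max() < 1e-9

    def test_dendrites_escape_somatic_clamp(self, bas_model, bas_membrane):
        # space-clamp failure: dendritic V deviates from the command
        # during strong dendritic GABA conductance
        from ionshift import protocols
        traces = protocols.run_hfs(bas_model, bas_membrane, activation=0.8,
                                   mode="clamp", clamp_mV=-75.0,
                                   duration=700.0, na_blocked=True,
                                   record=("v",))
        soma = bas_model.root
        distal = int(np.argmax(bas_model.path_distance))
        held = traces.time > 0.0            # first sample precedes the clamp
        assert np.abs(traces["v"][soma, held] + 75.0).max() < 1e-6
        assert np.abs(traces["v"][distal, held] + 75.0).max() > 3.0

    def test_biphasic_clamp_current_between_reversals(self, bas_model,
                                                      bas_membrane):
        # clamped between resting and peak E_GABA: the evoked current is
        # first outward (hyperpolarizing), later inward (depolarizing)
        from ionshift import protocols
        traces = protocols.run_hfs(bas_model, bas_membrane, activation=0.8,
                                   mode="clamp", clamp_mV=-72.0,
                                   duration=1100.0, na_blocked=True,
                                   record=("v", "i_clamp"))
        soma = bas_model.root
        t = traces.time
        ic = traces["i_clamp"][soma]
        base = ic[t < 200.0].mean()
        early = ic[(t >= 200.0) & (t <= 280.0)] - base
        late = ic[(t >= 500.0) & (t <= 900.0)] - base
        assert early.max() > 0.0
        assert late.min() < 0.0


class TestAxialCurrent:
    def test_zero_at_equal_potentials(self, bas_model):
        v = np.full(bas_model.n, -66.0)
        i = measure_axial_current(bas_model, v, 1, 0, 150.0)
        assert i == 0.0

    def test_hand_computed_two_compartment_value(self):
        model = morphology.make_fixture("ball_and_stick", n_segments=1,
                                        stick_length=50.0, stick_radius=1.0)
        v = np.array([-66.0, -60.0])
        g = model.axial_conductance(150.0)[1]
        area_cm2 = model.area[0] * 1e-8
        # depolarizing current into the soma (target) is negative
        expected = g * (v[0] - v[1]) / area_cm2
        got = measure_axial_current(model, v, 1, 0, 150.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got < 0

    def test_non_adjacent_pair_rejected(self, bas_model):
        v = np.full(bas_model.n, -66.0)
        with pytest.raises(ConfigurationError):
            measure_axial_current(bas_model, v, 0, 5, 150.0)


class TestSpikes:
    def test_threshold_crossing_with_refractory(self):
        t = np.arange(0, 20.0, 0.1)
        v = np.full_like(t, -66.0)
        for onset in (5.0, 5.5, 12.0):      # second crossing in refractory
            v[(t >= onset) & (t < onset + 0.3)] = 20.0
        spikes = detect_spikes(t, v, threshold=0.0, refractory=2.0)
        assert len(spikes) == 2

    def test_firing_on_current_step(self, bas_model, bas_membrane):
        sim = Simulation(bas_model, bas_membrane,
                         SolverConfig(dt=0.02, record_stride=5))
        n = bas_model.n
        soma = bas_model.root

        def inj(t):
            out = np.zeros(n)
            if 20.0 <= t < 220.0:
                out[soma] = 0.2e-6
            return out

        traces, _ = sim.run(250.0, Drive(injected_current=inj), record=("v",))
        spikes = detect_spikes(traces.time, traces["v"][soma])
        assert len(spikes) >= 3
        assert traces["v"][soma].max() > 0.0


class TestRecording:
    def test_traceset_shapes_and_units(self, bas_model, bas_membrane):
        sim = Simulation(bas_model, bas_membrane,
                         SolverConfig(dt=0.02, record_stride=25))
        traces, _ = sim.run(10.0, Drive(),
                            record=("v", "cl_i", "e_gaba"))
        assert traces["v"].shape == (bas_model.n, traces.time.size)
        assert traces.units["v"] == "mV"
        assert traces.units["cl_i"] == "mM"

    def test_csv_and_hdf5_round_trip(self, tmp_path, bas_model, bas_membrane):
        import h5py
        import pandas as pd
        sim = Simulation(bas_model, bas_membrane,
                         SolverConfig(dt=0.02, record_stride=25))
        traces, _ = sim.run(5.0, Drive(), record=("v",))
        csv = tmp_path / "tr.csv"
        traces.save_csv(csv)
        assert len(pd.read_csv(csv)) == traces.time.size
        h5 = tmp_path / "tr.h5"
        traces.save_hdf5(h5)
        with h5py.File(h5) as fh:
            np.testing.assert_allclose(fh["v"][...], traces["v"])

    def test_unknown_series_rejected(self, bas_model, bas_membrane):
        sim = Simulation(bas_model, bas_membrane, SolverConfig())
        with pytest.raises(ConfigurationError):
            sim.run(1.0, Drive(), record=("voltage_of_the_soul",))
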