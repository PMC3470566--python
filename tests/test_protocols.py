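"""Protocol plumbing: targeting, reproducibility, refusals, probes."""

import numpy as np
import pytest

from ionshift import morphology, protocols, solver
from ionshift.errors import ConfigurationError
from ionshift.gaba import TransmitterPulseTrain
from ionshift.params import default_params


class TestCompartmentMask:
    def test_region_shorthands(self, branched_model):
        apical = protocols.compartment_mask(branched_model, "apical")
        basal = protocols.compartment_mask(branched_model, "basal")
        soma = protocols.compartment_mask(branched_model, "soma")
        assert not (apical & basal).any()
        assert soma.sum() == 1
        assert (apical | basal | soma).sum() == branched_model.n

    def test_distance_window(self, branched_model):
        mask = protocols.compartment_mask(
            branched_model, {"kind": "apical", "min_distance": 200.0})
        assert mask.any()
        assert (branched_model.path_distance[mask] >= 200.0).all()

    def test_unknown_target_rejected(self, branched_model):
        with pytest.raises(ConfigurationError):
            protocols.compartment_mask(branched_model, "stratum_imaginarium")


class TestProtocolValidation:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ConfigurationError):
            protocols.Protocol(activation=1.2)
        with pytest.raises(ConfigurationError):
            protocols.Protocol(gaba_inhibition=-0.1)

    def test_uncalibrated_model_refused(self, bas_model, default_params):
        membrane = solver.build_membrane(bas_model, default_params)
        with pytest.raises(ConfigurationError, match="calibrat"):
            protocols.run_hfs(bas_model, membrane)

    def test_conflicting_k_modes_rejected(self, bas_model, bas_membrane):
        with pytest.raises(ConfigurationError):
            solver.Drive(k_o_frozen=True, k_o_waveform=lambda t: 0.0)


class TestStimulusBuilders:
    def test_noisy_current_reproducible(self, bas_model):
        a = protocols.make_noisy_current(bas_model, 0, 0.0, 0.1, 100.0, seed=9)
        b = protocols.make_noisy_current(bas_model, 0, 0.0, 0.1, 100.0, seed=9)
        ts = np.linspace(0, 99, 57)
        for t in ts:
            np.testing.assert_array_equal(a(t), b(t))
        c = protocols.make_noisy_current(bas_model, 0, 0.0, 0.1, 100.0, seed=10)
        assert any(not np.array_equal(a(t), c(t)) for t in ts)

    def test_glutamate_pulse_peaks_at_configured_amplitude(self, bas_model):
        mask = protocols.compartment_mask(bas_model, "apical_proximal")
        g = protocols.glutamate_pulses(bas_model, mask, [10.0], 1e-3)
        ts = np.arange(10.0, 30.0, 0.01)
        peaks = np.array([g(t).max() for t in ts])
        assert peaks.max() == pytest.approx(1e-3, rel=1e-3)
        assert g(5.0).max() == 0.0

    def test_transmitter_sum_over_trains(self, bas_model):
        m1 = protocols.compartment_mask(bas_model, "soma")
        m2 = protocols.compartment_mask(bas_model, "apical")
        t1 = TransmitterPulseTrain(pulse_onsets=[10.0])
        t2 = TransmitterPulseTrain(pulse_onsets=[10.0])
        f = protocols._transmitter([(t1, m1), (t2, m2)])
        conc = f(10.5)
        assert conc[bas_model.root] == pytest.approx(1.0)
        assert conc.max() == pytest.approx(1.0)


class TestHfsBasics:
    def test_zero_activation_resting_traces(self, bas_model, bas_membrane):
        traces = protocols.run_hfs(bas_model, bas_membrane, activation=0.0,
                                   duration=300.0)
        assert np.abs(traces["v"] + 66.0).max() < 1e-6

    def test_identical_protocols_bit_identical(self, bas_model, bas_membrane):
        kw = dict(activation=0.8, duration=320.0, na_blocked=True)
        a = protocols.run_hfs(bas_model, bas_membrane, **kw)
        b = protocols.run_hfs(bas_model, bas_membrane, **kw)
        np.testing.assert_array_equal(a["v"], b["v"])
        np.testing.assert_array_equal(a["cl_i"], b["cl_i"])

    def test_summary_fields(self, hfs_control, bas_model):
        s = protocols.hfs_response_summary(hfs_control, bas_model)
        for key in ("peak_hyperpolarization_mV", "peak_depolarization_mV",
                    "peak_dcl_i_mM", "peak_dk_o_mM"):
            assert np.isfinite(s[key])

    def test_somatic_voltage_tied_to_e_gaba_under_bias(self, bas_model,
                                                       bas_membrane):
        # constant bias currents separate resting V strongly, but during
        # the train the GABA conductance ties somatic V to somatic E_GABA
        soma = bas_model.root
        vals = {}
        for bias in (-0.1, 0.0, 0.1):
            protocol = protocols.Protocol(
                activation=0.8, duration=600.0, na_blocked=True,
                hfs_onset=150.0, current_steps=((bias, 10.0, 590.0),),
                record=("v", "e_gaba"), record_stride=50)
            tr = protocols.run_protocol(bas_model, bas_membrane, protocol)
            t = tr.time
            pre = (t > 60.0) & (t < 140.0)
            during = (t > 400.0) & (t < 540.0)
            vals[bias] = (tr["v"][soma, pre].mean(),
                          (tr["v"][soma] - tr["e_gaba"][soma])[during].mean())
        v_spread_rest = vals[0.1][0] - vals[-0.1][0]
        tie_spread = abs(vals[0.1][1] - vals[-0.1][1])
        assert v_spread_rest > 10.0
        assert tie_spread < 0.5 * v_spread_rest


class TestSecondHfs:
    def test_immediate_response_follows_local_driving_force(
            self, branched_model, branched_membrane):
        res = protocols.run_second_hfs(branched_model, branched_membrane,
                                       phase="falling", duration=1600.0,
                                       na_blocked=True)
        dv = res["immediate_dv"]
        drive = res["e_gaba_at_onset"] - res["v_at_onset"]
        # strongly depolarized-E_GABA dendrites depolarize immediately
        strong = drive > 3.0
        assert strong.any()
        assert (dv[strong] > 0).all()
        # responses rank with the local driving force among dendrites
        dend = branched_model.region != "soma"
        rho = np.corrcoef(drive[dend], dv[dend])[0, 1]
        assert rho > 0.7
        # dendrites beyond 150 um depolarize immediately
        far = branched_model.path_distance >= 150.0
        assert (dv[far] > 0).all()
        # the somatic response is weaker than the thin-dendrite response
        assert dv[branched_model.root] < dv[dend].max() / 3.0

    def test_unknown_phase_rejected(self, branched_model, branched_membrane):
        with pytest.raises(ConfigurationError):
            protocols.run_second_hfs(branched_model, branched_membrane,
                                     phase="rising")


class TestMembraneResistanceProbe:
    def test_shunting_during_hfs(self, bas_model, bas_membrane):
        distal = int(np.argmax(bas_model.path_distance))
        df = protocols.probe_membrane_resistance(
            bas_model, bas_membrane, probe_compartment=distal,
            amp_nA=-0.05, duration=1100.0, hfs_onset=300.0,
            na_blocked=True)
        pre = df.loc[df["t_ms"] < 280.0, "normalized"]
        during = df.loc[(df["t_ms"] > 360.0) & (df["t_ms"] < 650.0),
                        "normalized"]
        after = df.loc[df["t_ms"] > 800.0, "normalized"]
        assert pre.mean() == pytest.approx(1.0, abs=0.02)
        assert during.mean() < 0.5          # strong shunting
        assert after.mean() > during.mean()  # recovery begins

    def test_more_apical_conductance_more_shunting(self, bas_model,
                                                   bas_membrane):
        distal = int(np.argmax(bas_model.path_distance))
        vals = {}
        for act in (0.2, 0.8):
            df = protocols.probe_membrane_resistance(
                bas_model, bas_membrane, probe_compartment=distal,
                amp_nA=-0.05, duration=720.0, hfs_onset=300.0,
                activation=act, na_blocked=True)
            during = df.loc[(df["t_ms"] > 360.0) & (df["t_ms"] < 650.0),
                            "normalized"]
            vals[act] = during.mean()
        assert vals[0.8] < vals[0.2]


class TestSpikeProbability:
    def test_no_input_no_spikes(self, bas_model, bas_membrane):
        df = protocols.spike_probability_run(
            bas_model, bas_membrane, trials=1, seed=0, with_gaba=False,
            noise_sd_nA=0.0, glut_g_S_cm2=0.0, duration=400.0)
        assert (df["probability"] == 0).all()

    def test_probability_bounds_and_ci(self, bas_model, bas_membrane):
        df = protocols.spike_probability_run(
            bas_model, bas_membrane, trials=3, seed=2, with_gaba=False,
            duration=400.0)
        assert ((df["probability"] >= 0) & (df["probability"] <= 1)).all()
        assert (df["ci_low"] <= df["probability"] + 1e-9).all()
        assert (df["probability"] <= df["ci_high"] + 1e-9).all()

    def test_invalid_arguments_rejected(self, bas_model, bas_membrane):
        with pytest.raises(ConfigurationError):
            protocols.spike_probability_run(bas_model, bas_membrane, trials=0)
        with pytest.raises(ConfigurationError):
            protocols.spike_probability_run(bas_model, bas_membrane,
                                            glutamate_target="axonal")

    def test_early_hfs_suppresses_apical_response(self, bas_model,
                                                  bas_membrane):
        # during the initial fast hyperpolarization GABA vetoes spiking
        kw = dict(trials=2, seed=3, duration=560.0, hfs_onset=280.0,
                  glutamate_target="apical_proximal", dt=0.04,
                  noise_sd_nA=0.25, glut_g_S_cm2=6e-4)
        without = protocols.spike_probability_run(bas_model, bas_membrane,
                                                  with_gaba=False, **kw)
        with_g = protocols.spike_probability_run(bas_model, bas_membrane,
                                                 with_gaba=True, **kw)
        early = (without["pulse_t_ms"] >= 280.0) & (without["pulse_t_ms"] < 420.0)
        assert early.any()
        p_without = without.loc[early, "probability"].mean()
        p_with = with_g.loc[early, "probability"].mean()
        assert p_without > 0.3
        assert p_with < p_without


class TestSensitivitySweep:
    def test_gaba_conductance_is_dominant_parameter(self, bas_model,
                                                    bas_membrane):
        df = protocols.sensitivity_sweep(
            bas_model, bas_membrane,
            parameters=("gaba_conductance", "kcc2_density"),
            factors=(0.5,), duration=950.0)
        ctrl = df.loc[df["parameter"] == "control"].iloc[0]
        halved = df.loc[df["parameter"] == "gaba_conductance"].iloc[0]
        kcc2 = df.loc[df["parameter"] == "kcc2_density"].iloc[0]
        # halving the receptor conductance strongly cuts the excitation,
        # by far the largest effect in the sweep
        assert (halved["peak_depolarization_mV"]
                < 0.65 * ctrl["peak_depolarization_mV"])
        assert (halved["depolarization_auc_mV_ms"]
                < 0.6 * ctrl["depolarization_auc_mV_ms"])
        assert halved["effect_mV"] > 3.0 * kcc2["effect_mV"]
        # sorted output puts the dominant parameter first after control
        assert df.iloc[1]["parameter"] == "gaba_conductance"

    def test_unknown_parameter_rejected(self, bas_model, bas_membrane):
        with pytest.raises(ConfigurationError):
            protocols.sensitivity_sweep(bas_model, bas_membrane,
                                        parameters=("osmolarity",))
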