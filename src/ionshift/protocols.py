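"""Stimulation protocols.

Encodes the computational experiments run on a calibrated model:

* high-frequency GABA stimulation (HFS): 40 transmitter pulses at
  100 Hz delivered to the soma and apical dendrites, under current
  clamp or somatic voltage clamp;
* a second identical HFS during the falling phase of the response or
  after recovery, with the immediate response classified per
  compartment by comparing V to the local GABA_A reversal potential;
* interventions: partial GABA_A block (quinine mode), partial KCC2
  block, frozen or clamped extracellular potassium, a KCC2 variant that
  senses only the resting [K]o, and an enlarged extracellular shell in
  the dendrites;
* a single "physiological" GABA pulse after HFS, confined to the distal
  dendrites or to the perisomatic region, classified as excitatory or
  inhibitory from the somatic response;
* time-resolved membrane-resistance probing with brief hyperpolarizing
  pulses;
* spike probability in response to periodic glutamate pulses riding on
  a noisy somatic current, with and without HFS;
* a coarse sensitivity sweep of the parameters governing the
  GABA_A-mediated depolarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .gaba import TransmitterPulseTrain
from .ion_homeostasis import ION_INDEX
from .solver import Drive, Membrane, Simulation, SolverConfig, TraceSet, detect_spikes

APICAL_REGIONS = ("apical_proximal", "radiatum_thick_medial",
                  "radiatum_thick_distal_or_thin", "lacunosum_moleculare")
BASAL_REGIONS = ("oriens_proximal", "oriens_distal")


def compartment_mask(model, targets) -> np.ndarray:
    """Boolean mask from target descriptors.

    ``targets`` is an iterable of region names or the shorthands
    ``"soma"``, ``"apical"``, ``"basal"``, ``"axon"``, ``"all"``, or a
    dict with ``min_distance``/``max_distance`` (um) and optional
    ``kind`` restricting to apical/basal.
    """
    if isinstance(targets, (str, dict)):
        targets = (targets,)
    mask = np.zeros(model.n, dtype=bool)
    region = model.region
    dist = model.path_distance
    for t in targets:
        if isinstance(t, dict):
            m = np.ones(model.n, dtype=bool)
            if "kind" in t:
                m &= compartment_mask(model, t["kind"])
            if "min_distance" in t:
                m &= dist >= t["min_distance"]
            if "max_distance" in t:
                m &= dist <= t["max_distance"]
            mask |= m
        elif t == "all":
            mask |= np.ones(model.n, dtype=bool)
        elif t == "apical":
            mask |= np.isin(region, APICAL_REGIONS)
        elif t == "basal":
            mask |= np.isin(region, BASAL_REGIONS)
        elif t in ("soma", "axon"):
            mask |= region == t
        elif t in region:
            mask |= region == t
        else:
            raise ConfigurationError(f"unknown stimulation target {t!r}")
    return mask


@dataclass
class Protocol:
    """A declarative protocol: stimuli, interventions, solver settings."""

    duration: float = 1600.0
    dt: float = 0.02
    hfs_onset: float = 200.0
    hfs_pulses: int = 40
    hfs_rate_hz: float = 100.0
    activation: float = 0.8
    targets: tuple = ("soma", "apical")
    current_steps: tuple = ()          # (amp_nA, onset_ms, duration_ms) at soma
    gaba_inhibition: float = 0.0       # fraction of receptors blocked
    kcc2_inhibition: float = 0.0       # fraction of transport blocked
    k_o_frozen: bool = False
    kcc2_frozen_k: bool = False
    shell_override: dict | None = None  # {"fraction":..., "beyond_um":...}
    clamp_mV: float | None = None       # somatic voltage clamp command
    na_blocked: bool = False
    record: tuple = ("v", "cl_i", "k_o", "e_gaba", "e_cl")
    record_stride: int = 50
    seed: int | None = None

    def __post_init__(self):
        for name in ("activation", "gaba_inhibition", "kcc2_inhibition"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {val}")


def _require_calibrated(membrane: Membrane):
    if not membrane.calibrated:
        raise ConfigurationError(
            "model is not calibrated; run ionshift.calibration.balance_rest "
            "before applying a stimulation protocol")


def _transmitter(events):
    """Sum of (train, mask) transmitter sources as a t -> (N,) callable."""
    def conc(t):
        total = 0.0
        for train, mask in events:
            total = total + train.concentration(t) * mask
        return total
    return conc


def make_noisy_current(model, compartment: int, mean_nA: float, sd_nA: float,
                       duration: float, seed: int, segment_ms: float = 1.0):
    """Gaussian noise current, piecewise constant per segment (mA)."""
    rng = np.random.default_rng(seed)
    n_seg = int(np.ceil(duration / segment_ms)) + 1
    vals = (mean_nA + sd_nA * rng.standard_normal(n_seg)) * 1e-6
    n = model.n

    def current(t):
        out = np.zeros(n)
        out[compartment] = vals[min(int(t / segment_ms), n_seg - 1)]
        return out
    return current


def glutamate_pulses(model, mask, onsets, g_peak_S_cm2: float,
                     tau_rise: float = 0.5, tau_decay: float = 3.0):
    """Double-exponential conductance transients at the given onsets."""
    onsets = np.asarray(onsets, dtype=float)
    t_peak = (tau_rise * tau_decay / (tau_decay - tau_rise)
              * np.log(tau_decay / tau_rise))
    norm = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)

    def conductance(t):
        dt = t - onsets
        dt = dt[(dt >= 0) & (dt < 10.0 * tau_decay)]
        if dt.size == 0:
            return np.zeros(model.n)
        amp = np.sum(np.exp(-dt / tau_decay) - np.exp(-dt / tau_rise)) / norm
        return g_peak_S_cm2 * amp * mask
    return conductance


def _apply_static_interventions(model, membrane, protocol: Protocol):
    """Shell-fraction override returns a modified model copy."""
    if protocol.shell_override:
        model = model.with_shell_fraction(
            protocol.shell_override["fraction"],
            protocol.shell_override.get("beyond_um", 0.0))
    return model, membrane


def run_protocol(model, membrane: Membrane, protocol: Protocol,
                 extra_events=None, state=None,
                 v_rest: float = -66.0) -> TraceSet:
    """Run a declarative protocol and return the recorded traces."""
    _require_calibrated(membrane)
    model, membrane = _apply_static_interventions(model, membrane, protocol)
    cfg = SolverConfig(dt=protocol.dt, record_stride=protocol.record_stride)
    sim = Simulation(model, membrane, cfg)

    events = []
    if protocol.activation > 0 and protocol.hfs_pulses > 0:
        train = TransmitterPulseTrain.hfs(
            onset=protocol.hfs_onset, n_pulses=protocol.hfs_pulses,
            rate_hz=protocol.hfs_rate_hz)
        events.append((train, compartment_mask(model, protocol.targets)))
    if extra_events:
        events.extend(extra_events)

    injected = None
    if protocol.current_steps:
        soma = model.root
        steps = tuple(protocol.current_steps)
        n = model.n

        def injected(t):
            out = np.zeros(n)
            for amp_nA, onset, dur in steps:
                if onset <= t < onset + dur:
                    out[soma] += amp_nA * 1e-6
            return out

    drive = Drive(
        injected_current=injected,
        transmitter=_transmitter(events) if events else None,
        gaba_activation=protocol.activation if events else 0.0,
        gaba_scale=1.0 - protocol.gaba_inhibition,
        kcc2_scale=1.0 - protocol.kcc2_inhibition,
        k_o_frozen=protocol.k_o_frozen,
        kcc2_frozen_k=protocol.kcc2_frozen_k,
        na_blocked=protocol.na_blocked,
    )
    if protocol.clamp_mV is not None:
        clamp_mask = model.region == "soma"
        drive.clamp_mask = clamp_mask
        cmd = float(protocol.clamp_mV)
        drive.clamp_command = lambda t: cmd
        record = tuple(set(protocol.record) | {"i_clamp"})
    else:
        record = protocol.record
    traces, _ = sim.run(protocol.duration, drive, state=state, v0=v_rest,
                        record=record)
    return traces


def run_hfs(model, membrane: Membrane, activation: float = 0.8,
            targets=("soma", "apical"), mode: str = "free",
            clamp_mV: float = -75.0, **kwargs) -> TraceSet:
    """The canonical HFS experiment: 40 GABA pulses at 100 Hz.

    ``mode`` is ``"free"`` (current clamp) or ``"clamp"`` (somatic
    voltage clamp at ``clamp_mV``; dendrites evolve freely).
    """
    protocol = Protocol(activation=activation, targets=targets,
                        clamp_mV=clamp_mV if mode == "clamp" else None,
                        **kwargs)
    return run_protocol(model, membrane, protocol)


def hfs_response_summary(traces: TraceSet, model, v_rest: float = -66.0,
                         onset: float = 200.0) -> dict:
    """Peak hyperpolarization/depolarization and ion transients."""
    soma = model.root
    t = traces.time
    v = traces["v"][soma]
    early = (t >= onset) & (t <= onset + 150.0)
    late = t >= onset + 150.0
    out = {
        "peak_hyperpolarization_mV": float(v_rest - v[early].min()),
        "peak_depolarization_mV": float(v[late].max() - v_rest),
        "depolarization_auc_mV_ms": float(
            np.trapezoid(np.clip(v[late] - v_rest, 0, None), t[late])),
    }
    if "cl_i" in traces.data:
        cl = traces["cl_i"]
        out["peak_dcl_i_mM"] = float((cl - cl[:, :1]).max())
    if "k_o" in traces.data:
        ko = traces["k_o"]
        out["peak_dk_o_mM"] = float((ko - ko[:, :1]).max())
    if "e_gaba" in traces.data:
        eg = traces["e_gaba"]
        out["peak_e_gaba_soma_mV"] = float(eg[soma].max())
        out["peak_e_gaba_mV"] = float(eg.max())
    return out


def run_second_hfs(model, membrane: Membrane, phase: str = "falling",
                   activation: float = 0.8, duration: float = 2600.0,
                   recovery_tol_mV: float = 1.0,
                   window_ms: float = 15.0, **kwargs) -> dict:
    """Two identical HFS trains; the second at a response-defined time.

    ``phase`` is ``"falling"`` (25% decay from the peak of the
    GABA-mediated depolarization) or ``"recovered"`` (V back within
    ``recovery_tol_mV`` of rest).  Returns traces plus the immediate
    per-compartment response to the second train -- the mean voltage
    deviation in the first ``window_ms``, detrended against the
    pre-onset drift -- and the sign predicted by E_GABA - V at onset.
    """
    _require_calibrated(membrane)
    if phase not in ("falling", "recovered"):
        raise ConfigurationError(f"unknown phase {phase!r}")
    base = Protocol(activation=activation, duration=duration, **kwargs)
    control = run_protocol(model, membrane, base)
    soma = model.root
    t = control.time
    v = control["v"][soma]
    v_rest = v[t < base.hfs_onset].mean()
    late = t >= base.hfs_onset + 150.0
    ipk = np.argmax(np.where(late, v, -np.inf))
    t_peak, v_peak = t[ipk], v[ipk]
    if phase == "falling":
        target_v = v_peak - 0.25 * (v_peak - v_rest)
        after = (t > t_peak) & (v <= target_v)
        if not after.any():
            raise ConfigurationError(
                "response does not decay 25% within the run; extend duration")
        t2 = float(t[after][0])
    elif phase == "recovered":
        after = (t > t_peak) & (np.abs(v - v_rest) < recovery_tol_mV)
        if not after.any():
            raise ConfigurationError(
                "membrane does not recover within the run; extend duration")
        t2 = float(t[after][0])

    train2 = TransmitterPulseTrain.hfs(onset=t2, n_pulses=base.hfs_pulses,
                                       rate_hz=base.hfs_rate_hz)
    mask = compartment_mask(model, base.targets)
    needed = t2 + 1000.0 * base.hfs_pulses / base.hfs_rate_hz + 400.0
    full = replace(base, duration=max(duration, needed))
    traces = run_protocol(model, membrane, full, extra_events=[(train2, mask)])

    # immediate response at second-train onset, detrended per compartment
    tt = traces.time
    i0 = np.searchsorted(tt, t2)
    i1 = np.searchsorted(tt, t2 + window_ms)
    ipre = np.searchsorted(tt, t2 - 50.0)
    vv = traces["v"]
    v0 = vv[:, i0]
    dv = np.empty(model.n)
    for i in range(model.n):
        slope = np.polyfit(tt[ipre:i0 + 1], vv[i, ipre:i0 + 1], 1)[0]
        predicted = v0[i] + slope * (tt[i0:i1] - tt[i0])
        dv[i] = (vv[i, i0:i1] - predicted).mean()
    e_gaba0 = traces["e_gaba"][:, i0]
    return {
        "traces": traces,
        "control": control,
        "t_second": t2,
        "t_peak": t_peak,
        "immediate_dv": dv,
        "predicted_sign": np.sign(e_gaba0 - v0),
        "v_at_onset": v0,
        "e_gaba_at_onset": e_gaba0,
    }


def run_intervention(model, membrane: Membrane, intervention: dict,
                     **kwargs) -> TraceSet:
    """HFS with one of the mechanistic interventions applied.

    ``intervention`` keys: ``gaba_inhibition``, ``kcc2_inhibition``,
    ``k_o_frozen``, ``kcc2_frozen_k``, ``shell_override``.
    """
    if intervention.get("k_o_frozen") and intervention.get("k_o_waveform"):
        raise ConfigurationError("conflicting extracellular-K modes")
    protocol = Protocol(**{**kwargs, **intervention})
    return run_protocol(model, membrane, protocol)


def run_secondary_pulse(model, membrane: Membrane,
                        location: str = "distal_dendrites",
                        t_after_hfs: float = 600.0,
                        with_hfs: bool = True,
                        activation: float = 0.8,
                        window_ms: float = 40.0, **kwargs) -> dict:
    """A single GABA pulse after HFS, confined to one region.

    ``location``: ``"distal_dendrites"`` (> 200 um from the soma) or
    ``"perisomatic"`` (soma and apical < 50 um).  The somatic response
    in ``window_ms`` after the pulse, detrended against the pre-pulse
    drift, is classified as ``"excitatory"`` (net depolarization or
    spikes) or ``"inhibitory"``.
    """
    _require_calibrated(membrane)
    if location == "distal_dendrites":
        mask = compartment_mask(model, {"kind": "apical", "min_distance": 200.0})
    elif location == "perisomatic":
        mask = compartment_mask(model, "soma")
    else:
        raise ConfigurationError(f"unknown pulse location {location!r}")
    if not mask.any():
        raise ConfigurationError(f"no compartments match location {location!r}")

    base = Protocol(activation=activation, **kwargs)
    if not with_hfs:
        base = replace(base, hfs_pulses=0)
    hfs_end = base.hfs_onset + 1000.0 * base.hfs_pulses / base.hfs_rate_hz
    t_pulse = hfs_end + t_after_hfs
    pulse = TransmitterPulseTrain(pulse_onsets=[t_pulse])
    duration = max(base.duration, t_pulse + 250.0)
    protocol = replace(base, duration=duration)
    traces = run_protocol(model, membrane, protocol,
                          extra_events=[(pulse, mask)])

    soma = model.root
    t, v = traces.time, traces["v"][soma]
    i0 = np.searchsorted(t, t_pulse)
    i1 = np.searchsorted(t, t_pulse + window_ms)
    ipre = np.searchsorted(t, t_pulse - 50.0)
    # detrend against the ongoing (pulse-free) drift of the membrane
    slope = np.polyfit(t[ipre:i0 + 1], v[ipre:i0 + 1], 1)[0]
    predicted = v[i0] + slope * (t[i0:i1] - t[i0])
    net = float((v[i0:i1] - predicted).mean())
    spikes = detect_spikes(t[i0:i1], v[i0:i1])
    classification = "excitatory" if (net > 0 or spikes.size) else "inhibitory"
    return {"traces": traces, "t_pulse": t_pulse, "net_dv": net,
            "n_spikes": int(spikes.size), "classification": classification}


def probe_membrane_resistance(model, membrane: Membrane, probe_compartment: int,
                              amp_nA: float = -0.1, pulse_ms: float = 5.0,
                              period_ms: float = 50.0,
                              duration: float = 1500.0,
                              activation: float = 0.8,
                              hfs_onset: float = 400.0,
                              **kwargs) -> pd.DataFrame:
    """Somatic deflection to brief probe pulses, normalized to baseline.

    Hyperpolarizing pulses are injected into ``probe_compartment`` every
    ``period_ms``; the per-pulse somatic deflection -- measured against
    an identical probe-free run, so the ongoing GABA response cancels --
    is divided by the mean pre-HFS deflection, giving a time-resolved
    membrane-resistance fraction (1.0 before HFS, near 0 when the
    membrane is shunted).
    """
    _require_calibrated(membrane)
    protocol = Protocol(activation=activation, hfs_onset=hfs_onset,
                        duration=duration, record=("v",),
                        record_stride=25, **kwargs)
    model2, membrane2 = _apply_static_interventions(model, membrane, protocol)
    cfg = SolverConfig(dt=protocol.dt, record_stride=protocol.record_stride)
    sim = Simulation(model2, membrane2, cfg)
    onsets = np.arange(period_ms, duration - pulse_ms, period_ms)
    n = model2.n

    def inj(t):
        out = np.zeros(n)
        phase = t % period_ms
        if phase < pulse_ms and t >= period_ms:
            out[probe_compartment] = amp_nA * 1e-6
        return out

    events = []
    if protocol.hfs_pulses > 0 and activation > 0:
        train = TransmitterPulseTrain.hfs(onset=hfs_onset,
                                          n_pulses=protocol.hfs_pulses,
                                          rate_hz=protocol.hfs_rate_hz)
        events.append((train, compartment_mask(model2, protocol.targets)))
    transmitter = _transmitter(events) if events else None
    drive = Drive(injected_current=inj, transmitter=transmitter,
                  gaba_activation=activation,
                  na_blocked=protocol.na_blocked)
    reference = Drive(transmitter=transmitter, gaba_activation=activation,
                      na_blocked=protocol.na_blocked)
    traces, _ = sim.run(duration, drive, record=("v",))
    ref_traces, _ = sim.run(duration, reference, record=("v",))

    soma = model2.root
    t = traces.time
    diff = traces["v"][soma] - ref_traces["v"][soma]
    rows = []
    for onset in onsets:
        i0 = np.searchsorted(t, onset)
        i1 = np.searchsorted(t, onset + pulse_ms + 2.0)
        if i1 <= i0 + 1 or i0 == 0:
            continue
        deflection = -diff[i0:i1].min()        # hyperpolarizing probe
        rows.append((onset, deflection))
    df = pd.DataFrame(rows, columns=["t_ms", "deflection_mV"])
    baseline = df.loc[df["t_ms"] < hfs_onset - pulse_ms, "deflection_mV"].mean()
    df["normalized"] = df["deflection_mV"] / baseline
    df["during_hfs"] = ((df["t_ms"] >= hfs_onset)
                        & (df["t_ms"] <= hfs_onset
                           + 1000.0 * protocol.hfs_pulses / protocol.hfs_rate_hz))
    return df


def spike_probability_run(model, membrane: Membrane,
                          glutamate_target: str = "apical_proximal",
                          trials: int = 20, seed: int = 0,
                          with_gaba: bool = True,
                          noise_mean_nA: float = 0.0,
                          noise_sd_nA: float = 0.12,
                          glut_g_S_cm2: float = 2e-4,
                          glut_rate_hz: float = 10.0,
                          duration: float = 1400.0,
                          hfs_onset: float = 400.0,
                          activation: float = 0.8,
                          spike_window_ms: float = 10.0,
                          dt: float = 0.02) -> pd.DataFrame:
    """Per-glutamate-pulse firing probability across noisy trials.

    Glutamate pulses at ``glut_rate_hz`` target the apical-proximal or
    basal dendrites; a noisy current in the soma sets the baseline
    excitability.  A spike counts if the soma crosses threshold within
    ``spike_window_ms`` of the pulse.  Wilson 95% confidence intervals
    are attached per pulse.
    """
    _require_calibrated(membrane)
    if trials < 1:
        raise ConfigurationError("trials must be >= 1")
    if glutamate_target not in ("apical_proximal", "basal"):
        raise ConfigurationError(f"unknown glutamate target {glutamate_target!r}")
    glut_mask = compartment_mask(
        model, "basal" if glutamate_target == "basal" else "apical_proximal")
    glut_mask &= model.region != "soma"
    soma = model.root
    pulse_onsets = np.arange(100.0, duration - 20.0, 1000.0 / glut_rate_hz)

    cfg = SolverConfig(dt=dt, record_stride=10)
    events = []
    if with_gaba:
        train = TransmitterPulseTrain.hfs(onset=hfs_onset)
        events.append((train, compartment_mask(model, ("soma", "apical"))))

    hits = np.zeros(pulse_onsets.size, dtype=int)
    for trial in range(trials):
        noise = make_noisy_current(model, soma, noise_mean_nA, noise_sd_nA,
                                   duration, seed=seed * 100003 + trial)
        drive = Drive(
            injected_current=noise,
            transmitter=_transmitter(events) if events else None,
            gaba_activation=activation if events else 0.0,
            glutamate_conductance=glutamate_pulses(model, glut_mask,
                                                   pulse_onsets, glut_g_S_cm2),
        )
        sim = Simulation(model, membrane, cfg)
        traces, _ = sim.run(duration, drive, record=("v",))
        spikes = detect_spikes(traces.time, traces["v"][soma])
        for j, onset in enumerate(pulse_onsets):
            if np.any((spikes >= onset) & (spikes <= onset + spike_window_ms)):
                hits[j] += 1

    p = hits / trials
    # Wilson 95% interval
    z = 1.959963984540054
    denom = 1.0 + z ** 2 / trials
    center = (p + z ** 2 / (2 * trials)) / denom
    half = z * np.sqrt(p * (1 - p) / trials + z ** 2 / (4 * trials ** 2)) / denom
    hfs_end = hfs_onset + 400.0
    return pd.DataFrame({
        "pulse_t_ms": pulse_onsets,
        "probability": p,
        "ci_low": np.clip(center - half, 0, 1),
        "ci_high": np.clip(center + half, 0, 1),
        "during_hfs": (pulse_onsets >= hfs_onset) & (pulse_onsets <= hfs_end),
        "after_hfs": pulse_onsets > hfs_end,
    })


SWEEP_PARAMETERS = ("cl_i_init", "kcc2_density", "k_buffer_capacity",
                    "hco3_permeability", "gaba_conductance")


def sensitivity_sweep(model, membrane: Membrane, parameters=None,
                      factors=(0.5, 1.5), activation: float = 0.8,
                      duration: float = 1400.0, **kwargs) -> pd.DataFrame:
    """Peak GABA-mediated depolarization under parameter perturbations.

    Each parameter is scaled by each factor, the membrane is
    re-balanced at rest, and the HFS protocol is run with fast Na
    blocked.  Reports peak depolarization and its area, sorted by
    effect size relative to the control run.
    """
    from .calibration import balance_rest

    _require_calibrated(membrane)
    parameters = parameters or SWEEP_PARAMETERS
    for p in parameters:
        if p not in SWEEP_PARAMETERS:
            raise ConfigurationError(f"unknown sweep parameter {p!r}")

    def run_one(mb, mdl):
        protocol = Protocol(activation=activation, duration=duration,
                            na_blocked=True, record=("v",), **kwargs)
        traces = run_protocol(mdl, mb, protocol)
        return hfs_response_summary(traces, mdl, onset=protocol.hfs_onset)

    rows = []
    control = run_one(membrane, model)
    rows.append(("control", 1.0, control["peak_depolarization_mV"],
                 control["depolarization_auc_mV_ms"]))

    for pname in parameters:
        for f in factors:
            if f == 1.0:
                continue
            mb = membrane.scale()
            if pname == "cl_i_init":
                mb.initial_concentrations = dict(mb.initial_concentrations)
                mb.initial_concentrations["cl_i"] *= f
            elif pname == "kcc2_density":
                mb.kcc2_vmax = mb.kcc2_vmax * f
            elif pname == "k_buffer_capacity":
                mb.glial = replace(mb.glial, total=mb.glial.total * f)
            elif pname == "hco3_permeability":
                mb.hco3_fraction = min(mb.hco3_fraction * f, 1.0)
            elif pname == "gaba_conductance":
                mb.gaba_gmax = mb.gaba_gmax * f
            balance_rest(model, mb)
            summary = run_one(mb, model)
            rows.append((pname, f, summary["peak_depolarization_mV"],
                         summary["depolarization_auc_mV_ms"]))

    df = pd.DataFrame(rows, columns=["parameter", "factor",
                                     "peak_depolarization_mV",
                                     "depolarization_auc_mV_ms"])
    ctrl = df.loc[0, "peak_depolarization_mV"]
    df["effect_mV"] = (df["peak_depolarization_mV"] - ctrl).abs()
    return pd.concat([df.iloc[:1],
                      df.iloc[1:].sort_values("effect_mV", ascending=False)],
                     ignore_index=True)
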