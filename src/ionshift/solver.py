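"""Coupled voltage / gating / concentration integrator.

One time step applies operator splitting in a fixed order:

1. explicit Euler update of all Hodgkin-Huxley gates,
2. implicit Euler update of the Markov schemes (fast Na, GABA_A),
3. implicit Euler solve of the cable equation on the branched tree --
   a direct, exact solve of the symmetric tridiagonal-on-a-tree system
   (Hines elimination),
4. explicit update of ion concentrations, glial buffer, longitudinal
   diffusion and the NKCC1 carrier state.

The voltage solve treats all conductance-based currents implicitly in V
(conductances frozen at their post-update values) and transporter/pump
currents as constants within the step, which keeps the scheme
unconditionally stable for the passive system at any dt.

Voltage clamp is implemented by exact row substitution in the linear
system; the reported clamp current is the total membrane plus axial
current required to hold the command potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import channels as ch
from . import transporters as tr
from .constants import ION_NAMES
from .errors import ConfigurationError, IntegrationError
from .gaba import gaba_reversal, gaba_scheme
from .constants import ION_VALENCE, rt_over_f
from .ion_homeostasis import (DiffusionConstants, GlialBufferParams, ION_INDEX,
                              IonState, concentration_step, diffusion_step,
                              glial_buffer_step, make_diffusion_workspace,
                              nernst, reversal_potentials)


@dataclass
class SolverConfig:
    dt: float = 0.02                    # ms
    capacitance: float = 1.0            # uF/cm^2
    axial_resistivity: float = 150.0    # Ohm*cm
    record_stride: int = 25             # record every N steps
    record: tuple = ("v", "cl_i", "k_o", "e_gaba", "e_cl")
    spike_threshold: float = 0.0        # mV
    spike_refractory: float = 2.0       # ms
    temperature_k: float = 273.15 + 32.0


@dataclass
class TraceSet:
    """Recorded time series on a shared time base.

    ``data`` maps a series name to an array of shape (N, T) for
    per-compartment series or (T,) for global ones.  ``units`` records
    the unit string per series.
    """

    time: np.ndarray
    data: dict
    units: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.data[key]

    def to_frame(self, name: str, compartments=None):
        import pandas as pd
        arr = self.data[name]
        if arr.ndim == 1:
            return pd.DataFrame({"time_ms": self.time, name: arr})
        comps = range(arr.shape[0]) if compartments is None else compartments
        out = {"time_ms": self.time}
        for c in comps:
            out[f"{name}_{c}"] = arr[c]
        return pd.DataFrame(out)

    def save_csv(self, path, names=None):
        import pandas as pd
        names = names or list(self.data)
        frames = [self.to_frame(n).set_index("time_ms") for n in names]
        pd.concat(frames, axis=1).to_csv(path)

    def save_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as fh:
            fh.create_dataset("time_ms", data=self.time)
            for name, arr in self.data.items():
                ds = fh.create_dataset(name, data=arr)
                ds.attrs["units"] = self.units.get(name, "")


def detect_spikes(time, v, threshold=0.0, refractory=2.0):
    """Upward threshold-crossing times with a refractory period (ms)."""
    v = np.asarray(v)
    crossings = np.where((v[:-1] < threshold) & (v[1:] >= threshold))[0]
    out = []
    last = -np.inf
    for idx in crossings:
        t = time[idx + 1]
        if t - last >= refractory:
            out.append(t)
            last = t
    return np.asarray(out)


# ---------------------------------------------------------------------------
# membrane assembly

@dataclass
class Membrane:
    """Per-compartment mechanism placements for one model."""

    hh_channels: dict            # name -> (HHChannel, gbar array S/cm^2)
    gna_bar: np.ndarray          # fast Na total conductance, S/cm^2
    slow_fraction: np.ndarray    # 6-state share of gna_bar
    na_rates: dict
    na5: ch.MarkovScheme
    na6: ch.MarkovScheme
    gaba: ch.MarkovScheme
    gaba_counts: np.ndarray      # synapses per compartment
    gaba_gmax: np.ndarray        # fully-open conductance density, S/cm^2
    hco3_fraction: float
    kcc2: tr.Kcc2Params
    kcc2_vmax: np.ndarray        # mA/cm^2
    nkcc1: tr.Nkcc1Params
    nkcc1_vmax: np.ndarray
    pumps: tr.PumpParams
    nak_imax: np.ndarray
    nacax_imax: np.ndarray
    capump_imax: np.ndarray
    g_leak_na: np.ndarray        # S/cm^2
    g_leak_k: np.ndarray
    g_leak_cl: np.ndarray
    g_leak_ca: np.ndarray
    calibrated: bool = False
    glial: GlialBufferParams = field(default_factory=GlialBufferParams)
    diffusion: DiffusionConstants = field(default_factory=DiffusionConstants)
    initial_concentrations: dict = field(default_factory=dict)

    def scale(self, **factors) -> "Membrane":
        """Copy with named density arrays multiplied by given factors."""
        import copy
        out = copy.deepcopy(self)
        for name, f in factors.items():
            if not hasattr(out, name):
                raise ConfigurationError(f"unknown membrane field {name!r}")
            setattr(out, name, getattr(out, name) * f)
        return out


def build_membrane(model, params: dict) -> Membrane:
    """Instantiate all mechanisms on a morphology at parameter-file
    densities.  Pump rates, leaks and the NKCC1/NaCaX scales start at
    zero; the calibration module determines them."""
    n = model.n
    hh = {}
    for name, cfg in params["channels"].items():
        if cfg["kind"] != "hh":
            continue
        hh[name] = (ch.HHChannel.from_config(name, cfg),
                    ch.channel_density(name, cfg, model))
    na_cfg = params["channels"]["na"]
    gna = ch.channel_density("na", na_cfg, model)
    frac = ch.slow_na_fraction(model.path_distance,
                               na_cfg["slow_fraction_saturation_um"])
    frac = np.where(model.region == "soma", 0.0, frac)

    from .gaba import SynapseDistribution, place_synapses
    dist = SynapseDistribution(params["gaba_a"]["densities_per_um"])
    counts, gmax = place_synapses(model, dist,
                                  params["gaba_a"]["quantal_conductance_nS"])

    t_cfg = params["transporters"]
    kcc2 = tr.Kcc2Params.from_config(t_cfg["kcc2"])
    membrane = Membrane(
        hh_channels=hh,
        gna_bar=gna,
        slow_fraction=frac,
        na_rates=dict(na_cfg["rates"]),
        na5=ch.na_scheme_5state(na_cfg["rates"]),
        na6=ch.na_scheme_6state(na_cfg["rates"]),
        gaba=gaba_scheme(params["gaba_a"]["rates"]),
        gaba_counts=counts,
        gaba_gmax=gmax,
        hco3_fraction=float(params["gaba_a"]["hco3_fraction"]),
        kcc2=kcc2,
        kcc2_vmax=np.full(n, kcc2.vmax),
        nkcc1=tr.Nkcc1Params.from_config(t_cfg["nkcc1"]),
        nkcc1_vmax=np.zeros(n),
        pumps=tr.PumpParams.from_config(t_cfg),
        nak_imax=np.zeros(n),
        nacax_imax=np.zeros(n),
        capump_imax=np.full(n, float(t_cfg["ca_pump"]["imax_mA_cm2"])),
        g_leak_na=np.zeros(n),
        g_leak_k=np.zeros(n),
        g_leak_cl=np.zeros(n),
        g_leak_ca=np.full(n, float(params.get("leaks", {}).get("g_ca_S_cm2", 0.0))),
        glial=GlialBufferParams.from_config(params["glial_buffer"]),
        diffusion=DiffusionConstants(**params["diffusion_um2_ms"]),
        initial_concentrations=dict(params["initial_concentrations"]),
    )
    return membrane


# ---------------------------------------------------------------------------
# stimulation bundle

@dataclass
class Drive:
    """Everything time-dependent or interventional applied to one run."""

    injected_current: object = None      # t -> (N,) mA
    transmitter: object = None           # t -> (N,) mM free GABA
    gaba_activation: object = 1.0        # scalar or (N,) fraction
    glutamate_conductance: object = None  # t -> (N,) S/cm^2
    clamp_mask: object = None            # (N,) bool
    clamp_command: object = None         # t -> mV
    gaba_scale: float = 1.0              # receptor inhibition (quinine mode)
    kcc2_scale: float = 1.0              # transporter inhibition
    k_o_frozen: bool = False             # hold [K]o at its initial value
    k_o_waveform: object = None          # t -> (N,) mM, clamps [K]o
    kcc2_frozen_k: bool = False          # KCC2 senses resting [K]o only
    na_blocked: bool = False             # zero fast-Na conductance
    freeze_concentrations: bool = False  # skip all concentration updates

    def __post_init__(self):
        if self.k_o_frozen and self.k_o_waveform is not None:
            raise ConfigurationError("conflicting [K]o clamp modes")


# ---------------------------------------------------------------------------
# Hines direct tree solve

def hines_solve(diag, off, parent, rhs):
    """Direct solve of the symmetric tree system.

    A[i,i] = diag[i]; A[i,p] = A[p,i] = -off[i] for p = parent[i].
    Compartments are ordered parents-before-children.
    """
    d = diag.copy()
    b = rhs.copy()
    n = d.size
    for i in range(n - 1, 0, -1):
        p = parent[i]
        if p < 0:
            continue
        f = off[i] / d[i]
        d[p] -= off[i] * f
        b[p] += b[i] * f
    v = np.empty(n)
    for i in range(n):
        p = parent[i]
        if p < 0:
            v[i] = b[i] / d[i]
        else:
            v[i] = (b[i] + off[i] * v[p]) / d[i]
    return v


def dense_tree_matrix(diag, off, parent):
    """The same system as a dense matrix (test oracle for the tree solve)."""
    n = diag.size
    a = np.diag(diag.astype(float))
    for i in range(n):
        p = parent[i]
        if p >= 0:
            a[i, p] -= off[i]
            a[p, i] -= off[i]
    return a


def voltage_clamp_run(model, membrane, command, duration: float,
                      clamped=None, drive: "Drive" = None,
                      config: "SolverConfig" = None,
                      record=("v", "i_clamp")) -> "TraceSet":
    """Clamp a compartment set to a command waveform and record the
    clamp current.

    ``command`` is a callable t -> mV or a constant; ``clamped`` is a
    boolean mask (default: the somatic compartments).  Unclamped
    compartments evolve freely, so dendritic escape from a somatic
    clamp is reproduced.
    """
    import dataclasses
    sim = Simulation(model, membrane, config or SolverConfig())
    if clamped is None:
        clamped = model.region == "soma"
    cmd = command if callable(command) else (lambda t, c=float(command): c)
    drive = dataclasses.replace(drive or Drive(), clamp_mask=clamped,
                                clamp_command=cmd)
    traces, _ = sim.run(duration, drive, record=record)
    return traces


def measure_axial_current(model, v, from_comp: int, to_comp: int,
                          axial_resistivity: float) -> float:
    """Axial current between adjacent compartments, normalized to the
    target membrane area (mA/cm^2).

    Sign convention: current flowing *into* the target from a more
    depolarized neighbor is negative (inward-current convention).
    """
    p = model.parent_index
    if p[from_comp] == to_comp:
        g = model.axial_conductance(axial_resistivity)[from_comp]
    elif p[to_comp] == from_comp:
        g = model.axial_conductance(axial_resistivity)[to_comp]
    else:
        raise ConfigurationError(
            f"compartments {from_comp} and {to_comp} are not adjacent")
    area_cm2 = model.area[to_comp] * 1e-8
    return g * (v[to_comp] - v[from_comp]) / area_cm2


# ---------------------------------------------------------------------------
# simulation state

@dataclass
class SimState:
    t: float
    v: np.ndarray
    gates: dict                  # channel -> gate -> (N,)
    na5: np.ndarray              # (N, 5)
    na6: np.ndarray              # (N, 6)
    gaba: np.ndarray             # (N, 6)
    nkcc1_y: np.ndarray          # (N,)
    ions: IonState
    cum_current: np.ndarray      # (4, N) time-integrated per-ion current
    cum_hco3: np.ndarray         # (N,)

    def copy(self) -> "SimState":
        return SimState(
            t=self.t, v=self.v.copy(),
            gates={c: {g: a.copy() for g, a in gs.items()}
                   for c, gs in self.gates.items()},
            na5=self.na5.copy(), na6=self.na6.copy(), gaba=self.gaba.copy(),
            nkcc1_y=self.nkcc1_y.copy(), ions=self.ions.copy(),
            cum_current=self.cum_current.copy(), cum_hco3=self.cum_hco3.copy(),
        )


class Simulation:
    """Bind a morphology, a membrane and solver settings; run protocols."""

    def __init__(self, model, membrane: Membrane, config: SolverConfig | None = None):
        self.model = model
        self.membrane = membrane
        self.config = config or SolverConfig()
        self.g_axial = model.axial_conductance(self.config.axial_resistivity)
        self.area_cm2 = model.area * 1e-8
        self._parent = model.parent_index
        self._edges = np.where(self._parent >= 0)[0]
        self._diff_ws = make_diffusion_workspace(model)
        self._rtf_over_z = rt_over_f(self.config.temperature_k) / ION_VALENCE
        self._e_hco3 = float(nernst(membrane.initial_concentrations["hco3_o"],
                                    membrane.initial_concentrations["hco3_i"],
                                    -1.0, self.config.temperature_k))
        self._na_possible = bool(np.any(membrane.gna_bar > 0))
        self._gaba_possible = bool(np.any(membrane.gaba_gmax > 0))
        # glutamate split between Na and K chosen so the mixed current
        # reverses at 0 mV with the initial concentrations
        self._glu_na_fraction = None

    def _reversals(self, ions: IonState) -> dict:
        """Nernst potentials for the four dynamic ions plus fixed HCO3."""
        e = self._rtf_over_z[:, None] * np.log(ions.shell / ions.intra)
        e_gaba = gaba_reversal(e[2], self._e_hco3, self.membrane.hco3_fraction)
        return {"e_na": e[0], "e_k": e[1], "e_cl": e[2], "e_ca": e[3],
                "e_hco3": self._e_hco3, "e_gaba": e_gaba}

    # -- initialization ---------------------------------------------------
    def init_state(self, v0: float = -66.0) -> SimState:
        m, mb = self.model, self.membrane
        n = m.n
        ions = IonState.uniform(n, mb.initial_concentrations, mb.glial)
        gates = {}
        v = np.full(n, v0)
        for name, (channel, _) in mb.hh_channels.items():
            gates[name] = channel.steady_gates(v)
        na5 = np.tile(mb.na5.initial_distribution(v0), (n, 1))
        na6 = np.tile(mb.na6.initial_distribution(v0), (n, 1))
        gaba = np.tile(mb.gaba.initial_distribution(), (n, 1))
        y = np.full(n, tr.nkcc1_steady_y(
            ions.get("na", "i"), ions.get("na", "o"),
            ions.get("k", "i"), ions.get("k", "o"),
            ions.get("cl", "i"), ions.get("cl", "o"), mb.nkcc1))
        return SimState(t=0.0, v=v, gates=gates, na5=na5, na6=na6, gaba=gaba,
                        nkcc1_y=y, ions=ions,
                        cum_current=np.zeros((4, n)), cum_hco3=np.zeros(n))

    # -- core step --------------------------------------------------------
    def step(self, state: SimState, drive: Drive, k_o_ref=None) -> dict:
        """Advance one dt; mutates ``state``; returns per-step diagnostics."""
        cfg, m, mb = self.config, self.model, self.membrane
        dt = cfg.dt
        n = m.n
        v_old = state.v
        ions = state.ions
        rev = self._reversals(ions)
        e_gaba = rev["e_gaba"]

        # (1) explicit gate updates
        for name, (channel, _) in mb.hh_channels.items():
            state.gates[name] = ch.advance_gates(channel, state.gates[name],
                                                 v_old, dt)

        # (2) implicit Markov updates
        na_on = (not drive.na_blocked) and self._na_possible
        if na_on:
            state.na5, state.na6 = ch.na_dual_step(
                state.na5, state.na6, v_old, dt, mb.na_rates)
        gaba_on = self._gaba_possible
        ligand = np.zeros(n)
        if drive.transmitter is not None:
            ligand = np.asarray(drive.transmitter(state.t), dtype=float)
        if gaba_on:
            state.gaba = ch.markov_step_implicit(mb.gaba, state.gaba,
                                                 v_old, ligand, dt, check=False)

        # (3) conductances and constant currents
        g_by_ion = {ion: np.zeros(n) for ion in ("na", "k", "cl", "ca", "hco3")}
        if na_on:
            g_na_chan = ch.na_conductance(
                mb.gna_bar, mb.slow_fraction,
                mb.na5.open_fraction(state.na5), mb.na6.open_fraction(state.na6))
            g_by_ion["na"] += g_na_chan
        for name, (channel, gbar) in mb.hh_channels.items():
            g = gbar * channel.open_fraction(state.gates[name])
            if channel.ion == "mixed":
                g_by_ion["na"] += channel.na_fraction * g
                g_by_ion["k"] += (1.0 - channel.na_fraction) * g
            else:
                g_by_ion[channel.ion] += g
        g_by_ion["na"] += mb.g_leak_na
        g_by_ion["k"] += mb.g_leak_k
        g_by_ion["cl"] += mb.g_leak_cl
        g_by_ion["ca"] += mb.g_leak_ca

        activation = np.asarray(drive.gaba_activation) * drive.gaba_scale
        g_gaba = mb.gaba_gmax * activation * mb.gaba.open_fraction(state.gaba)
        g_by_ion["cl"] = g_by_ion["cl"] + (1.0 - mb.hco3_fraction) * g_gaba
        g_by_ion["hco3"] = g_by_ion["hco3"] + mb.hco3_fraction * g_gaba

        g_glu_na = g_glu_k = 0.0
        if drive.glutamate_conductance is not None:
            g_glu = np.asarray(drive.glutamate_conductance(state.t))
            if self._glu_na_fraction is None:
                f = -rev["e_k"] / (rev["e_na"] - rev["e_k"])
                self._glu_na_fraction = float(np.mean(f))
            g_glu_na = self._glu_na_fraction * g_glu
            g_glu_k = (1.0 - self._glu_na_fraction) * g_glu
            g_by_ion["na"] = g_by_ion["na"] + g_glu_na
            g_by_ion["k"] = g_by_ion["k"] + g_glu_k

        # transporters: explicit within the step
        na_i, na_o = ions.get("na", "i"), ions.get("na", "o")
        k_i, k_o = ions.get("k", "i"), ions.get("k", "o")
        cl_i, cl_o = ions.get("cl", "i"), ions.get("cl", "o")
        ca_i, ca_o = ions.get("ca", "i"), ions.get("ca", "o")

        k_o_for_kcc2 = k_o_ref if (drive.kcc2_frozen_k and k_o_ref is not None) else k_o
        i_kcc2_k, i_kcc2_cl = tr.kcc2_currents(
            k_i, k_o_for_kcc2, cl_i, cl_o, mb.kcc2,
            vmax=mb.kcc2_vmax * drive.kcc2_scale, check=False)
        i_nk_na, i_nk_k, i_nk_cl, y_new = tr.nkcc1_current(
            na_i, na_o, k_i, k_o, cl_i, cl_o, state.nkcc1_y, dt,
            mb.nkcc1, vmax=mb.nkcc1_vmax, check=False)
        state.nkcc1_y = y_new
        i_p_na, i_p_k = tr.nak_pump(na_i, k_o, mb.pumps, imax=mb.nak_imax,
                                    check=False)
        i_x = tr.nacax_master_current(v_old, na_i, na_o, ca_i, ca_o,
                                      mb.pumps, imax=mb.nacax_imax, check=False)
        i_cap = tr.ca_pump(ca_i, mb.pumps, imax=mb.capump_imax, check=False)

        const_by_ion = {
            "na": i_p_na + 3.0 * i_x + i_nk_na,
            "k": i_p_k + i_kcc2_k + i_nk_k,
            "cl": i_kcc2_cl + i_nk_cl,
            "ca": -2.0 * i_x + i_cap,
        }
        i_const_net = sum(const_by_ion.values())     # net charge, mA/cm^2

        # (4) implicit voltage solve
        e_by_ion = {"na": rev["e_na"], "k": rev["e_k"], "cl": rev["e_cl"],
                    "ca": rev["e_ca"], "hco3": rev["e_hco3"]}
        g_sum = sum(g_by_ion.values())
        ge_sum = sum(g_by_ion[i] * e_by_ion[i] for i in g_by_ion)

        c_row = cfg.capacitance * self.area_cm2 * 1e-3 / dt    # mA/mV
        diag = c_row + self.area_cm2 * g_sum
        off = self.g_axial
        # add axial conductances to both ends of every edge
        edges = self._edges
        diag[edges] += off[edges]
        np.add.at(diag, self._parent[edges], off[edges])

        i_inj = np.zeros(n)
        if drive.injected_current is not None:
            i_inj = np.asarray(drive.injected_current(state.t), dtype=float)
        rhs = c_row * v_old + self.area_cm2 * (ge_sum - i_const_net) + i_inj

        clamped = None
        if drive.clamp_mask is not None:
            clamped = np.asarray(drive.clamp_mask, dtype=bool)
            v_cmd = float(drive.clamp_command(state.t))
            # exact row substitution: move known voltages to the rhs
            for i in np.where(clamped)[0]:
                p = self._parent[i]
                if p >= 0 and not clamped[p]:
                    rhs[p] += off[i] * v_cmd
                for c in np.where(self._parent == i)[0]:
                    if not clamped[c]:
                        rhs[c] += off[c] * v_cmd
            off_solve = off.copy()
            for i in np.where(clamped)[0]:
                off_solve[i] = 0.0
                off_solve[np.where(self._parent == i)[0]] = 0.0
            diag_solve = diag.copy()
            diag_solve[clamped] = 1.0
            rhs_solve = rhs.copy()
            rhs_solve[clamped] = v_cmd
            v_new = hines_solve(diag_solve, off_solve, self._parent, rhs_solve)
        else:
            v_new = hines_solve(diag, off, self._parent, rhs)

        if not np.all(np.isfinite(v_new)):
            bad = int(np.where(~np.isfinite(v_new))[0][0])
            raise IntegrationError(
                f"non-finite voltage in compartment {bad} at t={state.t:.3f} ms")

        # (5) per-ion membrane currents at the new voltage
        currents = np.empty((4, n))
        for idx, ion in enumerate(ION_NAMES):
            currents[idx] = (g_by_ion[ion] * (v_new - e_by_ion[ion])
                             + const_by_ion[ion])
        i_hco3 = g_by_ion["hco3"] * (v_new - rev["e_hco3"])

        i_clamp = None
        if clamped is not None:
            # electrode current: membrane ionic - axial inflow, in mA
            i_mem_tot = (currents.sum(axis=0) + i_hco3) * self.area_cm2
            axial_in = np.zeros(n)
            for i in range(n):
                p = self._parent[i]
                if p >= 0:
                    axial_in[i] += off[i] * (v_new[p] - v_new[i])
                    axial_in[p] += off[i] * (v_new[i] - v_new[p])
            i_clamp = np.where(clamped, i_mem_tot - axial_in - i_inj, 0.0)

        # (6) concentrations, buffering, diffusion
        if not drive.freeze_concentrations:
            concentration_step(ions, currents, m, dt)
            glial_buffer_step(ions, mb.glial, dt)
            diffusion_step(ions, m, mb.diffusion, dt, workspace=self._diff_ws)
            if drive.k_o_frozen and k_o_ref is not None:
                ions.shell[ION_INDEX["k"]] = k_o_ref
            elif drive.k_o_waveform is not None:
                ions.shell[ION_INDEX["k"]] = np.asarray(drive.k_o_waveform(state.t))

        state.cum_current += currents * dt
        state.cum_hco3 += i_hco3 * dt
        state.v = v_new
        state.t += dt

        return {
            "e_gaba": e_gaba, "e_cl": rev["e_cl"], "e_k": rev["e_k"],
            "i_gaba_cl": (1.0 - mb.hco3_fraction) * g_gaba
            * (v_new - rev["e_cl"]),
            "i_gaba_hco3": i_hco3,
            "i_kcc2": i_kcc2_k,
            "i_clamp": i_clamp,
            "gaba_open": mb.gaba.open_fraction(state.gaba),
        }

    # -- run loop ----------------------------------------------------------
    def run(self, duration: float, drive: Drive | None = None,
            state: SimState | None = None, v0: float = -66.0,
            record: tuple | None = None) -> tuple[TraceSet, SimState]:
        """Integrate for ``duration`` ms and return traces + final state."""
        cfg = self.config
        drive = drive or Drive()
        if state is None:
            state = self.init_state(v0)
        k_o_ref = state.ions.shell[ION_INDEX["k"]].copy()
        names = record if record is not None else cfg.record
        n_steps = int(round(duration / cfg.dt))
        stride = max(1, cfg.record_stride)
        n_rec = n_steps // stride + 1
        n = self.model.n

        per_comp = {
            "v": lambda st, d: st.v,
            "cl_i": lambda st, d: st.ions.get("cl", "i"),
            "cl_o": lambda st, d: st.ions.get("cl", "o"),
            "k_o": lambda st, d: st.ions.get("k", "o"),
            "k_i": lambda st, d: st.ions.get("k", "i"),
            "na_i": lambda st, d: st.ions.get("na", "i"),
            "ca_i": lambda st, d: st.ions.get("ca", "i"),
            "e_gaba": lambda st, d: d["e_gaba"],
            "e_cl": lambda st, d: d["e_cl"],
            "e_k": lambda st, d: d["e_k"],
            "i_gaba_cl": lambda st, d: d["i_gaba_cl"],
            "i_gaba_hco3": lambda st, d: d["i_gaba_hco3"],
            "i_gaba": lambda st, d: d["i_gaba_cl"] + d["i_gaba_hco3"],
            "i_kcc2": lambda st, d: d["i_kcc2"],
            "i_clamp": lambda st, d: (d["i_clamp"] if d["i_clamp"] is not None
                                      else np.zeros(st.v.size)),
            "gaba_open": lambda st, d: d["gaba_open"],
        }
        units = {"v": "mV", "cl_i": "mM", "cl_o": "mM", "k_o": "mM",
                 "k_i": "mM", "na_i": "mM", "ca_i": "mM", "e_gaba": "mV",
                 "e_cl": "mV", "e_k": "mV", "i_gaba_cl": "mA/cm^2",
                 "i_gaba_hco3": "mA/cm^2", "i_gaba": "mA/cm^2",
                 "i_kcc2": "mA/cm^2", "i_clamp": "mA", "gaba_open": ""}
        for name in names:
            if name not in per_comp:
                raise ConfigurationError(f"unknown record series {name!r}")

        time = np.empty(n_rec)
        data = {name: np.empty((n, n_rec)) for name in names}

        # record the initial sample
        rev0 = reversal_potentials(state.ions,
                                   temperature_k=cfg.temperature_k,
                                   hco3_fraction=self.membrane.hco3_fraction)
        diag0 = {"e_gaba": rev0["e_gaba"], "e_cl": rev0["e_cl"],
                 "e_k": rev0["e_k"],
                 "i_gaba_cl": np.zeros(n), "i_gaba_hco3": np.zeros(n),
                 "i_kcc2": np.zeros(n), "i_clamp": None,
                 "gaba_open": self.membrane.gaba.open_fraction(state.gaba)}
        time[0] = state.t
        for name in names:
            data[name][:, 0] = per_comp[name](state, diag0)

        rec = 1
        for istep in range(1, n_steps + 1):
            diag = self.step(state, drive, k_o_ref=k_o_ref)
            if istep % stride == 0 and rec < n_rec:
                time[rec] = state.t
                for name in names:
                    data[name][:, rec] = per_comp[name](state, diag)
                rec += 1

        time = time[:rec]
        data = {k: v[:, :rec] for k, v in data.items()}
        return TraceSet(time=time, data=data,
                        units={k: units[k] for k in names}), state
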