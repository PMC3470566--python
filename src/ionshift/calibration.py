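"""Resting-state balancing and parameter tuning.

A stable resting potential requires every ion's net transmembrane flux
to vanish in every compartment.  :func:`balance_rest` determines, per
compartment and in this order:

1. the Ca pump scale and Na/Ca exchanger scale that cancel the resting
   Ca influx (split between pump and exchanger),
2. the NKCC1 transport scale that cancels resting Cl extrusion by KCC2,
3. the minimum Na/K-ATPase rate that balances resting Na influx, raised
   by a configurable margin (default 20%) so that a potassium leak
   exists and the cell can respond to extracellular K transients,
4. the Na and K leak conductances that zero the remaining Na and K
   fluxes at the resting potential.

Because the balance is enforced compartment by compartment at a uniform
resting potential, axial currents vanish and the per-compartment
calibration equals the whole-model calibration.

Also provided: the +4 mM extracellular-K depolarization check, the
input-resistance probe, and a least-squares fit of the KCC2 transport
density to a chloride-clearance time course.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from . import transporters as tr
from .errors import CalibrationError, FittingError
from .ion_homeostasis import ION_INDEX, IonState, reversal_potentials
from .solver import Drive, Membrane, Simulation, SolverConfig


@dataclass
class CalibrationResult:
    nak_imax: np.ndarray          # mA/cm^2 per compartment
    nkcc1_vmax: np.ndarray
    nacax_imax: np.ndarray
    capump_imax: np.ndarray
    g_leak_na: np.ndarray         # S/cm^2
    g_leak_k: np.ndarray
    g_leak_cl: np.ndarray
    v_rest: float                 # mV
    residuals: dict               # per-ion net flux after balancing, mA/cm^2


def resting_channel_currents(model, membrane: Membrane, v_rest: float,
                             temperature_k: float) -> dict:
    """Steady-state per-ion channel currents at a uniform V_rest."""
    n = model.n
    ions = IonState.uniform(n, membrane.initial_concentrations, membrane.glial)
    rev = reversal_potentials(ions, temperature_k=temperature_k,
                              hco3_fraction=membrane.hco3_fraction)
    v = np.full(n, v_rest)
    out = {ion: np.zeros(n) for ion in ("na", "k", "cl", "ca")}

    o5 = membrane.na5.initial_distribution(v_rest)
    o6 = membrane.na6.initial_distribution(v_rest)
    from .channels import na_conductance
    g_na = na_conductance(membrane.gna_bar, membrane.slow_fraction,
                          membrane.na5.open_fraction(o5),
                          membrane.na6.open_fraction(o6))
    out["na"] += g_na * (v - rev["e_na"])

    for name, (channel, gbar) in membrane.hh_channels.items():
        g = gbar * channel.open_fraction(channel.steady_gates(v))
        if channel.ion == "mixed":
            out["na"] += channel.na_fraction * g * (v - rev["e_na"])
            out["k"] += (1.0 - channel.na_fraction) * g * (v - rev["e_k"])
        else:
            out[channel.ion] += g * (v - rev[f"e_{channel.ion}"])
    out["ca"] += membrane.g_leak_ca * (v - rev["e_ca"])
    return out


def balance_rest(model, membrane: Membrane, v_rest: float = -66.0,
                 margin: float = 0.20, ca_pump_share: float = 0.5,
                 temperature_k: float = 273.15 + 32.0,
                 pump_imax=None) -> CalibrationResult:
    """Determine pump rates, transporter scales and leak conductances so
    that every ion's net flux is zero at ``v_rest`` in every compartment.

    Mutates ``membrane`` in place and returns the determined parameters.
    ``pump_imax`` overrides the computed minimum-plus-margin Na/K-ATPase
    density (used by the algebraic toy tests).

    Raises :class:`CalibrationError` when the balance would require a
    negative conductance or transport rate.
    """
    n = model.n
    conc = membrane.initial_concentrations
    ions = IonState.uniform(n, conc, membrane.glial)
    rev = reversal_potentials(ions, temperature_k=temperature_k,
                              hco3_fraction=membrane.hco3_fraction)
    v = np.full(n, v_rest)
    chan = resting_channel_currents(model, membrane, v_rest, temperature_k)

    na_i, na_o = ions.get("na", "i"), ions.get("na", "o")
    k_i, k_o = ions.get("k", "i"), ions.get("k", "o")
    cl_i, cl_o = ions.get("cl", "i"), ions.get("cl", "o")
    ca_i, ca_o = ions.get("ca", "i"), ions.get("ca", "o")

    # --- calcium: split extrusion of the resting influx between the
    # pump and the exchanger
    i_ca_chan = chan["ca"]
    if np.any(i_ca_chan >= 0):
        bad = int(np.where(i_ca_chan >= 0)[0][0])
        raise CalibrationError(
            f"compartment {bad}: no resting Ca influx to balance")
    pump_sat = ca_i / (ca_i + membrane.pumps.capump_km)
    capump_imax = ca_pump_share * (-i_ca_chan) / pump_sat
    i_x_unit = tr.nacax_master_current(v, na_i, na_o, ca_i, ca_o,
                                       membrane.pumps, imax=1.0)
    if np.any(i_x_unit >= 0):
        bad = int(np.where(i_x_unit >= 0)[0][0])
        raise CalibrationError(
            f"compartment {bad}: Na/Ca exchanger not in forward mode at rest")
    nacax_imax = (1.0 - ca_pump_share) * (-i_ca_chan) / (-2.0 * i_x_unit)

    # --- chloride: NKCC1 loading balances KCC2 extrusion
    i_kcc2_k, i_kcc2_cl = tr.kcc2_currents(k_i, k_o, cl_i, cl_o,
                                           membrane.kcc2,
                                           vmax=membrane.kcc2_vmax)
    y_ss = tr.nkcc1_steady_y(na_i, na_o, k_i, k_o, cl_i, cl_o, membrane.nkcc1)
    _, _, i_nk_cl_unit, _ = tr.nkcc1_current(
        na_i, na_o, k_i, k_o, cl_i, cl_o, y_ss, 0.0, membrane.nkcc1, vmax=1.0)
    i_cl_other = chan["cl"] + i_kcc2_cl + membrane.g_leak_cl * (v - rev["e_cl"])
    with np.errstate(divide="ignore", invalid="ignore"):
        nkcc1_vmax = np.where(i_nk_cl_unit != 0.0,
                              -i_cl_other / i_nk_cl_unit, 0.0)
    if np.any(nkcc1_vmax < 0):
        bad = int(np.where(nkcc1_vmax < 0)[0][0])
        raise CalibrationError(
            f"compartment {bad}: chloride balance requires negative NKCC1 rate")
    i_nk_na = -0.5 * nkcc1_vmax * i_nk_cl_unit
    i_nk_k = i_nk_na

    # --- pump: the minimum rate is the larger of the two one-sided
    # constraints -- 3*I_p must at least cancel the resting Na influx
    # (else the Na leak would be negative) and 2*I_p must at least
    # cancel the resting K efflux (else the K leak would be negative).
    # The margin raises the pump above this minimum, creating the
    # potassium-leak headroom that lets the cell depolarize to
    # extracellular K transients.
    i_na_other = chan["na"] + 3.0 * nacax_imax * i_x_unit + i_nk_na
    i_k_prepump = chan["k"] + i_kcc2_k + i_nk_k
    i_pump_req = np.maximum(-i_na_other / 3.0, i_k_prepump / 2.0)
    if np.any(i_pump_req < 0):
        bad = int(np.where(i_pump_req < 0)[0][0])
        raise CalibrationError(
            f"compartment {bad}: resting fluxes admit no nonnegative pump rate")
    sat = 1.0 / ((1.0 + membrane.pumps.nak_km_k_o / k_o) ** 2
                 * (1.0 + membrane.pumps.nak_km_na_i / na_i) ** 3)
    if pump_imax is None:
        nak_imax = (1.0 + margin) * i_pump_req / sat
    else:
        nak_imax = np.full(n, pump_imax, dtype=float)
    i_pump = nak_imax * sat
    resid_na = i_na_other + 3.0 * i_pump
    if np.any(resid_na < -1e-18):      # leak would have to expel sodium
        bad = int(np.where(resid_na < -1e-18)[0][0])
        raise CalibrationError(
            f"compartment {bad}: sodium balance requires negative leak conductance")
    g_leak_na = resid_na / (rev["e_na"] - v_rest)

    # --- potassium: leak absorbs the pump influx surplus
    i_k_other = i_k_prepump - 2.0 * i_pump
    g_leak_k = -i_k_other / (v_rest - rev["e_k"])
    if np.any(g_leak_k < 0):
        bad = int(np.where(g_leak_k < 0)[0][0])
        raise CalibrationError(
            f"compartment {bad}: potassium balance requires negative leak "
            "conductance (margin too small)")

    # install
    membrane.capump_imax = capump_imax
    membrane.nacax_imax = nacax_imax
    membrane.nkcc1_vmax = nkcc1_vmax
    membrane.nak_imax = nak_imax
    membrane.g_leak_na = g_leak_na
    membrane.g_leak_k = g_leak_k
    membrane.calibrated = True

    # verify residuals
    residuals = {
        "na": i_na_other + 3.0 * i_pump + g_leak_na * (v_rest - rev["e_na"]),
        "k": i_k_other + g_leak_k * (v_rest - rev["e_k"]),
        "cl": i_cl_other + nkcc1_vmax * i_nk_cl_unit,
        "ca": i_ca_chan + capump_imax * pump_sat
        - 2.0 * nacax_imax * i_x_unit,
    }
    return CalibrationResult(
        nak_imax=nak_imax, nkcc1_vmax=nkcc1_vmax, nacax_imax=nacax_imax,
        capump_imax=capump_imax, g_leak_na=g_leak_na, g_leak_k=g_leak_k,
        g_leak_cl=membrane.g_leak_cl.copy(), v_rest=v_rest,
        residuals=residuals,
    )


# ---------------------------------------------------------------------------
# post-calibration checks and fits

def check_k_sensitivity(model, membrane: Membrane, delta_mM: float = 4.0,
                        settle_ms: float = 1500.0, dt: float = 0.05,
                        v_rest: float = -66.0) -> float:
    """Steady-state somatic depolarization for a clamped [K]o step (mV)."""
    if delta_mM == 0.0:
        return 0.0
    cfg = SolverConfig(dt=dt, record_stride=int(round(1.0 / dt)))
    sim = Simulation(model, membrane, cfg)
    n = model.n
    k_base = membrane.initial_concentrations["k_o"]
    drive = Drive(k_o_waveform=lambda t: np.full(n, k_base + delta_mM),
                  na_blocked=True)
    traces, _ = sim.run(settle_ms, drive, v0=v_rest, record=("v",))
    soma = model.root
    return float(traces["v"][soma, -1] - v_rest)


def input_resistance(model, membrane: Membrane, amp_nA: float = -0.05,
                     duration_ms: float = 600.0, dt: float = 0.05,
                     v_rest: float = -66.0) -> float:
    """Somatic input resistance from a small hyperpolarizing step (MOhm)."""
    cfg = SolverConfig(dt=dt, record_stride=int(round(1.0 / dt)))
    sim = Simulation(model, membrane, cfg)
    soma = model.root
    n = model.n

    def inj(t):
        out = np.zeros(n)
        if 50.0 <= t < 50.0 + duration_ms:
            out[soma] = amp_nA * 1e-6       # nA -> mA
        return out

    traces, _ = sim.run(duration_ms + 100.0, Drive(injected_current=inj,
                                                   na_blocked=True),
                        v0=v_rest, record=("v",))
    t = traces.time
    v = traces["v"][soma]
    base = v[t < 50.0][-1]
    plateau = v[(t > 50.0 + 0.8 * duration_ms) & (t < 50.0 + duration_ms)].mean()
    return float((plateau - base) / amp_nA)


def simulate_clearance(model, membrane: Membrane, kcc2_vmax: float,
                       compartment: int, cl_load_mM: float = 20.0,
                       duration_ms: float = 800.0, dt: float = 0.05,
                       v_rest: float = -66.0):
    """Chloride decay in one compartment after a uniform dendritic Cl load.

    Returns ``(time_ms, cl_i_trace)``.  Fast Na is blocked; clearance is
    carried by KCC2 (at the given transport density), NKCC1 and
    longitudinal diffusion.
    """
    mb = membrane.scale()    # deep copy
    mb.kcc2_vmax = np.full(model.n, kcc2_vmax)
    cfg = SolverConfig(dt=dt, record_stride=int(round(2.0 / dt)))
    sim = Simulation(model, mb, cfg)
    state = sim.init_state(v_rest)
    dend = model.region != "soma"
    state.ions.intra[ION_INDEX["cl"], dend] = cl_load_mM
    traces, _ = sim.run(duration_ms, Drive(na_blocked=True), state=state,
                        record=("cl_i",))
    return traces.time, traces["cl_i"][compartment]


def fit_kcc2_density(target_time, target_cl, model, membrane: Membrane,
                     compartment: int, cl_load_mM: float = 20.0,
                     bounds=(1e-4, 0.2), dt: float = 0.05,
                     max_residual_fraction: float = 0.25) -> float:
    """Least-squares fit of the KCC2 transport density to a clearance curve.

    Simulates the chloride decay at candidate densities and minimizes
    the sum of squared differences to the target curve.  Raises
    :class:`FittingError` if the best fit leaves a residual larger than
    ``max_residual_fraction`` of the target's dynamic range (e.g. when
    clearance in the data cannot be produced by the other mechanisms).
    """
    target_time = np.asarray(target_time)
    target_cl = np.asarray(target_cl)
    duration = float(target_time[-1])

    def sse(log_vmax):
        t, cl = simulate_clearance(model, membrane, float(np.exp(log_vmax)),
                                   compartment, cl_load_mM, duration, dt)
        sim_cl = np.interp(target_time, t, cl)
        return float(np.sum((sim_cl - target_cl) ** 2))

    res = minimize_scalar(sse, bounds=(np.log(bounds[0]), np.log(bounds[1])),
                          method="bounded", options={"xatol": 1e-3})
    if not res.success:
        raise FittingError(f"KCC2 density fit did not converge: {res.message}")
    vmax = float(np.exp(res.x))
    rms = np.sqrt(res.fun / target_cl.size)
    dynamic_range = float(target_cl.max() - target_cl.min())
    if dynamic_range > 0 and rms > max_residual_fraction * dynamic_range:
        raise FittingError(
            f"KCC2 density fit rejected: rms residual {rms:.3g} mM exceeds "
            f"{max_residual_fraction:.0%} of the clearance amplitude")
    return vmax
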