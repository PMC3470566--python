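"""Ion transporters, pumps and leak currents.

Sign convention: every returned quantity is a current density in
mA/cm^2, outward-positive (positive charge leaving the cell).

KCC2
    Electroneutral K-Cl cotransport, modeled as a 2-state carrier with
    rapid symmetric substrate binding.  Net flux is proportional to
    ``[K]o[Cl]o - [K]i[Cl]i`` over a saturating denominator, so the flux
    vanishes exactly at the thermodynamic equilibrium of the
    electroneutral cotransporter and follows the KCl chemical-potential
    gradient elsewhere.  The potassium current is I_KCC2, the chloride
    current is -I_KCC2 (no net charge moves).

NKCC1
    Electroneutral Na-K-2Cl cotransport as a two-faced carrier: a state
    variable y tracks the fraction of carriers facing the extracellular
    side; loaded and empty carriers translocate with separate rate
    constants and binding is at rapid equilibrium on each face.  With
    symmetric rates, steady-state flux vanishes exactly when
    ``[Na]o[K]o[Cl]o^2 = [Na]i[K]i[Cl]i^2``.  Per-ion currents are
    (-0.5, -0.5, +1.0) * I_NKCC1 for Na, K, Cl: zero net charge.

Na/K-ATPase
    Saturating in [Na]i and [K]o; I_Na = 3*I_pump, I_K = -2*I_pump
    (one net positive charge extruded per cycle).

Ca pump / Na-Ca exchanger
    Michaelis extrusion pump plus an electrogenic 3Na:1Ca exchanger
    (I_Na = 3*I_NaCaX, I_Ca = -2*I_NaCaX).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import rt_over_f
from .errors import HomeostasisError


def _check_positive(name, *concs):
    for c in concs:
        if np.any(np.asarray(c) <= 0.0):
            raise HomeostasisError(f"{name}: non-positive concentration encountered")


# ---------------------------------------------------------------------------
# KCC2

@dataclass
class Kcc2Params:
    vmax: float = 0.012    # mA/cm^2, maximum transport density
    km_k: float = 5.2      # mM
    km_cl: float = 7.0     # mM

    @classmethod
    def from_config(cls, cfg: dict) -> "Kcc2Params":
        return cls(vmax=float(cfg.get("vmax_mA_cm2") or 0.012),
                   km_k=float(cfg["km_k_mM"]), km_cl=float(cfg["km_cl_mM"]))


def kcc2_unit_flux(k_i, k_o, cl_i, cl_o, params: Kcc2Params):
    """Dimensionless saturable flux, positive for KCl efflux."""
    num = np.asarray(k_i) * np.asarray(cl_i) - np.asarray(k_o) * np.asarray(cl_o)
    den = ((np.asarray(k_i) + params.km_k) * (np.asarray(cl_i) + params.km_cl)
           + (np.asarray(k_o) + params.km_k) * (np.asarray(cl_o) + params.km_cl))
    return num / den


def kcc2_currents(k_i, k_o, cl_i, cl_o, params: Kcc2Params, vmax=None,
                  check: bool = True):
    """(I_K, I_Cl) carried by KCC2; I_Cl = -I_K (electroneutral)."""
    if check:
        _check_positive("kcc2", k_i, k_o, cl_i, cl_o)
    v = params.vmax if vmax is None else vmax
    i_k = v * kcc2_unit_flux(k_i, k_o, cl_i, cl_o, params)
    return i_k, -i_k


# ---------------------------------------------------------------------------
# NKCC1

@dataclass
class Nkcc1Params:
    vmax: float = 0.0      # mA/cm^2, set by the resting-balance algorithm
    km_na: float = 22.0
    km_k: float = 3.5
    km_cl: float = 55.0
    k_full: float = 1.0    # 1/ms
    k_empty: float = 0.5   # 1/ms

    @classmethod
    def from_config(cls, cfg: dict) -> "Nkcc1Params":
        return cls(
            vmax=float(cfg.get("vmax_mA_cm2") or 0.0),
            km_na=float(cfg["km_na_mM"]), km_k=float(cfg["km_k_mM"]),
            km_cl=float(cfg["km_cl_mM"]),
            k_full=float(cfg["k_full"]), k_empty=float(cfg["k_empty"]),
        )


def _nkcc1_bound_probability(na, k, cl, p: Nkcc1Params):
    odds = (np.asarray(na) / p.km_na) * (np.asarray(k) / p.km_k) \
        * (np.asarray(cl) / p.km_cl) ** 2
    return odds / (1.0 + odds)


def nkcc1_steady_y(na_i, na_o, k_i, k_o, cl_i, cl_o, p: Nkcc1Params):
    """Steady-state outward-facing carrier fraction for given concentrations."""
    p_of = _nkcc1_bound_probability(na_o, k_o, cl_o, p)
    p_if = _nkcc1_bound_probability(na_i, k_i, cl_i, p)
    r_to_out = p.k_empty * (1.0 - p_if) + p.k_full * p_if
    r_to_in = p.k_empty * (1.0 - p_of) + p.k_full * p_of
    return r_to_out / (r_to_out + r_to_in)


def nkcc1_current(na_i, na_o, k_i, k_o, cl_i, cl_o, y, dt,
                  params: Nkcc1Params, vmax=None, check: bool = True):
    """NKCC1 master current and updated carrier state.

    Returns ``(i_na, i_k, i_cl, y_new)`` where ``i_cl = I_NKCC1`` and
    ``i_na = i_k = -0.5 * I_NKCC1``; the summed charge flux is exactly
    zero.  Positive I_NKCC1 corresponds to inward Na-K-2Cl cargo flux
    (chloride loading).
    """
    if check:
        _check_positive("nkcc1", na_i, na_o, k_i, k_o, cl_i, cl_o)
    v = params.vmax if vmax is None else vmax
    p_of = _nkcc1_bound_probability(na_o, k_o, cl_o, params)
    p_if = _nkcc1_bound_probability(na_i, k_i, cl_i, params)
    # inward translocation of loaded carriers minus outward
    unit = params.k_full * (np.asarray(y) * p_of - (1.0 - np.asarray(y)) * p_if)
    i_cl = v * unit
    # carrier redistribution
    r_to_in = params.k_empty * (1.0 - p_of) + params.k_full * p_of
    r_to_out = params.k_empty * (1.0 - p_if) + params.k_full * p_if
    y_new = np.clip(
        np.asarray(y) + dt * ((1.0 - np.asarray(y)) * r_to_out
                              - np.asarray(y) * r_to_in),
        0.0, 1.0,
    )
    return -0.5 * i_cl, -0.5 * i_cl, i_cl, y_new


# ---------------------------------------------------------------------------
# pumps and exchanger

@dataclass
class PumpParams:
    nak_imax: float = 0.0      # mA/cm^2 (calibrated)
    nak_km_k_o: float = 3.5    # mM
    nak_km_na_i: float = 10.0  # mM
    capump_imax: float = 2e-5  # mA/cm^2
    capump_km: float = 5e-4    # mM
    nacax_imax: float = 0.0    # mA/cm^2 (calibrated)
    nacax_km_na: float = 87.5
    nacax_km_ca: float = 1.38
    nacax_gamma: float = 0.35
    nacax_ksat: float = 0.1

    @classmethod
    def from_config(cls, cfg: dict) -> "PumpParams":
        return cls(
            nak_imax=float(cfg["nak_pump"].get("imax_mA_cm2") or 0.0),
            nak_km_k_o=float(cfg["nak_pump"]["km_k_o_mM"]),
            nak_km_na_i=float(cfg["nak_pump"]["km_na_i_mM"]),
            capump_imax=float(cfg["ca_pump"]["imax_mA_cm2"]),
            capump_km=float(cfg["ca_pump"]["km_ca_mM"]),
            nacax_imax=float(cfg["nacax"].get("imax_mA_cm2") or 0.0),
            nacax_km_na=float(cfg["nacax"]["km_na_mM"]),
            nacax_km_ca=float(cfg["nacax"]["km_ca_mM"]),
            nacax_gamma=float(cfg["nacax"]["gamma"]),
            nacax_ksat=float(cfg["nacax"]["k_sat"]),
        )


def nak_pump_rate(na_i, k_o, params: PumpParams, imax=None):
    """Saturating pump cycle rate I_pump (mA/cm^2)."""
    im = params.nak_imax if imax is None else imax
    return im / ((1.0 + params.nak_km_k_o / np.asarray(k_o)) ** 2
                 * (1.0 + params.nak_km_na_i / np.asarray(na_i)) ** 3)


def nak_pump(na_i, k_o, params: PumpParams, imax=None, check: bool = True):
    """(I_Na, I_K): 3 Na out, 2 K in per cycle."""
    if check:
        _check_positive("nak_pump", na_i, k_o)
    i_p = nak_pump_rate(na_i, k_o, params, imax)
    return 3.0 * i_p, -2.0 * i_p


def ca_pump(ca_i, params: PumpParams, imax=None, check: bool = True):
    """Plasma-membrane Ca pump current (outward positive)."""
    if check:
        _check_positive("ca_pump", ca_i)
    im = params.capump_imax if imax is None else imax
    return im * np.asarray(ca_i) / (np.asarray(ca_i) + params.capump_km)


def nacax_master_current(v, na_i, na_o, ca_i, ca_o, params: PumpParams,
                         imax=None, check: bool = True):
    """Master exchanger current I_NaCaX (mA/cm^2).

    Negative in forward mode (Ca extrusion, Na entry).  Per-ion currents
    are I_Na = 3*I_NaCaX and I_Ca = -2*I_NaCaX.
    """
    if check:
        _check_positive("nacax", na_i, na_o, ca_i, ca_o)
    im = params.nacax_imax if imax is None else imax
    vf = np.asarray(v) / rt_over_f()
    g = params.nacax_gamma
    num = (np.exp(g * vf) * np.asarray(na_i) ** 3 * np.asarray(ca_o)
           - np.exp((g - 1.0) * vf) * np.asarray(na_o) ** 3 * np.asarray(ca_i))
    den = ((params.nacax_km_na ** 3 + np.asarray(na_o) ** 3)
           * (params.nacax_km_ca + np.asarray(ca_o))
           * (1.0 + params.nacax_ksat * np.exp((g - 1.0) * vf)))
    return im * num / den


def nacax_and_capump(v, na_i, na_o, ca_i, ca_o, params: PumpParams,
                     nacax_imax=None, capump_imax=None):
    """Per-ion currents of the exchanger plus the Ca pump.

    Returns ``(i_na, i_ca)`` with the exchanger contributing currents in
    the stoichiometric 3:-2 ratio and the pump extruding Ca.
    """
    i_x = nacax_master_current(v, na_i, na_o, ca_i, ca_o, params, nacax_imax)
    i_cap = ca_pump(ca_i, params, capump_imax)
    return 3.0 * i_x, -2.0 * i_x + i_cap


def leak_current(v, e_rev, g_leak):
    """Ohmic leak current (mA/cm^2)."""
    return np.asarray(g_leak) * (np.asarray(v) - np.asarray(e_rev))
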