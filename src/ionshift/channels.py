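"""Voltage-gated membrane currents.

Two families of channel model coexist:

* Hodgkin-Huxley style channels (delayed rectifier, A-type, M-current,
  Ih, a high-threshold Ca channel, and any further plug-in defined in a
  parameter file).  Gates are advanced with the explicit Euler method
  and clipped to [0, 1].
* Markov-scheme channels: the fast sodium current, present as a 5-state
  scheme without slow inactivation and a 6-state scheme with a slow
  inactivated state.  Occupancies are advanced with the implicit Euler
  method, which remains on the probability simplex for any step size.

The fraction of sodium conductance governed by the slow-inactivating
scheme grows linearly with path distance from the soma and saturates at
250 um; the soma carries only the 5-state scheme.  Total conductance is

    g = g_bar * [(1 - fraction) * O_5state + fraction * O_6state].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import IntegrationError, StateCorruptionError, ValidationError


# ---------------------------------------------------------------------------
# Hodgkin-Huxley style gating

def _sigmoid(v, v_half, slope):
    # slope > 0: activation; slope < 0: inactivation
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - v_half) / slope))


@dataclass
class GatingVariableSpec:
    """One gating variable: steady state, time constant, exponent."""

    name: str
    exponent: int
    inf_v_half: float
    inf_slope: float
    tau_kind: str = "const"          # "const" or "bell"
    tau_params: dict = field(default_factory=lambda: {"value": 1.0})

    def steady_state(self, v):
        return _sigmoid(v, self.inf_v_half, self.inf_slope)

    def time_constant(self, v):
        v = np.asarray(v, dtype=float)
        if self.tau_kind == "const":
            return np.full_like(v, self.tau_params["value"])
        if self.tau_kind == "bell":
            p = self.tau_params
            return p.get("floor", 0.1) + p["amp"] / (
                np.exp((v - p["v_half"]) / p["sigma_up"])
                + np.exp(-(v - p["v_half"]) / p["sigma_down"])
            )
        raise ValidationError(f"unknown tau kind {self.tau_kind!r}")

    @classmethod
    def from_config(cls, cfg: dict) -> "GatingVariableSpec":
        tau = cfg["tau"]
        return cls(
            name=cfg["name"],
            exponent=int(cfg.get("exponent", 1)),
            inf_v_half=float(cfg["inf"]["v_half"]),
            inf_slope=float(cfg["inf"]["slope"]),
            tau_kind=tau.get("kind", "const"),
            tau_params={k: v for k, v in tau.items() if k != "kind"},
        )


@dataclass
class HHChannel:
    """A channel made of independent gating variables."""

    name: str
    ion: str                       # "na", "k", "ca" or "mixed"
    gates: list
    na_fraction: float = 0.0       # only used for ion == "mixed"

    @classmethod
    def from_config(cls, name: str, cfg: dict) -> "HHChannel":
        return cls(
            name=name,
            ion=cfg["ion"],
            gates=[GatingVariableSpec.from_config(g) for g in cfg["gates"]],
            na_fraction=float(cfg.get("na_fraction", 0.0)),
        )

    def open_fraction(self, gate_values: dict) -> np.ndarray:
        out = 1.0
        for g in self.gates:
            out = out * gate_values[g.name] ** g.exponent
        return out

    def steady_gates(self, v) -> dict:
        return {g.name: g.steady_state(v) for g in self.gates}


def advance_gates(channel: HHChannel, gate_values: dict, v, dt: float) -> dict:
    """One explicit Euler step for every gate, clipped to [0, 1]."""
    out = {}
    for g in channel.gates:
        x = gate_values[g.name]
        tau = (g.tau_params["value"] if g.tau_kind == "const"
               else g.time_constant(v))
        x_new = x + (dt / tau) * (g.steady_state(v) - x)
        out[g.name] = np.clip(x_new, 0.0, 1.0)
    return out


def hh_current(channel: HHChannel, gate_values: dict, v, e_rev, g_bar, dt: float):
    """Current density and one explicit gate step.

    Returns ``(current_mA_cm2, new_gate_values)`` with
    I = g_bar * prod(gate^exponent) * (V - E_rev).
    """
    current = g_bar * channel.open_fraction(gate_values) * (np.asarray(v) - e_rev)
    return current, advance_gates(channel, gate_values, v, dt)


# ---------------------------------------------------------------------------
# Markov schemes

@dataclass
class MarkovScheme:
    """State names, conducting subset, and a rate-matrix builder.

    ``rate_matrix(v, ligand)`` returns generator matrices of shape
    ``(..., n, n)`` in the row convention: ``Q[i, j]`` is the transition
    rate from state i to state j (per ms) for i != j, and rows sum to
    zero.  Occupancy row vectors evolve as dp/dt = p @ Q.
    """

    name: str
    states: tuple
    conducting_states: tuple
    rate_matrix: Callable

    @property
    def n_states(self) -> int:
        return len(self.states)

    def initial_distribution(self, v=None, ligand=0.0) -> np.ndarray:
        """Stationary distribution of Q(v, ligand) (or unbound/closed start)."""
        if v is None:
            p = np.zeros(self.n_states)
            p[0] = 1.0
            return p
        q = np.atleast_2d(np.asarray(self.rate_matrix(np.atleast_1d(v), ligand)))
        q = q.reshape(-1, self.n_states, self.n_states)
        out = np.empty((q.shape[0], self.n_states))
        for i, qi in enumerate(q):
            # stationary p solves p Q = 0, sum p = 1
            a = np.vstack([qi.T, np.ones(self.n_states)])
            b = np.zeros(self.n_states + 1)
            b[-1] = 1.0
            p, *_ = np.linalg.lstsq(a, b, rcond=None)
            out[i] = np.clip(p, 0.0, None)
            out[i] /= out[i].sum()
        return out[0] if np.ndim(v) == 0 else out

    def open_fraction(self, occupancy: np.ndarray) -> np.ndarray:
        idx = [self.states.index(s) for s in self.conducting_states]
        return np.asarray(occupancy)[..., idx].sum(axis=-1)


def markov_step_implicit(scheme: MarkovScheme, occupancy, v, ligand, dt: float,
                         check: bool = True):
    """One implicit Euler step of d p/dt = p Q, batched over compartments.

    Solves (I - dt Q^T) p' = p for each compartment, clips tiny negative
    round-off and renormalizes to the simplex.  Raises
    :class:`IntegrationError` if the linear system is singular.
    """
    p = np.atleast_2d(np.asarray(occupancy, dtype=float))
    if check and (p.min() < -1e-9 or p.max() > 1.0 + 1e-9):
        raise StateCorruptionError(
            f"{scheme.name}: occupancy outside [0,1]: "
            f"min={p.min():.3g} max={p.max():.3g}"
        )
    n = scheme.n_states
    q = scheme.rate_matrix(np.atleast_1d(v), ligand)
    q = np.broadcast_to(q, (p.shape[0], n, n))
    a = np.eye(n)[None, :, :] - dt * np.swapaxes(q, -1, -2)
    try:
        p_new = np.linalg.solve(a, p[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise IntegrationError(
            f"singular implicit Markov solve for {scheme.name}: "
            f"v={np.atleast_1d(v)[:5]}, dt={dt}"
        ) from exc
    p_new = np.clip(p_new, 0.0, None)
    p_new /= p_new.sum(axis=-1, keepdims=True)
    if np.ndim(occupancy) == 1:
        return p_new[0]
    return p_new


# ---------------------------------------------------------------------------
# fast sodium Markov schemes

def _vtrap(x, k):
    """x / (1 - exp(-x/k)) with the x -> 0 singularity removed."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / k) < 1e-6
    safe = np.where(small, 1.0, x)
    out = safe / (1.0 - np.exp(-safe / k))
    return np.where(small, k + x / 2.0, out)


def _na_activation_rates(v, p):
    dv = np.asarray(v, dtype=float) - p["m_v_half"]
    alpha = p["am_rate"] * _vtrap(dv, p["m_k"])
    beta = p["bm_rate"] * _vtrap(-dv, p["m_k"])
    return alpha, beta


def _na_inactivation_rates(v, p):
    v = np.asarray(v, dtype=float)
    k_oi = p["k_oi_max"] * _sigmoid(v, p["k_oi_v_half"], p["k_oi_k"])
    k_rec = p["k_rec_rate"] * np.exp(-(v - p["k_rec_v_half"]) / p["k_rec_k"])
    return k_oi, k_rec


def _build_na_q(v, p, slow: bool):
    v = np.atleast_1d(np.asarray(v, dtype=float))
    n = 6 if slow else 5
    q = np.zeros(v.shape + (n, n))
    alpha, beta = _na_activation_rates(v, p)
    k_oi, k_rec = _na_inactivation_rates(v, p)
    # states: C0 C1 C2 O I (S)
    q[..., 0, 1] = 3.0 * alpha
    q[..., 1, 0] = beta
    q[..., 1, 2] = 2.0 * alpha
    q[..., 2, 1] = 2.0 * beta
    q[..., 2, 3] = alpha
    q[..., 3, 2] = 3.0 * beta
    q[..., 3, 4] = k_oi
    q[..., 4, 0] = k_rec
    if slow:
        q[..., 4, 5] = p["k_is"]
        q[..., 5, 4] = p["k_si"]
    idx = np.arange(n)
    q[..., idx, idx] = -q.sum(axis=-1)
    return q


def na_dual_step(na5_occ, na6_occ, v, dt, rates: dict):
    """Advance both Na schemes one implicit step, sharing the rate
    evaluation (hot path used by the solver)."""
    v = np.atleast_1d(np.asarray(v, dtype=float))
    n_comp = v.size
    alpha, beta = _na_activation_rates(v, rates)
    k_oi, k_rec = _na_inactivation_rates(v, rates)
    out = []
    for occ, n, slow in ((na5_occ, 5, False), (na6_occ, 6, True)):
        q = np.zeros((n_comp, n, n))
        q[:, 0, 1] = 3.0 * alpha
        q[:, 1, 0] = beta
        q[:, 1, 2] = 2.0 * alpha
        q[:, 2, 1] = 2.0 * beta
        q[:, 2, 3] = alpha
        q[:, 3, 2] = 3.0 * beta
        q[:, 3, 4] = k_oi
        q[:, 4, 0] = k_rec
        if slow:
            q[:, 4, 5] = rates["k_is"]
            q[:, 5, 4] = rates["k_si"]
        idx = np.arange(n)
        q[:, idx, idx] = -q.sum(axis=-1)
        a = np.eye(n)[None, :, :] - dt * np.swapaxes(q, -1, -2)
        p_new = np.linalg.solve(a, occ[..., None])[..., 0]
        np.clip(p_new, 0.0, None, out=p_new)
        p_new /= p_new.sum(axis=-1, keepdims=True)
        out.append(p_new)
    return out[0], out[1]


def na_scheme_5state(rates: dict) -> MarkovScheme:
    """Fast Na scheme without slow inactivation (somatic form)."""
    p = dict(rates)
    return MarkovScheme(
        name="na_5state",
        states=("C0", "C1", "C2", "O", "I"),
        conducting_states=("O",),
        rate_matrix=lambda v, ligand=0.0: _build_na_q(v, p, slow=False),
    )


def na_scheme_6state(rates: dict) -> MarkovScheme:
    """Fast Na scheme with a slow inactivated state (dendritic form)."""
    p = dict(rates)
    return MarkovScheme(
        name="na_6state",
        states=("C0", "C1", "C2", "O", "I", "S"),
        conducting_states=("O",),
        rate_matrix=lambda v, ligand=0.0: _build_na_q(v, p, slow=True),
    )


def slow_na_fraction(distance, saturation: float = 250.0):
    """Fraction of Na conductance carried by the slow-inactivating scheme.

    Linear in path distance from the soma, saturating at 1 beyond
    ``saturation`` um; the soma (distance 0) carries none.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValidationError("distance must be >= 0")
    return np.clip(d / saturation, 0.0, 1.0)


def na_conductance(g_bar, fraction, o5, o6):
    """Mix the open fractions of the two schemes into one conductance."""
    o5 = np.asarray(o5, dtype=float)
    o6 = np.asarray(o6, dtype=float)
    if np.any((o5 < 0) | (o5 > 1)) or np.any((o6 < 0) | (o6 > 1)):
        raise StateCorruptionError("open-state occupancy outside [0, 1]")
    return g_bar * ((1.0 - fraction) * o5 + fraction * o6)


# ---------------------------------------------------------------------------
# density placement

def channel_density(name: str, cfg: dict, model) -> np.ndarray:
    """Per-compartment density (S/cm^2) from a channel's density table."""
    dens = cfg["densities"]
    out = np.zeros(model.n)
    is_axon = model.region == "axon"
    is_soma = model.region == "soma"
    is_dend = ~(is_axon | is_soma)
    out[is_axon] = dens.get("axon", 0.0)
    out[is_soma] = dens.get("soma", 0.0)
    if "dendrite" in dens:
        out[is_dend] = dens["dendrite"]
    else:   # radius-split rule (fast Na): evaluated per compartment
        thick = model.radius > cfg.get("thick_radius_um", 0.6)
        out[is_dend & thick] = dens.get("dendrite_thick", 0.0)
        out[is_dend & ~thick] = dens.get("dendrite_thin", 0.0)
    return out
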