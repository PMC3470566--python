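"""Ion concentration dynamics: flux conversion, glial buffering,
longitudinal diffusion and reversal potentials.

Each compartment carries an intracellular pool and an extracellular
shell (15% of the intracellular volume by default).  Transmembrane
current I_ion (mA/cm^2, outward-positive) changes concentrations as

    d[ion]_i/dt = -I_ion * A / (z F V_i),
    d[ion]_o/dt = +I_ion * A / (z F V_shell),

so the moles leaving one pool enter the other exactly.  Because the
shell volume is a small fraction of the intracellular volume, shell
concentration excursions are amplified by V_i/V_shell (about 6.7x at
the default 15% fraction).

Extracellular potassium is additionally buffered by a first-order
reversible glial scheme, and all ions diffuse longitudinally along the
tree in both the intracellular and the shell pools.

Bicarbonate concentrations are held constant; the bicarbonate branch of
the GABA_A current carries charge but does not alter any stored
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (DEFAULT_TEMPERATURE_K, FARADAY, ION_NAMES,
                        ION_VALENCE, rt_over_f)
from .errors import HomeostasisError
from .gaba import gaba_reversal

ION_INDEX = {name: i for i, name in enumerate(ION_NAMES)}


@dataclass
class DiffusionConstants:
    """Longitudinal diffusion coefficients, um^2/ms."""

    na: float = 1.33
    k: float = 1.96
    cl: float = 2.08
    ca: float = 0.60

    def as_array(self) -> np.ndarray:
        return np.array([self.na, self.k, self.cl, self.ca])


@dataclass
class GlialBufferParams:
    total: float = 60.0    # mM, shell-referred total buffer
    k_on: float = 2e-5     # 1/(mM*ms)
    k_off: float = 2e-4    # 1/ms

    @classmethod
    def from_config(cls, cfg: dict) -> "GlialBufferParams":
        return cls(total=float(cfg["total_mM"]), k_on=float(cfg["k_on"]),
                   k_off=float(cfg["k_off"]))

    def equilibrium_bound(self, k_o) -> np.ndarray:
        """Bound-buffer concentration in equilibrium with a given [K]o."""
        ko = np.asarray(k_o, dtype=float)
        return self.total * self.k_on * ko / (self.k_on * ko + self.k_off)


@dataclass
class IonState:
    """Per-compartment intra/extracellular concentrations (mM).

    ``intra`` and ``shell`` have shape (4, N) ordered Na, K, Cl, Ca.
    Bicarbonate is constant.  ``buffer_bound`` is the glial-bound K pool
    expressed as a shell concentration.
    """

    intra: np.ndarray
    shell: np.ndarray
    hco3_i: float
    hco3_o: float
    buffer_bound: np.ndarray = field(default=None)

    def __post_init__(self):
        self.intra = np.asarray(self.intra, dtype=float)
        self.shell = np.asarray(self.shell, dtype=float)
        if self.buffer_bound is None:
            self.buffer_bound = np.zeros(self.intra.shape[1])

    @classmethod
    def uniform(cls, n: int, concentrations: dict,
                buffer_params: GlialBufferParams | None = None) -> "IonState":
        intra = np.empty((4, n))
        shell = np.empty((4, n))
        for name, idx in ION_INDEX.items():
            intra[idx] = concentrations[f"{name}_i"]
            shell[idx] = concentrations[f"{name}_o"]
        state = cls(intra=intra, shell=shell,
                    hco3_i=float(concentrations["hco3_i"]),
                    hco3_o=float(concentrations["hco3_o"]))
        if buffer_params is not None:
            state.buffer_bound = np.full(
                n, buffer_params.equilibrium_bound(concentrations["k_o"]))
        return state

    def copy(self) -> "IonState":
        return IonState(self.intra.copy(), self.shell.copy(),
                        self.hco3_i, self.hco3_o, self.buffer_bound.copy())

    def get(self, ion: str, side: str) -> np.ndarray:
        pool = self.intra if side == "i" else self.shell
        return pool[ION_INDEX[ion]]

    def total_moles(self, model) -> np.ndarray:
        """Moles per ion summed over the tree (mM*um^3), including the
        glial-bound potassium pool."""
        vol_i = model.volume
        vol_s = model.shell_volume
        tot = self.intra @ vol_i + self.shell @ vol_s
        tot[ION_INDEX["k"]] += float(self.buffer_bound @ vol_s)
        return tot


def concentration_step(state: IonState, currents: np.ndarray, model, dt: float,
                       check: bool = True) -> IonState:
    """Convert per-ion membrane currents into concentration changes.

    ``currents`` has shape (4, N): mA/cm^2 per ion, outward-positive.
    Mutates and returns ``state``.  Raises :class:`HomeostasisError`
    naming the compartment and ion if a concentration is driven to zero
    or below.
    """
    area = model.area
    coeff_i = 1.0e4 * area / model.volume          # per-ion valence applied below
    coeff_s = 1.0e4 * area / model.shell_volume
    z = ION_VALENCE[:, None]
    state.intra -= dt * currents * coeff_i[None, :] / (z * FARADAY)
    state.shell += dt * currents * coeff_s[None, :] / (z * FARADAY)
    if check:
        for pool, label in ((state.intra, "intracellular"),
                            (state.shell, "extracellular")):
            if np.any(pool <= 0.0):
                ion_idx, comp = np.argwhere(pool <= 0.0)[0]
                raise HomeostasisError(
                    f"{label} [{ION_NAMES[ion_idx]}] <= 0 in compartment {comp}"
                )
    return state


def glial_buffer_step(state: IonState, params: GlialBufferParams,
                      dt: float) -> IonState:
    """First-order reversible glial uptake of extracellular K+.

    Moles are conserved exactly between the free and bound pools; the
    free [K]o relaxes toward the level set by the buffer equilibrium.
    """
    k_o = state.shell[ION_INDEX["k"]]
    free_buffer = params.total - state.buffer_bound
    rate = params.k_on * k_o * free_buffer - params.k_off * state.buffer_bound
    state.buffer_bound += dt * rate
    state.shell[ION_INDEX["k"]] = k_o - dt * rate
    return state


def make_diffusion_workspace(model) -> dict:
    """Precomputed index/geometry arrays for :func:`diffusion_step`."""
    parent = model.parent_index
    child = np.where(parent >= 0)[0]
    par = parent[child]
    dist = (model.length[child] + model.length[par]) / 2.0
    surf_i = model.cross_section[child]
    return {
        "child": child, "par": par,
        "k_intra": surf_i / dist,
        "k_shell": model.shell_fraction[child] * surf_i / dist,
        "vol_i_child": model.volume[child], "vol_i_par": model.volume[par],
        "vol_s_child": model.shell_volume[child],
        "vol_s_par": model.shell_volume[par],
    }


def diffusion_step(state: IonState, model, constants: DiffusionConstants,
                   dt: float, workspace: dict | None = None) -> IonState:
    """Longitudinal diffusion between connected compartments.

    Flux between a compartment and its parent is proportional to the
    diffusion constant, the connecting cross-section and the
    concentration gradient over the center-to-center distance; applied
    to the intracellular pool and (scaled by the shell fraction) to the
    extracellular shell.  Total moles of every ion are conserved.
    """
    ws = workspace if workspace is not None else make_diffusion_workspace(model)
    child, par = ws["child"], ws["par"]
    if child.size == 0:
        return state
    d = constants.as_array()[:, None]

    for pool, kgeom, vol_c, vol_p in (
        (state.intra, ws["k_intra"], ws["vol_i_child"], ws["vol_i_par"]),
        (state.shell, ws["k_shell"], ws["vol_s_child"], ws["vol_s_par"]),
    ):
        grad = pool[:, par] - pool[:, child]
        delta = (dt * d) * kgeom[None, :] * grad       # mM*um^3 moved
        np.add.at(pool, (slice(None), child), delta / vol_c[None, :])
        np.add.at(pool, (slice(None), par), -delta / vol_p[None, :])
    return state


def nernst(c_out, c_in, valence, temperature_k: float = DEFAULT_TEMPERATURE_K):
    """Nernst potential in mV."""
    c_out = np.asarray(c_out, dtype=float)
    c_in = np.asarray(c_in, dtype=float)
    if np.any(c_out <= 0) or np.any(c_in <= 0):
        raise HomeostasisError("non-positive concentration in Nernst computation")
    return rt_over_f(temperature_k) / valence * np.log(c_out / c_in)


def reversal_potentials(state: IonState, compartment=None,
                        temperature_k: float = DEFAULT_TEMPERATURE_K,
                        hco3_fraction: float = 0.2) -> dict:
    """Nernst potentials for every ion plus the weighted E_GABA (mV)."""
    sel = slice(None) if compartment is None else compartment
    out = {}
    for name, idx in ION_INDEX.items():
        out[f"e_{name}"] = nernst(state.shell[idx, sel], state.intra[idx, sel],
                                  ION_VALENCE[idx], temperature_k)
    out["e_hco3"] = nernst(state.hco3_o, state.hco3_i, -1.0, temperature_k)
    out["e_gaba"] = gaba_reversal(out["e_cl"], out["e_hco3"], hco3_fraction)
    return out
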