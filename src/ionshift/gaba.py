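"""GABA_A receptor kinetics, transmitter waveforms and synapse placement.

The receptor is a 6-state Markov scheme with two sequential transmitter
binding steps, one open state and two desensitized states:

    C  <=> C1 <=> C2 <=> O
           |      |
           D1     D2

Binding rates are proportional to the free GABA concentration; all rate
constants live in the parameter file (literature-derived defaults for
the alpha1-beta2-gamma3 receptor).

The open-channel current is carried by chloride and bicarbonate with a
1:4 bicarbonate:chloride permeability ratio, implemented as two ohmic
branches carrying fixed fractions (0.8 Cl, 0.2 HCO3) of the open
conductance.  The implied reversal potential is the weighted average

    E_GABA = 0.8 * E_Cl + 0.2 * E_HCO3.

High-frequency stimulation (HFS) is a train of brief square transmitter
pulses: 1 mM for 1 ms, decaying with tau = 0.1 ms, 40 pulses at 100 Hz
unless configured otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import MarkovScheme
from .errors import ConfigurationError

#: Fraction of GABA_A conductance carried by bicarbonate (1:4 HCO3:Cl).
HCO3_FRACTION = 0.2


@dataclass
class TransmitterPulseTrain:
    """Square transmitter pulses with exponential tails."""

    pulse_onsets: np.ndarray        # ms
    peak: float = 1.0               # mM
    square_duration: float = 1.0    # ms
    decay_tau: float = 0.1          # ms

    def __post_init__(self):
        self.pulse_onsets = np.atleast_1d(np.asarray(self.pulse_onsets, dtype=float))
        if self.peak <= 0 or self.decay_tau <= 0:
            raise ConfigurationError("peak and decay_tau must be positive")

    @classmethod
    def hfs(cls, onset: float = 0.0, n_pulses: int = 40, rate_hz: float = 100.0,
            **kw) -> "TransmitterPulseTrain":
        period = 1000.0 / rate_hz
        return cls(pulse_onsets=onset + period * np.arange(n_pulses), **kw)

    def concentration(self, t: float) -> float:
        """Free GABA concentration at time t (mM)."""
        dt = t - self.pulse_onsets
        active = dt >= 0.0
        if not np.any(active):
            return 0.0
        dt = dt[active]
        conc = np.where(
            dt <= self.square_duration,
            self.peak,
            self.peak * np.exp(-(dt - self.square_duration) / self.decay_tau),
        )
        # pulses are far apart relative to the decay; take the freshest one
        return float(conc.max())

    @property
    def end_time(self) -> float:
        return float(self.pulse_onsets.max() + self.square_duration)


def transmitter_concentration(train: TransmitterPulseTrain, t: float) -> float:
    """Free GABA concentration of a pulse train at time t (mM)."""
    return train.concentration(t)


# ---------------------------------------------------------------------------
# receptor scheme

GABA_STATES = ("C", "C1", "C2", "O", "D1", "D2")


def _build_gaba_q(v, ligand, p):
    """Generator matrix; voltage-independent, ligand-dependent binding."""
    g = np.atleast_1d(np.asarray(ligand, dtype=float))
    n = 6
    q = np.zeros(g.shape + (n, n))
    q[..., 0, 1] = 2.0 * p["k_on"] * g     # two free binding sites
    q[..., 1, 0] = p["k_off"]
    q[..., 1, 2] = p["k_on"] * g
    q[..., 2, 1] = 2.0 * p["k_off"]
    q[..., 2, 3] = p["beta"]
    q[..., 3, 2] = p["alpha"]
    q[..., 1, 4] = p["d1"]
    q[..., 4, 1] = p["r1"]
    q[..., 2, 5] = p["d2"]
    q[..., 5, 2] = p["r2"]
    idx = np.arange(n)
    q[..., idx, idx] = -q.sum(axis=-1)
    return q


def gaba_scheme(rates: dict) -> MarkovScheme:
    """6-state GABA_A receptor scheme with the given rate constants."""
    p = dict(rates)
    return MarkovScheme(
        name="gaba_a",
        states=GABA_STATES,
        conducting_states=("O",),
        rate_matrix=lambda v, ligand=0.0: _build_gaba_q(v, ligand, p),
    )


# ---------------------------------------------------------------------------
# placement

@dataclass
class SynapseDistribution:
    """Synapses per um of compartment length, by region."""

    density_per_um: dict = field(default_factory=dict)

    def density(self, region: str) -> float:
        if region not in self.density_per_um:
            raise ConfigurationError(f"no synapse density configured for {region!r}")
        return float(self.density_per_um[region])


def place_synapses(model, distribution: SynapseDistribution,
                   quantal_g_nS: float = 1.0):
    """Place GABA_A synapses at the configured per-length densities.

    Per-compartment synapse count is density * length rounded half-up.
    Returns ``(counts, g_max_S_cm2)``: integer counts and the resulting
    maximum conductance density when every synapse is fully open.
    """
    counts = np.zeros(model.n, dtype=int)
    for i in range(model.n):
        dens = distribution.density(str(model.region[i]))
        counts[i] = int(np.floor(dens * model.length[i] + 0.5))
    area_cm2 = model.area * 1e-8
    g_max = np.where(area_cm2 > 0, counts * quantal_g_nS * 1e-9 / area_cm2, 0.0)
    return counts, g_max


def gaba_current(open_fraction, v, e_cl, e_hco3, g_total,
                 hco3_fraction: float = HCO3_FRACTION):
    """Chloride and bicarbonate components of the receptor current.

    ``g_total`` is the fully-open conductance density (S/cm^2); the open
    conductance splits into fixed Cl and HCO3 fractions.  Returns
    ``(I_Cl, I_HCO3)`` in mA/cm^2, outward-positive.  The total current
    reverses at E_GABA = (1-f)*E_Cl + f*E_HCO3.
    """
    g_open = g_total * np.asarray(open_fraction)
    i_cl = (1.0 - hco3_fraction) * g_open * (np.asarray(v) - e_cl)
    i_hco3 = hco3_fraction * g_open * (np.asarray(v) - e_hco3)
    return i_cl, i_hco3


def gaba_reversal(e_cl, e_hco3, hco3_fraction: float = HCO3_FRACTION):
    """Permeability-weighted GABA_A reversal potential (mV)."""
    return (1.0 - hco3_fraction) * np.asarray(e_cl) + hco3_fraction * np.asarray(e_hco3)
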