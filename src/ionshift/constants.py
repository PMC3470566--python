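"""Physical constants and the internal unit system.

The whole package works in one consistent unit system:

========================  ==========
quantity                  unit
========================  ==========
voltage                   mV
time                      ms
length                    um
membrane area             um^2
volume                    um^3
concentration             mM
current density           mA/cm^2
conductance density       S/cm^2
specific capacitance      uF/cm^2
axial resistivity         Ohm*cm
diffusion coefficient     um^2/ms
========================  ==========

With these choices ``g [S/cm^2] * (V - E) [mV]`` is directly a current
density in mA/cm^2, and the mole-flux conversion carries a single factor
of 1e4 (see :func:`flux_coefficient`).
"""

import numpy as np

#: Faraday constant, C/mol.
FARADAY = 96485.332

#: Gas constant, J/(mol*K).
GAS_CONSTANT = 8.314462

#: Default bath temperature for Nernst potentials (slice convention), Kelvin.
DEFAULT_TEMPERATURE_K = 273.15 + 32.0


def rt_over_f(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """RT/F in mV."""
    return 1000.0 * GAS_CONSTANT * temperature_k / FARADAY


def flux_coefficient(area_um2, volume_um3, valence):
    """Conversion factor from current density to concentration rate.

    For an outward-positive current density I (mA/cm^2) crossing a
    membrane of ``area_um2`` into a pool of ``volume_um3``, the
    concentration of an ion of charge ``valence`` changes at

        d[C]/dt = -I * flux_coefficient  (mM/ms)

    Derivation: I [mA/cm^2] * A [um^2] = 1e-11 * I*A ampere;
    dividing by z*F gives mol/ms*1e-3...; collecting powers of ten for
    mM/ms over a volume in um^3 leaves a net factor of 1e4/(z*F).
    """
    return 1.0e4 * np.asarray(area_um2) / (valence * FARADAY * np.asarray(volume_um3))


#: Order in which the four dynamic ions are stored in state arrays.
ION_NAMES = ("na", "k", "cl", "ca")

#: Signed valence of each dynamic ion, aligned with ION_NAMES.
ION_VALENCE = np.array([1.0, 1.0, -1.0, 2.0])

#: Valence of bicarbonate (concentration held fixed, current still flows).
HCO3_VALENCE = -1.0
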