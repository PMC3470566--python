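# ionshift

A biophysically detailed compartmental simulator of a CA1 hippocampal
pyramidal neuron with full ionic homeostasis, built to study how GABA —
normally the brain's inhibitory transmitter — can paradoxically *excite*
a neuron after intense synaptic bombardment. It is a library plus a
small CLI for computational neuroscientists who need voltage **and**
ion-concentration dynamics in the same model: intra- and extracellular
Na⁺, K⁺, Cl⁻ and Ca²⁺ evolve in every compartment, coupled through
voltage-gated channels, GABA_A receptors, the cotransporters KCC2 and
NKCC1, the Na/K-ATPase, the Ca pump and Na/Ca exchanger, glial potassium
buffering, and longitudinal diffusion.

## The mechanism in brief

The GABA_A receptor conducts both chloride and bicarbonate, with a 1:4
HCO₃⁻:Cl⁻ permeability ratio, so its reversal potential is

```
E_GABA = 0.8 · E_Cl + 0.2 · E_HCO3
```

At rest (E_Cl ≈ −89 mV, E_HCO3 ≈ −14.5 mV) this sits below the −66 mV
resting potential and GABA inhibits. During high-frequency stimulation
(HFS: 40 transmitter pulses at 100 Hz onto the soma and apical
dendrites), chloride pours into thin dendrites faster than KCC2 can
extrude it; E_Cl and hence E_GABA climb, the bicarbonate current comes
to dominate, and the dendrites become a source of depolarizing current —
the cell hyperpolarizes briefly and then depolarizes for seconds.
Because KCC2 exports K⁺ with every Cl⁻, the extracellular potassium
transient is itself mostly KCC2-generated, and elevated [K⁺]o feeds back
to slow chloride extrusion. The simulator reproduces this chain and the
interventions that dissect it (partial receptor block, KCC2 block,
potassium clamps, shell-volume changes, late GABA pulses at different
locations).

Everything runs on synthetic morphologies generated in code
(single compartment, ball-and-stick, reduced branched tree); real
reconstructions load from standard SWC files.

## Worked example

```python
import numpy as np
from ionshift import morphology, params, solver, calibration, protocols

model = morphology.make_fixture("ball_and_stick")     # 9 compartments
membrane = solver.build_membrane(model, params.default_params())

# determine pump rates, transporter scales and leaks so every ion's
# flux is zero at -66 mV in every compartment
result = calibration.balance_rest(model, membrane)
print(f"somatic Na/K pump i_max: {result.nak_imax[model.root]:.4f} mA/cm^2")
print(f"input resistance: {calibration.input_resistance(model, membrane):.0f} MOhm")

# 40 GABA pulses at 100 Hz, 80% synapse activation, Na channels blocked
traces = protocols.run_hfs(model, membrane, activation=0.8,
                           duration=1600.0, na_blocked=True)
s = protocols.hfs_response_summary(traces, model)
print(f"peak hyperpolarization: {s['peak_hyperpolarization_mV']:.1f} mV")
print(f"peak depolarization:    {s['peak_depolarization_mV']:.1f} mV")
print(f"peak dendritic [Cl]i rise: {s['peak_dcl_i_mM']:.1f} mM")
```

prints, with the shipped defaults:

```
somatic Na/K pump i_max: 0.0494 mA/cm^2
input resistance: 146 MOhm
peak hyperpolarization: 7.4 mV
peak depolarization:    11.3 mV
peak dendritic [Cl]i rise: 9.0 mM
```

i.e. the classic biphasic response: the soma dips ~7 mV below rest
during the early train, then depolarizes ~11 mV above rest as dendritic
chloride (here +9 mM at the peak) drags E_GABA above the membrane
potential. Recorded series (`v`, `cl_i`, `k_o`, `e_gaba`, per-mechanism
currents, clamp current, ...) are in `traces`, a `TraceSet` that saves
to CSV or HDF5.

The CLI wraps the same calls:

```
ionshift morph fixture --kind ball_and_stick --out cell.swc
ionshift morph inspect cell.swc
ionshift calibrate --morphology cell.swc
ionshift run --activation 0.8 --mode clamp --clamp-mv -75 --out traces.csv
```

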