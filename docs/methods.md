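# Methods

`ionshift` simulates a CA1 pyramidal neuron as a branched tree of
cylindrical compartments in which the membrane potential and the intra-
and extracellular concentrations of Na+, K+, Cl- and Ca2+ evolve
together. The package exists to study a specific phenomenon: the
paradoxical excitation produced by high-frequency activation of GABA_A
synapses, which depends on chloride accumulation inside thin dendrites,
bicarbonate current through the GABA_A receptor, and potassium export
by the K-Cl cotransporter KCC2. This note records the model, its
assumptions, the numerical choices, and what the synthetic fixtures can
and cannot show.

## Electrical model

Each compartment obeys the cable equation

    c_m dV/dt = -SUM_ion I_ion(V, state, concentrations) + I_axial + I_inj

with specific capacitance `c_m = 1 uF/cm^2` and axial resistivity
`150 Ohm*cm` (both configurable). Axial coupling between a compartment
and its parent uses the series resistance of the two half-cylinders.
The voltage system is advanced with the implicit Euler method
(`dt = 0.02 ms` by default): all conductance-based currents enter the
linear solve with their conductances frozen at post-gate-update values,
and the symmetric tree system is solved exactly by Hines elimination
(a direct O(N) solve; the test suite checks it against a dense solve to
1e-12). Transporter and pump currents are treated as constants within a
step. This makes the passive solve unconditionally stable; halving the
time step changes the peak of the stimulation response by well under
0.5%.

Somatic voltage clamp is implemented by exact row substitution in the
linear system; dendritic compartments evolve freely, so space-clamp
failure is reproduced rather than assumed away. The reported clamp
current is the membrane plus axial current required to hold the
command.

Operator splitting order, chosen once and kept: (1) explicit Euler for
all Hodgkin-Huxley gates (clipped to [0,1]); (2) implicit Euler for the
Markov schemes; (3) implicit voltage solve; (4) explicit concentration,
glial-buffer, diffusion and carrier-state updates.

## Channels

The fast sodium current is the sum of two Markov schemes sharing one
total density: a 5-state scheme (3 closed states, open, fast
inactivated) and a 6-state scheme that adds a slowly entered, slowly
vacated inactivated state. The 6-state share of the local density is
`min(distance/250 um, 1)` and zero in the soma, so repetitive firing
progressively removes dendritic but not somatic availability - the
mechanism behind distance-dependent attenuation of back-propagating
action potentials. Total densities: 0.1 S/cm^2 in the axon,
0.014 S/cm^2 in the soma and dendrites thicker than 0.6 um radius,
0.0014 S/cm^2 in thinner dendrites. The Markov occupancies are advanced
implicitly, which keeps them on the probability simplex at any step
size (tested at 50x the production step).

The delayed rectifier, A-type K, M-current, Ih (a mixed Na/K current,
40% Na so that it reverses near -30 mV) and a high-threshold Ca channel
are generic gating-variable channels defined entirely in the parameter
file (`ionshift/data/default_params.yaml`); any further channel of this
form can be added there without code changes. The rate constants are
literature-style defaults for CA1 cells, not fits performed here.

## GABA_A receptor and transmitter

The receptor is a 6-state scheme - unbound, singly bound, doubly bound,
open, and two desensitized states entered from the singly and doubly
bound states; binding rates are proportional to the free transmitter
concentration. High-frequency stimulation (HFS) delivers 40 transmitter
pulses at 100 Hz, each a 1 mM square of 1 ms followed by a 0.1 ms
exponential tail, to all synapses in the targeted regions. Synapses are
placed at fixed per-length densities by layer (1.7 per um at the soma
and proximal apical dendrites, 0.5 in medial radiatum, 0.15 in distal or
thin radiatum, 0.12 in lacunosum-moleculare, 0.61/0.1 in proximal/distal
oriens), each with a 1 nS quantal conductance; counts are density times
length rounded half-up. "X% activation" scales every synapse's
conductance by X/100 - a deterministic stand-in for activating a random
X% of synapses, chosen for reproducibility.

The open-channel current is split into ohmic chloride (80%) and
bicarbonate (20%) branches, the 1:4 HCO3:Cl permeability ratio, so the
receptor reverses at `E_GABA = 0.8 E_Cl + 0.2 E_HCO3`. Bicarbonate
concentrations are fixed (15 mM in, 26 mM out), so E_HCO3 is a constant
of about -14.5 mV at 32 C; E_Cl follows the chloride state. The
bicarbonate branch carries charge but does not change any stored
concentration.

## Transporters and pumps

All are defined so that stoichiometry is exact in floating point:

* **KCC2** - electroneutral K-Cl cotransport modeled as a symmetric
  2-state carrier with rapid-equilibrium binding (K and Cl affinities
  5.2 and 7.0 mM). The net flux is proportional to
  `[K]i[Cl]i - [K]o[Cl]o` over a saturating denominator, so it vanishes
  exactly at the thermodynamic equilibrium of the cotransporter and
  reverses across it. Potassium current `I_KCC2`, chloride current
  `-I_KCC2`. This is the coupling at the heart of the study: chloride
  extrusion deposits potassium in the extracellular shell, and elevated
  shell potassium throttles further extrusion.
* **NKCC1** - electroneutral Na-K-2Cl cotransport as a two-faced
  carrier. A state variable y tracks the fraction of carriers facing
  the extracellular side; loaded and empty carriers translocate with
  separate symmetric rate constants, binding is at rapid equilibrium on
  each face. Steady-state flux vanishes exactly at
  `[Na]o[K]o[Cl]o^2 = [Na]i[K]i[Cl]i^2`. Per-ion currents are
  (-0.5, -0.5, +1.0) x I_NKCC1 for Na, K, Cl.
* **Na/K-ATPase** - `I_Na = 3 I_p`, `I_K = -2 I_p`, with I_p saturating
  in [Na]i (Km 10 mM, cubed) and [K]o (Km 3.5 mM, squared).
* **Ca pump and Na/Ca exchanger** - Michaelis extrusion pump plus an
  electrogenic exchanger (`I_Na = 3 I_X`, `I_Ca = -2 I_X`) with a
  voltage-dependent driving term; a small fixed Ca leak gives them a
  resting operating point.

## Ion concentrations

Outward-positive current I over membrane area A changes concentrations
as `d[C]i/dt = -I A/(z F V_i)` and `d[C]o/dt = +I A/(z F V_shell)`, so
moles are conserved across the membrane exactly. The extracellular
shell of each compartment is 15% of its intracellular volume (22%
beyond a configurable distance in the enlarged-shell variant), which
amplifies extracellular excursions by about 6.7x. Initial
concentrations (mM): Na 10/145, K 140/3.5, Cl 4.5/135, Ca 1e-4/2.
Intracellular chloride of 4.5 mM puts the resting E_Cl near -89 mV and
resting E_GABA near -74 mV, below the -66 mV resting potential, so GABA
is initially hyperpolarizing.

Extracellular potassium is additionally buffered by a first-order
reversible glial scheme (60 mM total buffer, on-rate 4e-5 /(mM ms),
off-rate 4e-4 /ms). These defaults make a +4 mM free-K excursion relax
with a time constant around half a second and let the buffer absorb
roughly three quarters of a step at equilibrium. The buffer rate was
chosen once so that the potassium transient is shorter-lived than the
chloride elevation; the location-dependent response to late GABA pulses
depends on that ordering, and the paper-scale behavior (E_GABA elevated
for seconds) shows the same ordering.

All four ions diffuse longitudinally along the tree, in the
intracellular pool and, scaled by the shell fraction, in the shell,
with D(Na, K, Cl, Ca) = 1.33, 1.96, 2.08, 0.60 um^2/ms. Flux between
neighbors is D times the connecting cross-section times the gradient
over the midpoint distance; tree totals are conserved to float
round-off.

Nernst potentials use a bath temperature of 32 C (slice convention,
configurable).

## Resting-state calibration

A stable rest requires each ion's net flux to vanish per compartment.
`calibration.balance_rest` solves this in closed form, per compartment,
at V_rest = -66 mV:

1. Ca: the pump and exchanger scales split the resting Ca influx.
2. Cl: the NKCC1 scale cancels resting KCC2 extrusion.
3. Na/K pump: the minimum rate is the larger of two one-sided
   constraints - 3 I_p must cover the resting Na influx (else the Na
   leak would be negative) and 2 I_p must cover the resting K efflux
   (else the K leak would be negative). The pump is set 20% above this
   minimum; the margin is precisely what creates the potassium leak
   that lets the cell depolarize to extracellular K transients. With a
   zero margin the model still rests at -66 mV but barely responds to a
   K_o step.
4. Na and K leak conductances zero the remaining fluxes.

Because the balance holds at a uniform V_rest, axial currents vanish
and per-compartment calibration equals whole-model calibration (tested).
The calibrated fixture rests at -66.000 mV with drift far below
0.01 mV/s; rest is a fixed point of the discrete scheme to round-off.

The KCC2 transport density is the one deliberately tunable homeostasis
parameter. Its default (0.012 mA/cm^2) gives dendritic chloride
clearance on the multi-second timescale of published CA1 measurements
and makes KCC2 the dominant source of the HFS-evoked potassium
transient. `calibration.fit_kcc2_density` recovers the density from a
chloride-clearance time course by bounded least squares; the test suite
demonstrates round-trip recovery within 5%.

## Stimulation protocols

`protocols` encodes the computational experiments: HFS under current or
somatic voltage clamp; a second identical HFS at the falling phase or
after recovery; partial GABA_A block (the quinine surrogate, 60%);
partial or complete KCC2 block; frozen or waveform-clamped
extracellular potassium; a KCC2 variant that senses only the resting
[K]o while the membrane sees the true transient; an enlarged dendritic
shell; single late GABA pulses confined to the distal dendrites or the
soma; membrane-resistance probing with brief hyperpolarizing pulses
(each deflection measured against a paired probe-free run, so the
ongoing transmitter response cancels); a
glutamate-pulse spike-probability assay against a seeded noisy somatic
current (Wilson 95% intervals); and a sensitivity sweep that rescales
initial chloride, KCC2 density, buffer capacity, bicarbonate
permeability fraction or GABA_A conductance, re-balances the rest, and
re-runs HFS with sodium channels blocked.

Timing definitions where the protocol needs one: "falling phase" is the
time of 25% decay from the peak depolarization; "recovered" is V within
a configurable tolerance of rest; a spike is an upward 0 mV crossing
with a 2 ms refractory period.

## Synthetic fixtures: what they show and what they do not

Tests run on two fixtures generated in code: a ball-and-stick (soma plus
a 400 um, 0.5 um-radius apical stick) and a reduced CA1-like branched
tree (thick trunk, thin proximal oblique, distal tuft, basal stick)
populating every synapse-density class with mixed radii. On these the
full mechanism chain emerges from the calibrated model with no further
tuning: HFS produces a fast hyperpolarization followed by a slow
depolarization of about 11 mV that outlasts the train; chloride loading
scales with surface-to-volume (smaller radius, larger rise); dendritic
E_GABA rises up to ~20 mV above somatic; 60% receptor block preserves
the hyperpolarization while more than halving the depolarization and
slowing the switch; KCC2 block prolongs the dendritic E_GABA elevation,
shrinks the potassium transient and does not reduce the peak
depolarization; a late GABA pulse excites from the distal dendrites and
inhibits from the soma, and is plainly inhibitory without a preceding
HFS.

Two behaviors require the full reconstructed morphology and are *not*
asserted in absolute form on fixtures. First, the immediate *somatic
hyperpolarization* by a second HFS during the falling phase: in a small
fixture the soma is axially slaved to thin, strongly depolarized-E_GABA
dendrites, whereas in the full cell the perisomatic conductance
dominates; the tests assert the underlying rule instead (the immediate
response sign tracks the local E_GABA - V, and the somatic response is
much weaker than the dendritic one). Second, absolute electrical
constants (input resistance, firing rate at a given current, pump
density) scale with total membrane area and are reported, not asserted,
for fixtures. The synthetic fixtures also idealize geometry (uniform
cylinders, no spines, no 3D extracellular space) and the noisy drive
(piecewise-constant Gaussian), so passing tests demonstrate mechanism
and numerics, not quantitative agreement with any particular recorded
cell.

## Problem sizes

Default desk-scale runs use 9-16 compartments, dt = 0.02 ms (0.04-0.05
for fitting and subthreshold probes, where the implicit scheme remains
accurate), 1.6 s of simulated time per HFS experiment, and a handful of
noisy trials per spike-probability condition; all sizes are arguments
and can be raised for full-morphology work with an SWC reconstruction
via `morphology.load_swc`.
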