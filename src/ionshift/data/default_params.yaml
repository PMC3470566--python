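# Default model parameters.
#
# Kinetic constants for the plug-in channel set, the two fast-Na Markov
# schemes, the GABA_A receptor scheme and the transporters are
# literature-derived defaults for CA1 pyramidal neurons; everything here
# can be overridden by passing a modified mapping to the loaders.
# Units follow the package convention (mV, ms, mM, S/cm^2, mA/cm^2).

membrane:
  capacitance_uF_cm2: 1.0
  axial_resistivity_ohm_cm: 150.0

temperature_c: 32.0

initial_concentrations:   # mM
  na_i: 10.0
  na_o: 145.0
  k_i: 140.0
  k_o: 3.5
  cl_i: 4.5
  cl_o: 135.0
  ca_i: 1.0e-4
  ca_o: 2.0
  hco3_i: 15.0
  hco3_o: 26.0

channels:
  na:
    kind: markov_na
    densities:            # S/cm^2
      axon: 0.1
      soma: 0.014
      dendrite_thick: 0.014   # radius > thick_radius_um
      dendrite_thin: 0.0014
    thick_radius_um: 0.6
    slow_fraction_saturation_um: 250.0
    rates:
      am_rate: 0.4        # 1/(ms*mV), activation forward slope factor
      m_v_half: -30.0     # mV
      m_k: 7.2            # mV
      bm_rate: 0.124
      k_oi_max: 0.8       # 1/ms, open -> fast-inactivated
      k_oi_v_half: -40.0
      k_oi_k: 5.0
      k_rec_rate: 0.2     # 1/ms at v_half, recovery I -> C0
      k_rec_v_half: -66.0
      k_rec_k: 20.0       # e-fold per mV of hyperpolarization
      k_is: 0.0025        # 1/ms, fast- -> slow-inactivated (6-state only)
      k_si: 0.001         # 1/ms, slow recovery
  kdr:
    kind: hh
    ion: k
    densities: {axon: 0.04, soma: 0.02, dendrite: 0.01}
    gates:
      - name: n
        exponent: 2
        inf: {v_half: -5.0, slope: 11.0}
        tau: {kind: const, value: 2.5}
  ka:
    kind: hh
    ion: k
    densities: {axon: 0.0, soma: 0.002, dendrite: 0.004}
    gates:
      - name: m
        exponent: 1
        inf: {v_half: -20.0, slope: 15.0}
        tau: {kind: const, value: 1.0}
      - name: h
        exponent: 1
        inf: {v_half: -60.0, slope: -8.0}
        tau: {kind: const, value: 20.0}
  km:
    kind: hh
    ion: k
    densities: {axon: 0.0, soma: 0.0003, dendrite: 0.0003}
    gates:
      - name: m
        exponent: 1
        inf: {v_half: -35.0, slope: 5.0}
        tau: {kind: const, value: 50.0}
  ih:
    kind: hh
    ion: mixed
    na_fraction: 0.4      # split of the mixed cation current carried by Na
    densities: {axon: 0.0, soma: 0.0002, dendrite: 0.0004}
    gates:
      - name: h
        exponent: 1
        inf: {v_half: -82.0, slope: -7.0}
        tau: {kind: const, value: 40.0}
  ca:
    kind: hh
    ion: ca
    densities: {axon: 0.0, soma: 0.0001, dendrite: 0.0001}
    gates:
      - name: m
        exponent: 2
        inf: {v_half: -20.0, slope: 6.0}
        tau: {kind: const, value: 2.0}

gaba_a:
  quantal_conductance_nS: 1.0
  hco3_fraction: 0.2            # 1:4 bicarbonate:chloride permeability
  densities_per_um:             # synapses per um of compartment length
    soma: 1.7
    apical_proximal: 1.7
    radiatum_thick_medial: 0.5
    radiatum_thick_distal_or_thin: 0.15
    lacunosum_moleculare: 0.12
    oriens_proximal: 0.61
    oriens_distal: 0.1
    axon: 0.0
  rates:                        # 6-state scheme, per ms / per (mM*ms)
    k_on: 5.0                   # binding, per site
    k_off: 0.13
    beta: 1.2                   # doubly bound -> open
    alpha: 0.25                 # open -> doubly bound
    d1: 0.0015                  # singly bound -> slow desensitized
    r1: 0.0002
    d2: 0.035                   # doubly bound -> fast desensitized
    r2: 0.0015

transporters:
  kcc2:
    vmax_mA_cm2: 0.012          # maximum transport density (tunable/fit)
    km_k_mM: 5.2                # K+ affinity
    km_cl_mM: 7.0               # Cl- affinity
  nkcc1:
    vmax_mA_cm2: null           # determined by the resting-balance algorithm
    km_na_mM: 22.0
    km_k_mM: 3.5
    km_cl_mM: 55.0
    k_full: 1.0                 # 1/ms, loaded translocation
    k_empty: 0.5                # 1/ms, unloaded translocation
  nak_pump:
    imax_mA_cm2: null           # determined by the resting-balance algorithm
    km_k_o_mM: 3.5
    km_na_i_mM: 10.0
  ca_pump:
    imax_mA_cm2: 2.0e-5
    km_ca_mM: 5.0e-4
  nacax:
    imax_mA_cm2: null           # determined by the resting-balance algorithm
    km_na_mM: 87.5
    km_ca_mM: 1.38
    gamma: 0.35
    k_sat: 0.1

leaks:
  g_ca_S_cm2: 1.0e-6    # small fixed Ca leak; Na/K leaks are calibrated

glial_buffer:
  total_mM: 60.0                # total buffer, shell-referred concentration
  k_on: 4.0e-5                  # 1/(mM*ms)
  k_off: 4.0e-4                 # 1/ms

diffusion_um2_ms:               # longitudinal diffusion constants
  na: 1.33
  k: 1.96
  cl: 2.08
  ca: 0.60

solver:
  dt_ms: 0.02
  spike_threshold_mV: 0.0
  spike_refractory_ms: 2.0

calibration:
  v_rest_mV: -66.0
  pump_margin: 0.2
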