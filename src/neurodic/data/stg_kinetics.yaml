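# Crustacean STG neuron model: six voltage-gated currents plus leak and a
# first-order intracellular calcium pool.  Gating kinetics transcribed from the
# lineage of published STG conductance-based models fitted to crustacean
# stomatogastric measurements; the calcium reversal potential is fixed at
# +120 mV rather than computed from a Nernst relation.
# Units: mV, ms, mS/cm2, uA/cm2, uF/cm2, uM.
name: stg
capacitance: 1.0
v_range: [-80.0, 50.0]
i_app: 0.0
leak: {g: 0.01, e: -50.0}
calcium:
  tau: 2000.0      # ms; a slow integrator of calcium entry (see docs/methods.md)
  f: 9.3952        # uM per uA/cm2 of calcium current
  c_rest: 0.05     # uM
timescales:
  fast: [Na, m]
  slow: [Kd, m]
  ultraslow: [CaS, h]
currents:
  - name: Na
    gbar: 700.0
    reversal: 50.0
    polarity: depolarizing
    activation:
      exponent: 3
      steady_state: {form: sigmoid, vhalf: -25.5, k: 5.29}
      time_constant: {form: tau_sigmoid, a: 1.32, b: -1.26, vhalf: -120.0, k: 25.0}
    inactivation:
      exponent: 1
      steady_state: {form: sigmoid, vhalf: -48.9, k: -5.18}
      time_constant:
        form: tau_product
        factors:
          - {form: tau_sigmoid, a: 0.0, b: 0.67, vhalf: -62.9, k: 10.0}
          - {form: tau_sigmoid, a: 1.5, b: 1.0, vhalf: -34.9, k: -3.6}
  - name: CaT
    gbar: 2.0
    reversal: 120.0
    polarity: depolarizing
    calcium_carrying: true
    activation:
      exponent: 3
      steady_state: {form: sigmoid, vhalf: -27.1, k: 7.2}
      # transient calcium channel: fast activation (participates in the fast
      # timescale), slower inactivation
      time_constant:
        form: tau_biexp
        a: 1.4
        b: 7.0
        vh1: -27.0
        k1: -10.0
        vh2: -70.0
        k2: 13.0
    inactivation:
      exponent: 1
      steady_state: {form: sigmoid, vhalf: -32.1, k: -5.5}
      time_constant: {form: tau_sigmoid, a: 105.0, b: -89.8, vhalf: -55.0, k: 16.9}
  - name: CaS
    gbar: 4.0
    reversal: 120.0
    polarity: depolarizing
    calcium_carrying: true
    activation:
      exponent: 3
      steady_state: {form: sigmoid, vhalf: -33.0, k: 8.1}
      # slow calcium channel: slow activation (no fast-timescale pathway)
      time_constant: {form: tau_sigmoid, a: 21.7, b: -21.3, vhalf: -68.1, k: 20.5}
    inactivation:
      exponent: 1
      steady_state: {form: sigmoid, vhalf: -60.0, k: -6.2}
      time_constant:
        form: tau_biexp
        a: 60.0
        b: 150.0
        vh1: -55.0
        k1: -9.0
        vh2: -65.0
        k2: 16.0
  - name: A
    gbar: 50.0
    reversal: -80.0
    polarity: repolarizing
    activation:
      exponent: 3
      steady_state: {form: sigmoid, vhalf: -27.2, k: 8.7}
      time_constant: {form: tau_sigmoid, a: 11.6, b: -10.4, vhalf: -32.9, k: 15.2}
    inactivation:
      exponent: 1
      steady_state: {form: sigmoid, vhalf: -56.9, k: -4.9}
      time_constant: {form: tau_sigmoid, a: 38.6, b: -29.2, vhalf: -38.9, k: 26.5}
  - name: Kd
    gbar: 70.0
    reversal: -80.0
    polarity: repolarizing
    activation:
      exponent: 4
      steady_state: {form: sigmoid, vhalf: -12.3, k: 11.8}
      time_constant: {form: tau_sigmoid, a: 7.2, b: -6.4, vhalf: -28.3, k: 19.2}
  - name: KCa
    gbar: 40.0
    reversal: -80.0
    polarity: repolarizing
    activation:
      exponent: 4
      steady_state: {form: ca_sigmoid, vhalf: -28.3, k: 12.6, kd: 3.0}
      time_constant: {form: tau_sigmoid, a: 90.3, b: -75.1, vhalf: -46.0, k: 22.7}
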