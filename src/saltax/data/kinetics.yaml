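# Default HH channel kinetics for the L5 corticothalamic neuron model.
#
# Rate-function forms (see saltax.biophysics.eval_rate):
#   const       c0
#   exp         c0*exp((v-c1)/c2)
#   sigmoid     c3 + c0/(1+exp(-(v-c1)/c2))
#   linoid      c0*(v-c1)/(1-exp(-(v-c1)/c2))      (limit c0*c2 at v=c1)
#   linoid_dec  c0*(c1-v)/(1-exp((v-c1)/c2))       (limit c0*c2 at v=c1)
#   bell        c0 + c1/(exp((v-c2)/c3)+exp(-(v-c4)/c5))
#   ca_linear   c0*[Ca]   (KCa forward rate)
#
# Rates are 1/ms at ref_temp; gating speeds scale by q10^((T-ref)/10).
# Coefficients follow the rat L5 pyramidal modelling tradition
# (Mainen & Sejnowski-style Na/Kv/Ca/KCa; M-type and low-threshold K and
# HCN in the forms used for cortical axon models).

NaV:
  reversal: 55.0
  q10: 2.3
  ref_temp: 23.0
  gates:
    - name: m
      exponent: 3
      alpha: {type: linoid, c0: 0.273, c1: -44.0, c2: 9.0}
      beta: {type: linoid_dec, c0: 0.186, c1: -44.0, c2: 9.0}
    - name: h
      exponent: 1
      # inactivation positioned near rest with slow recovery from
      # hyperpolarized levels and fast entry at depolarized levels,
      # giving strong use-dependence of axonal excitability
      inf: {type: sigmoid, c0: 1.0, c1: -74.0, c2: -6.2}
      tau: {type: sigmoid, c0: 45.0, c1: -75.0, c2: -8.0, c3: 1.0}

NaP:
  reversal: 55.0
  q10: 2.3
  ref_temp: 23.0
  gates:
    - name: m
      exponent: 1
      inf: {type: sigmoid, c0: 1.0, c1: -52.6, c2: 4.6}
      tau: {type: const, c0: 1.0}

KV1:
  reversal: -85.0
  q10: 2.3
  ref_temp: 23.0
  gates:
    - name: n
      exponent: 1
      inf: {type: sigmoid, c0: 1.0, c1: -36.0, c2: 6.0}
      tau: {type: bell, c0: 0.5, c1: 4.0, c2: -45.0, c3: 25.0, c4: -45.0, c5: 25.0}
    - name: h
      exponent: 1
      inf: {type: sigmoid, c0: 0.9, c1: -66.0, c2: -10.0, c3: 0.1}
      tau: {type: const, c0: 150.0}

KV23:
  reversal: -85.0
  q10: 2.3
  ref_temp: 23.0
  gates:
    - name: n
      exponent: 1
      alpha: {type: linoid, c0: 0.02, c1: 25.0, c2: 9.0}
      beta: {type: linoid_dec, c0: 0.002, c1: 25.0, c2: 9.0}

KV7:
  reversal: -85.0
  q10: 2.3
  ref_temp: 23.0
  gates:
    - name: n
      exponent: 1
      inf: {type: sigmoid, c0: 1.0, c1: -45.0, c2: 8.0}
      tau: {type: bell, c0: 8.0, c1: 60.0, c2: -45.0, c3: 20.0, c4: -45.0, c5: 20.0}

CaH:
  reversal: 140.0
  q10: 2.3
  ref_temp: 23.0
  is_ca_channel: true
  gates:
    - name: m
      exponent: 2
      alpha: {type: linoid, c0: 0.055, c1: -27.0, c2: 3.8}
      beta: {type: exp, c0: 0.94, c1: -75.0, c2: -17.0}
    - name: h
      exponent: 1
      alpha: {type: exp, c0: 0.000457, c1: -13.0, c2: -50.0}
      beta: {type: sigmoid, c0: 0.0065, c1: -15.0, c2: 28.0}

CaT:
  reversal: 140.0
  q10: 2.3
  ref_temp: 23.0
  is_ca_channel: true
  gates:
    - name: m
      exponent: 2
      inf: {type: sigmoid, c0: 1.0, c1: -59.0, c2: 6.2}
      tau: {type: bell, c0: 0.6, c1: 10.0, c2: -65.0, c3: 8.0, c4: -65.0, c5: 8.0}
    - name: h
      exponent: 1
      inf: {type: sigmoid, c0: 1.0, c1: -83.0, c2: -4.0}
      tau: {type: bell, c0: 20.0, c1: 60.0, c2: -85.0, c3: 10.0, c4: -85.0, c5: 10.0}

KCa:
  reversal: -85.0
  q10: 2.3
  ref_temp: 23.0
  ca_dependent: true
  gates:
    - name: n
      exponent: 1
      alpha: {type: ca_linear, c0: 0.01}
      beta: {type: const, c0: 0.02}

HCN:
  reversal: -45.0
  q10: 2.3
  ref_temp: 33.0
  gates:
    - name: q
      exponent: 1
      inf: {type: sigmoid, c0: 1.0, c1: -90.0, c2: -6.0}
      tau: {type: bell, c0: 40.0, c1: 50.0, c2: -75.0, c3: 20.0, c4: -75.0, c5: 20.0}
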