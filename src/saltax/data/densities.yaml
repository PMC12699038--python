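# Maximal conductance densities per subcellular domain (pS/µm²).
#
# AIS: very high uniform NaV with low Ca/KCa; Kv1 and Kv7 ramp linearly
# from the soma end to distal peak densities of 12000 and 150.
# Dendrites: NaV decreases linearly 800 -> 25 from soma to the most
# distal dendrite; Kv gradients decrease with distance; HCN increases
# exponentially.  Nodes of Ranvier: high NaV/Kv7, low Kv1.
# Juxtaparanodes: Kv1-dominated (8000).  Paranodes: low Kv1/Kv7.
# Internodal axolemma (active under the sheath): modest NaV/Kv1/Kv7.
# Axonal HCN is uniform at 1.  Somatic Kv2/3 and Ca/KCa densities are
# not independently constrained; the values here are the documented
# defaults of this model's repolarizing budget.

soma:
  NaV: {profile: const, value: 800.0}
  NaP: {profile: const, value: 10.0}
  KV23: {profile: const, value: 4700.0}
  KV1: {profile: const, value: 100.0}
  KV7: {profile: const, value: 15.0}
  CaH: {profile: const, value: 3.0}
  CaT: {profile: const, value: 2.0}
  KCa: {profile: const, value: 8.0}
  HCN: {profile: const, value: 2.0}

apical_dendrite:
  NaV: {profile: linear_path, from: 800.0, to: 25.0}
  KV23: {profile: linear_path, from: 300.0, to: 10.0}
  KV1: {profile: linear_path, from: 100.0, to: 10.0}
  KV7: {profile: linear_path, from: 30.0, to: 3.0}
  CaH: {profile: const, value: 2.0}
  CaT: {profile: const, value: 2.0}
  KCa: {profile: const, value: 5.0}
  HCN: {profile: exp_path, from: 1.5, to: 12.0}

basal_dendrite:
  NaV: {profile: linear_path, from: 800.0, to: 25.0}
  KV23: {profile: linear_path, from: 300.0, to: 10.0}
  KV1: {profile: linear_path, from: 100.0, to: 10.0}
  KV7: {profile: linear_path, from: 30.0, to: 3.0}
  HCN: {profile: exp_path, from: 1.5, to: 12.0}

AIS:
  NaV: {profile: const, value: 30000.0}
  NaP: {profile: const, value: 10.0}
  CaH: {profile: const, value: 1.5}
  CaT: {profile: const, value: 1.5}
  KCa: {profile: const, value: 1.0}
  KV1: {profile: linear_section, from: 0.0, to: 12000.0}
  KV7: {profile: linear_section, from: 0.0, to: 150.0}
  KV23: {profile: const, value: 4700.0}
  HCN: {profile: const, value: 1.0}

node:
  NaV: {profile: const, value: 30000.0}
  KV7: {profile: const, value: 150.0}
  KV1: {profile: const, value: 15.0}
  HCN: {profile: const, value: 1.0}

paranode:
  NaP: {profile: const, value: 5.0}
  KV1: {profile: const, value: 15.0}
  KV7: {profile: const, value: 1.5}
  HCN: {profile: const, value: 1.0}

juxtaparanode:
  NaP: {profile: const, value: 5.0}
  KV1: {profile: const, value: 8000.0}
  KV7: {profile: const, value: 15.0}
  HCN: {profile: const, value: 1.0}

internode:
  NaP: {profile: const, value: 5.0}
  NaV: {profile: const, value: 25.0}
  KV1: {profile: const, value: 15.0}
  KV7: {profile: const, value: 15.0}
  HCN: {profile: const, value: 1.0}

collateral:
  NaV: {profile: const, value: 200.0}
  KV1: {profile: const, value: 15.0}
  KV7: {profile: const, value: 15.0}
  HCN: {profile: const, value: 1.0}

bouton:
  NaV: {profile: const, value: 5000.0}
  KV23: {profile: const, value: 1000.0}
  KV1: {profile: const, value: 100.0}
  KV7: {profile: const, value: 15.0}
  HCN: {profile: const, value: 1.0}
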