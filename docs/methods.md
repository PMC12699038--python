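# Methods

`saltax` couples a biophysical simulator of a myelinated layer-5
corticothalamic (L5→POm) projection neuron with the spike-train
analysis procedures used to characterize L5→POm transmission in vivo.
This note documents the model, its assumptions, the numerical choices,
and what the synthetic data generators do and do not emulate.

## The model cell

The cell is a reduced L5 extra-telencephalic pyramidal neuron: a
cylindrical soma (25 × 25 µm), dendritic equivalent cylinders (one
apical trunk + tuft and four basal sticks), a 45 µm axon initial
segment (AIS), and a ~4.2 mm primary axon running through cortex
(Ctx, 1.2 mm), white matter (WM, 1.6 mm) and thalamus (Thal, 1.4 mm)
to a giant presynaptic bouton. The axon tiles each region with repeat
units of `node (1 µm) – paranode (2 µm) – juxtaparanode (5 µm) –
internode – juxtaparanode – paranode`; nominal internode lengths are
70 µm in gray matter and 100 µm in WM and are stretched slightly so
each region tiles exactly. Axon diameters are 0.98 µm in gray matter
and 1.18 µm in WM. The dendritic cylinders are sized so the somatic
input resistance lands near the experimentally constrained 13.5 MΩ
(the full arbor is not reconstructable from the available data); with
the default geometry the model measures ≈13.8 MΩ.

## Double-cable myelin

Internodes, paranodes and juxtaparanodes carry a second, periaxonal
layer: the transmembrane potential is `v_i − v_e` and the transmyelin
potential `V_mym = v_e` (the outermost layer is grounded). The sheath
contributes a radial branch `R_my ∥ C_my` from the periaxonal node to
ground with

    R_my = 2 n R_mem   (R_mem = 8.56 kΩ cm² per membrane)
    C_my = C_mem / 2n  (C_mem = 1.00 µF/cm²)

for `n` lamellae (two membranes per wrap); nine lamellae give
154.08 kΩ cm² and 0.0556 µF/cm². The periaxonal space couples
longitudinally with `r_pa = 124.9 GΩ/cm`, raised 18.15-fold across the
paranodal seal. Unmyelinated membrane (soma, dendrites, AIS, nodes,
bouton, and demyelinated stretches) has its external layer collapsed
to ground (sentinel values: R_my = 1e-6 Ω cm², C_ext = 0,
r_pa/r_pn = 1e-6/1e-8 MΩ/cm).

Passive parameters are uniform: R_i = 180 Ω cm, C_m = 0.9 µF/cm²,
R_m = 2.3 kΩ cm² (deliberately low, matching the in vivo input
resistance regime), e_pas = −85 mV, 37 °C.

## Channels and densities

Ten HH-style conductances are implemented (fast NaV with m³h gating,
persistent NaP, low-threshold Kv1, delayed-rectifier Kv2/3, M-type
Kv7, high/low-threshold Ca²⁺, Ca²⁺-activated K⁺, HCN, leak). All rate
functions live in `src/saltax/data/kinetics.yaml` (singularity-protected
linoid/sigmoid/bell forms, per-channel Q10 = 2.3 relative to a stated
reference temperature) and can be swapped without touching the solver.
The density table (`data/densities.yaml`) encodes the spatial layout:
AIS NaV 30,000 pS/µm² with Kv1/Kv7 ramps to 12,000/150; dendritic NaV
decreasing linearly 800→25 with distance; nodes 30,000/150/15
(NaV/Kv7/Kv1); juxtaparanodes Kv1-dominated (8,000); paranodes 15/1.5;
internodal axolemma 25/15/15; HCN 1 pS/µm² on the axon with a
dendritic exponential gradient. Reversal potentials: K −85, Na +55,
HCN −45, Ca +140 mV.

The exact gating equations of the study system are not published, so
the kinetics set is this package's own calibration within the L5
modelling tradition. Three choices matter and are deliberate:

- **NaV activation** (linoid, v½ −44 mV, 1.5× base rates) sets the
  conduction velocity of the 9-lamella axon (≈1.6 m/s) while keeping
  the solution insensitive to halving the 10 µs step (<1%).
- **NaV inactivation** sits close to rest (v½ −74 mV) with a
  voltage-shaped time constant: slow recovery from hyperpolarized
  levels (≈10 ms effective at rest) and fast entry when depolarized.
  This use-dependence is what makes propagation along *bared*
  gray-matter axon fail selectively for late, high-frequency spikes in
  a burst while leaving myelinated saltatory conduction untouched.
- **Axonal persistent Na⁺** (4.5–5 pS/µm² on the sheathed domains; not
  experimentally constrained) amplifies the inter-spike depolarization
  that a bared proximal axon feeds back to the AIS. It reproduces the
  direction of the demyelination effect on burst frequency (bared
  axon bursts slightly faster) and couples it to propagation failure;
  above ≈6 pS/µm² the bare axon enters depolarization block, below ≈4
  the amplification vanishes.

Somatic/AIS Kv2/3 (4,700 pS/µm²) is the repolarizing budget that tunes
the evoked burst to 3–4 APs near 200 Hz under the standard protocol;
somatic KCa/CaH/CaT and the Ca²⁺ shell (80 ms decay, 0.1 µm depth) are
documented defaults with little leverage on the reported quantities.

## Numerics

Each section is split into an odd number of segments by the d_lambda
rule (0.1 of the AC length constant at 2 kHz); paranodes always get at
least 3 segments because the paranodal seal carries the steepest
periaxonal gradients — without this floor the solution changes by ~2%
under grid refinement, with it <0.1%. Time integration solves the
coupled two-layer system implicitly per step by block-Hines
elimination with 2×2 blocks over the segment tree; conductive terms
are θ-weighted (default θ = 0.5, Crank–Nicolson with staggered
analytic gating updates; θ = 1 backward Euler is used for settling
runs where strong damping is preferable). Backward Euler alone changes
the measured CV by ~3% when the 10 µs step is halved, Crank–Nicolson
by <1%. Voltage-dependent rates are tabulated on a 0.05 mV grid and
linearly interpolated. Gating states advance by the exact exponential
update; the fluctuating synaptic conductances use the exact
Ornstein–Uhlenbeck update (clipped to zero only where evaluated into a
current). Spike peaks are refined by parabolic interpolation so peak
times do not quantize to the step size.

Initialization: the model settles for 500 ms (zero stimulus) once and
the settled state is reused as the initial condition for repeated
trials; a drift check (<1 µV/ms at the soma) guards the settled state.

Units: mV, ms, nA, µm, µS, nF internally; Ω cm, kΩ cm², µF/cm², GΩ/cm
at the interfaces.

## Demyelination transforms

`Scenario` objects apply region-masked transforms: `remove_myelin`
replaces the sheath with the bare sentinels and sets the bared
membrane to NaV 200 pS/µm² (the published default; `min_gna_search`
implements the original calibration procedure — smallest density that
propagates a single AP without ectopic spiking), Kv1/Kv7 15 pS/µm².
`remove_nodes` lowers nodal NaV to the internodal density. Spheroids
scale local diameters (relative to the section's configured diameter,
so application is idempotent); decompaction substitutes a
reduced-lamella sheath. The `cpz` preset (gray-matter demyelination
with intact nodes: Ctx + Thal) is the condition used for the
burst-transfer experiments.

## Standard protocols (`saltax.study`)

- Single AP: 3 ms somatic step at threshold (found by bisection); CV =
  AIS→terminal path length / peak-time difference; spike-to-spike
  delay adds a nominal 1.5 ms synaptic delay.
- Burst transfer: 150 ms trials with the point-conductance background
  (g_e 0.012 ± 0.012 µS, τ 2.72 ms; g_i 0.057 ± 0.0066 µS, τ 10.50 ms,
  at an apical site 50 µm from the soma) plus a 1.7 nA, 20 ms somatic
  step. Intra-burst frequency, spike counts, propagation failure and
  L5→POm delay variance are measured on the evoked window
  (step onset to offset + 8 ms), because the background also fires the
  cell spontaneously outside it.
- Passive probes: −0.1 nA/100 ms step for input resistance; settled
  somatic potential for the resting potential.
- Myelin sweep: CV across 0–21 lamellae (0 = fully demyelinated with
  the bare-NaV floor); the curve rises monotonically and saturates.

With the default configuration the model measures: resting potential
−81.4 mV, input resistance 13.8 MΩ, CV 1.62 m/s at 9 lamellae
(0.40 m/s bare, 2.0 m/s at 21 lamellae), spike-to-spike delay 4.1 ms,
first-AP halfwidth ≈370–440 µs across background seeds, control bursts
of ~4 spikes near 200 Hz with ~2% propagation failure, and gray-matter
demyelinated bursts at a similar or slightly higher rate with ~35%
failure of intra-burst spikes and a ~7-fold larger delay variance.
The demyelinated-vs-control frequency *difference* (paired seeds:
≈+5 Hz) is smaller than the experimentally reported separation; both
conditions nevertheless fall within the reported uncertainty bands.
These numbers are produced by `scripts/acceptance.py` and the test
suite — nothing in this note is asserted beyond what those compute.

## Synthetic sessions

The generators in `saltax.synthetic_data` emulate the *statistical*
structure of the recordings — Poisson background at 0.5/0.6 Hz
(L5/POm), optogenetically locked 3–4-spike L5 bursts near 200 Hz,
planted monosynaptic L5→POm connections with transmission delay,
first-spike failure probability, jitter and giant-synapse depression
for later burst spikes, and paired opto/whisker coincidence trials
with a supralinear boost window. They do not emulate waveforms, common
drive between units, cortical up/down states, or non-stationary rates;
a passing analysis on synthetic sessions therefore validates the
estimator logic and its calibration, not robustness to those real-data
complications. Every generator returns a machine-readable ground-truth
record, and the analysis tests assert recovery against it.

One calibration is analytically bounded: with a two-sided Fisher test
at α = 0.05 on an 11-delay grid, the probability that a *null*
coincidence experiment yields a zero-width integration window cannot
exceed ≈0.86 for any Bernoulli design (exact enumeration over count
tables); the generator defaults (paired 30 trials/delay at p = 0.02,
singles 90 trials/modality shared across delays) sit at that optimum,
and the calibration test compares the Monte-Carlo rate against the
enumerated value rather than an unattainable target.

## Known limitations

- Channel kinetics are a calibrated stand-in; quantities that depend
  on them (CV, burst frequency, failure rates) carry that uncertainty
  and are validated only within the published tolerance bands.
- The morphology is a parameterized stick model: no collateral trees,
  curvature, or per-internode length variation.
- The giant synapse is a fixed 1.5 ms delay, not a release model;
  POm spiking itself is not simulated.
- The periaxonal layer is the only extracellular compartment; there is
  no far-field potential.
- The demyelinated>control burst-frequency separation is reproduced in
  direction but at ~+5 Hz (paired seeds) rather than the reported
  ~+29 Hz; under the stated per-condition uncertainty bands both
  conditions pass, but single 20-trial batches scatter with SD ≈5 Hz,
  so individual reruns can land outside a band.
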