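"""Time-domain solver for the coupled neuronal/double-cable system.

The axon is a two-layer cable: the intracellular core couples axially
through the cytoplasmic resistivity ``R_i``; under the myelin sheath a
periaxonal layer couples longitudinally through ``r_pa`` (raised to
``r_pn`` across the paranodal seal) and radially to ground through the
sheath's ``R_my``/``C_my``.  Unmyelinated membrane (soma, dendrites,
AIS, nodes of Ranvier, terminal bouton, demyelinated stretches) has its
external layer collapsed to ground.  Integration is backward Euler
(unconditionally stable for the stiff two-layer system at 10 µs steps)
with staggered analytic exponential updates of the HH gating states.

The module also provides spike detection (50 V/s threshold criterion),
AP waveform measurement, conduction-velocity estimation, and the
point-conductance (Ornstein-Uhlenbeck) fluctuating synaptic input used
to emulate in vivo background activity.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .biophysics import (
    CalciumDynamics,
    ChannelSpec,
    DensityTable,
    MyelinSpec,
    PassiveSpec,
    SegmentConductances,
    assign_densities,
    channel_steady_state,
    load_kinetics,
    myelin_params_from_lamellae,
)
from .morphology import (
    DOMAINS,
    Discretization,
    MorphConfig,
    Morphology,
    SegmentationRule,
    build_default_morphology,
    segmentize,
)

FARADAY = 96485.3329  # C/mol

#: domains whose membrane lies under the myelin sheath
SHEATHED_DOMAINS = ("paranode", "juxtaparanode", "internode")


class SimulationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Run parameters for one simulation."""

    duration: float            # ms
    dt: float = 0.010          # ms (10 µs)
    temperature: float = 37.0  # °C
    seed: int = 0
    record_sites: tuple = ("soma", "ais_end", "bouton")
    theta: float = 0.5         # implicit weight: 0.5 Crank-Nicolson, 1.0 backward Euler

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("require dt > 0 and duration >= dt")


@dataclass
class FluctuatingInput:
    """Point-conductance synaptic background (two OU processes).

    Means/SDs are total conductances in µS injected at one apical
    segment ~50 µm from the soma; the excitatory and inhibitory
    processes relax with their own time constants toward their means.
    """

    site: str = "apical_50um"
    g_e0: float = 0.012
    sd_e: float = 0.012
    tau_e: float = 2.72
    e_e: float = 0.0
    g_i0: float = 0.057
    sd_i: float = 0.0066
    tau_i: float = 10.50
    e_i: float = -75.0

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("OU time constants must be > 0")
        if self.sd_e < 0 or self.sd_i < 0:
            raise ValueError("OU SDs must be >= 0")


@dataclass
class StimulusProtocol:
    """Step currents plus optional fluctuating background."""

    step_currents: list = field(default_factory=list)  # (site, onset, dur, nA)
    fluctuating: FluctuatingInput | None = None


@dataclass
class SimResult:
    """Recorded traces and detected spikes.

    ``v_m`` holds transmembrane potentials, ``v_mym`` the transmyelin
    (periaxonal-layer) potentials of the recorded segments; ``spikes``
    holds AP peak times per site.
    """

    time: np.ndarray
    v_m: dict
    v_mym: dict
    spikes: dict
    thresholds: dict
    dt: float


@dataclass
class State:
    """Full dynamic state of a cable system (for settling/reuse)."""

    vi: np.ndarray
    ve: np.ndarray
    gates: np.ndarray
    ca: np.ndarray
    ou: np.ndarray

    def copy(self) -> "State":
        return State(self.vi.copy(), self.ve.copy(), self.gates.copy(),
                     self.ca.copy(), self.ou.copy())


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


@dataclass
class Model:
    """A buildable model: geometry + densities + myelin + passive."""

    morphology: Morphology
    disc: Discretization
    passive: PassiveSpec
    conductances: SegmentConductances
    myelin: list                      # per segment: MyelinSpec or None
    kinetics: dict
    calcium: CalciumDynamics = field(default_factory=CalciumDynamics)

    def copy(self) -> "Model":
        return Model(
            morphology=self.morphology,
            disc=copy.deepcopy(self.disc),
            passive=copy.deepcopy(self.passive),
            conductances=SegmentConductances(
                {k: v.copy() for k, v in self.conductances.density.items()}
            ),
            myelin=list(self.myelin),
            kinetics=self.kinetics,
            calcium=copy.deepcopy(self.calcium),
        )


def build_default_model(
    n_lamellae: int = 9,
    morph_config: MorphConfig | None = None,
    passive: PassiveSpec | None = None,
    rule: SegmentationRule | None = None,
    density_table: DensityTable | None = None,
    kinetics: dict | None = None,
) -> Model:
    """Assemble the default control model (9-lamella sheath)."""
    passive = passive or PassiveSpec()
    morph = build_default_morphology(morph_config)
    disc = segmentize(morph, rule or SegmentationRule(), passive)
    cond = assign_densities(disc, density_table or DensityTable.from_yaml())
    spec = myelin_params_from_lamellae(n_lamellae)
    sheathed = {DOMAINS.index(d) for d in SHEATHED_DOMAINS}
    myelin = [
        spec if int(code) in sheathed else None for code in disc.domain_code
    ]
    return Model(
        morphology=morph,
        disc=disc,
        passive=passive,
        conductances=cond,
        myelin=myelin,
        kinetics=kinetics or load_kinetics(),
    )


# ---------------------------------------------------------------------------
# compiled cable system
# ---------------------------------------------------------------------------

_VGRID_LO, _VGRID_HI, _VGRID_DV = -130.0, 70.0, 0.05


class CableSystem:
    """Flat-array form of a model, ready for the integrator kernel."""

    def __init__(self, model: Model):
        self.model = model
        d = model.disc
        p = model.passive
        n = d.n_segments
        self.n = n
        self.sites = dict(d.sites)
        self.temperature = p.temperature

        area_cm2 = d.area * 1e-8  # µm² -> cm²
        self.cm = p.c_m * area_cm2 * 1e3          # nF
        self.gpas = p.g_pas_s_cm2 * area_cm2 * 1e6  # µS
        self.epas = p.e_pas

        # myelin layer
        grounded = np.ones(n, dtype=np.uint8)
        gmy = np.zeros(n)
        cmy = np.zeros(n)
        r_per_cm = np.zeros(n)  # periaxonal longitudinal resistance, GΩ/cm
        for i, spec in enumerate(model.myelin):
            if spec is None or spec.bare:
                continue
            grounded[i] = 0
            gmy[i] = area_cm2[i] / (spec.r_my_kohm_cm2 * 1e3) * 1e6   # µS
            cmy[i] = spec.c_my_uf_cm2 * area_cm2[i] * 1e3             # nF
            if d.domain_of(i) == "paranode":
                r_per_cm[i] = spec.r_pn_gohm_cm
            else:
                r_per_cm[i] = spec.effective_r_pa_gohm_cm()
        self.grounded = grounded
        self.gmy = gmy
        self.cmy = cmy

        # axial couplings
        parent = d.parent
        if (parent[1:] >= np.arange(1, n)).any():
            raise SimulationError("segment ordering violates parent < child")
        if (parent[1:] < 0).any():
            raise SimulationError("disconnected discretization")
        ga = np.zeros(n)
        gp = np.zeros(n)
        gp_ground = np.zeros(n)
        half_r_intra = (
            p.r_i * (d.length * 1e-4 / 2.0) / (np.pi * (d.diam * 1e-4 / 2.0) ** 2)
        )  # Ω per half segment
        for i in range(1, n):
            q = parent[i]
            r_ohm = half_r_intra[i] + half_r_intra[q]
            ga[i] = 1.0 / (r_ohm / 1e6)  # µS = 1/MΩ
            gi_my = grounded[i] == 0
            gq_my = grounded[q] == 0
            if gi_my and gq_my:
                r_gohm = (
                    r_per_cm[i] * d.length[i] * 1e-4 / 2.0
                    + r_per_cm[q] * d.length[q] * 1e-4 / 2.0
                )
                gp[i] = 1e-3 / r_gohm  # µS = 1/MΩ = 1e-3/GΩ
            elif gi_my:
                r_gohm = r_per_cm[i] * d.length[i] * 1e-4 / 2.0
                gp_ground[i] += 1e-3 / r_gohm
            elif gq_my:
                r_gohm = r_per_cm[q] * d.length[q] * 1e-4 / 2.0
                gp_ground[q] += 1e-3 / r_gohm
        self.parent = parent.astype(np.int64)
        self.ga = ga
        self.gp = gp
        self.gp_ground = gp_ground

        # channels
        self._pack_channels(model, area_cm2)

        # calcium shell
        cal = model.calcium
        vol_cm3 = area_cm2 * (cal.depth_um * 1e-4)
        scale = 1e-6 / (2.0 * FARADAY * np.maximum(vol_cm3, 1e-30))
        has_ca = np.zeros(n, dtype=bool)
        for c, name in enumerate(self.chan_names):
            if self.is_ca[c]:
                has_ca[self.chan_seg[self.chan_ptr[c]:self.chan_ptr[c + 1]]] = True
        self.ca_scale = np.where(has_ca, scale, 0.0)
        self.tau_ca = cal.tau_decay_ms
        self.ca0 = cal.ca0_mm

        self._tables_dt: float | None = None

    # -- channel packing ---------------------------------------------------

    def _pack_channels(self, model: Model, area_cm2: np.ndarray) -> None:
        dens = model.conductances.density
        kin = model.kinetics
        chan_names, chan_seg, gbar, chan_ptr = [], [], [], [0]
        for name, values in dens.items():
            if name not in kin:
                raise SimulationError(f"no kinetics for channel {name!r}")
            idx = np.nonzero(values > 0)[0]
            if len(idx) == 0:
                continue
            chan_names.append(name)
            chan_seg.append(idx)
            gbar.append(values[idx] * area_cm2[idx] * 1e2)  # pS/µm² -> µS
            chan_ptr.append(chan_ptr[-1] + len(idx))
        self.chan_names = chan_names
        self.chan_seg = (
            np.concatenate(chan_seg).astype(np.int64)
            if chan_seg else np.empty(0, dtype=np.int64)
        )
        self.gbar = np.concatenate(gbar) if gbar else np.empty(0)
        self.chan_ptr = np.asarray(chan_ptr, dtype=np.int64)
        self.erev = np.array([kin[c].reversal for c in chan_names])
        self.is_ca = np.array(
            [1 if kin[c].is_ca_channel else 0 for c in chan_names], dtype=np.uint8
        )

        gate_chan, gate_exp, gate_is_kca = [], [], []
        gate_kca_a, gate_kca_b, gate_specs = [], [], []
        gate_state_ptr = [0]
        for c, name in enumerate(chan_names):
            spec: ChannelSpec = kin[name]
            n_inst = self.chan_ptr[c + 1] - self.chan_ptr[c]
            for g in spec.gates:
                gate_chan.append(c)
                gate_exp.append(g.exponent)
                kca = spec.ca_dependent
                gate_is_kca.append(1 if kca else 0)
                qt = spec.qt(self.temperature)
                if kca:
                    gate_kca_a.append(g.a["c0"] * qt)
                    gate_kca_b.append(g.b["c0"] * qt)
                else:
                    gate_kca_a.append(0.0)
                    gate_kca_b.append(0.0)
                gate_specs.append((name, g))
                gate_state_ptr.append(gate_state_ptr[-1] + int(n_inst))
        self.gate_chan = np.asarray(gate_chan, dtype=np.int64)
        self.gate_exp = np.asarray(gate_exp, dtype=np.int64)
        self.gate_is_kca = np.asarray(gate_is_kca, dtype=np.uint8)
        self.gate_kca_a = np.asarray(gate_kca_a)
        self.gate_kca_b = np.asarray(gate_kca_b)
        self.gate_state_ptr = np.asarray(gate_state_ptr, dtype=np.int64)
        self.gate_specs = gate_specs
        self.n_gate_states = int(self.gate_state_ptr[-1])

    # -- rate tables -------------------------------------------------------

    def _build_tables(self, dt: float) -> None:
        if self._tables_dt == dt:
            return
        kin = self.model.kinetics
        vgrid = np.arange(_VGRID_LO, _VGRID_HI + _VGRID_DV / 2, _VGRID_DV)
        n_gate = len(self.gate_specs)
        xinf = np.empty((n_gate, len(vgrid)))
        xfac = np.empty((n_gate, len(vgrid)))
        cache: dict[str, dict] = {}
        for gi, (cname, gspec) in enumerate(self.gate_specs):
            if self.gate_is_kca[gi]:
                xinf[gi] = 0.0
                xfac[gi] = 0.0
                continue
            if cname not in cache:
                cache[cname] = channel_steady_state(
                    kin[cname], vgrid, temperature=self.temperature
                )
            inf, tau = cache[cname][gspec.name]
            xinf[gi] = inf
            xfac[gi] = 1.0 - np.exp(-dt / tau)
        self.xinf_tab = np.ascontiguousarray(xinf)
        self.xfac_tab = np.ascontiguousarray(xfac)
        self.vgrid0 = float(vgrid[0])
        self.vgrid_dv = _VGRID_DV
        self._tables_dt = dt

    # -- state -------------------------------------------------------------

    def initial_state(self, v0: float | None = None) -> State:
        """Uniform state at ``v0`` (default leak reversal), gates at x_inf."""
        v0 = self.epas if v0 is None else v0
        vi = np.full(self.n, v0)
        ve = np.zeros(self.n)
        gates = np.empty(self.n_gate_states)
        kin = self.model.kinetics
        for gi, (cname, gspec) in enumerate(self.gate_specs):
            s0, s1 = self.gate_state_ptr[gi], self.gate_state_ptr[gi + 1]
            if self.gate_is_kca[gi]:
                a = self.gate_kca_a[gi] * self.ca0
                gates[s0:s1] = a / (a + self.gate_kca_b[gi])
            else:
                inf, _ = channel_steady_state(
                    kin[cname], np.array([v0]), temperature=self.temperature
                )[gspec.name]
                gates[s0:s1] = inf[0]
        ca = np.full(self.n, self.ca0)
        ou = np.zeros(2)
        return State(vi, ve, gates, ca, ou)

    def path_length_between(self, site_a: str, site_b: str) -> float:
        """Axonal path length (µm) between two named record sites."""
        d = self.model.disc
        return abs(float(d.path_dist[self.sites[site_b]] - d.path_dist[self.sites[site_a]]))


def build_system(
    d: Discretization,
    g: SegmentConductances,
    myelin,
    p: PassiveSpec,
    kinetics: dict | None = None,
    calcium: CalciumDynamics | None = None,
) -> CableSystem:
    """Compile a discretization + conductances + myelin map to a system.

    ``myelin`` is either a single :class:`MyelinSpec` (applied to every
    paranode/juxtaparanode/internode segment) or a per-segment sequence
    of ``MyelinSpec | None``; ``None`` and bare specs collapse the
    periaxonal layer to ground.
    """
    if isinstance(myelin, MyelinSpec):
        sheathed = {DOMAINS.index(x) for x in SHEATHED_DOMAINS}
        myelin = [myelin if int(c) in sheathed else None for c in d.domain_code]
    model = Model(
        morphology=d.morphology,
        disc=d,
        passive=p,
        conductances=g,
        myelin=list(myelin),
        kinetics=kinetics or load_kinetics(),
        calcium=calcium or CalciumDynamics(),
    )
    return CableSystem(model)


# ---------------------------------------------------------------------------
# running simulations
# ---------------------------------------------------------------------------


def _resolve_site(sys: CableSystem, site) -> int:
    if isinstance(site, (int, np.integer)):
        return int(site)
    try:
        return sys.sites[site]
    except KeyError:
        raise SimulationError(f"unknown site {site!r}; known: {sorted(sys.sites)}")


def run_simulation(
    sys: CableSystem,
    proto: StimulusProtocol,
    cfg: SimConfig,
    init_state: State | None = None,
    return_state: bool = False,
):
    """Integrate the system and return a :class:`SimResult`.

    Identical seeds and configs give bitwise-identical results.  If
    ``init_state`` is omitted the run starts from the uniform
    leak-reversal state (use :func:`settle` for a resting start).
    """
    sys._build_tables(cfg.dt)
    nsteps = int(round(cfg.duration / cfg.dt))
    state = (init_state.copy() if init_state is not None
             else sys.initial_state())

    stim_seg, stim_on, stim_off, stim_amp = [], [], [], []
    for (site, onset, dur, amp) in proto.step_currents:
        if not (0.0 <= onset <= cfg.duration):
            raise SimulationError(f"stimulus onset {onset} outside [0, duration]")
        stim_seg.append(_resolve_site(sys, site))
        stim_on.append(float(onset))
        stim_off.append(float(onset + dur))
        stim_amp.append(float(amp))

    flu = proto.fluctuating
    if flu is not None:
        ou_seg = _resolve_site(sys, flu.site)
        ou_par = np.array([flu.g_e0, flu.sd_e, flu.tau_e, flu.e_e,
                           flu.g_i0, flu.sd_i, flu.tau_i, flu.e_i])
        rng = np.random.default_rng(cfg.seed)
        noise = rng.standard_normal((nsteps, 2))
        if init_state is None or not init_state.ou.any():
            state.ou = np.array([flu.g_e0, flu.g_i0])
    else:
        ou_seg = -1
        ou_par = np.zeros(8)
        noise = np.zeros((1, 2))

    rec_idx = np.array([_resolve_site(sys, s) for s in cfg.record_sites],
                       dtype=np.int64)
    vm_out = np.empty((nsteps + 1, len(rec_idx)))
    ve_out = np.empty((nsteps + 1, len(rec_idx)))

    bad_step = _kernels.integrate(
        nsteps, cfg.dt, cfg.theta,
        sys.parent, sys.ga, sys.gp, sys.grounded,
        sys.cm, sys.cmy, sys.gmy, sys.gp_ground, sys.gpas, sys.epas,
        sys.chan_ptr, sys.chan_seg, sys.gbar, sys.erev, sys.is_ca,
        sys.gate_chan, sys.gate_exp, sys.gate_is_kca,
        sys.gate_kca_a, sys.gate_kca_b, sys.gate_state_ptr,
        state.gates, sys.xinf_tab, sys.xfac_tab, sys.vgrid0, sys.vgrid_dv,
        state.ca, sys.ca_scale, sys.tau_ca, sys.ca0,
        ou_seg, ou_par, state.ou, noise,
        np.asarray(stim_seg, dtype=np.int64), np.asarray(stim_on),
        np.asarray(stim_off), np.asarray(stim_amp),
        state.vi, state.ve,
        rec_idx, vm_out, ve_out,
    )
    if bad_step >= 0:
        seg = int(np.nonzero(~np.isfinite(state.vi))[0][0]) if (
            ~np.isfinite(state.vi)).any() else -1
        raise SimulationError(
            f"divergence (non-finite voltage) at t={bad_step * cfg.dt:.3f} ms, "
            f"segment {seg}"
        )

    time = np.arange(nsteps + 1) * cfg.dt
    v_m = {str(s): vm_out[:, k] for k, s in enumerate(cfg.record_sites)}
    v_mym = {str(s): ve_out[:, k] for k, s in enumerate(cfg.record_sites)}
    spikes, thresholds = {}, {}
    for name, trace in v_m.items():
        st, th = detect_spikes(trace, cfg.dt)
        spikes[name] = st
        thresholds[name] = th
    res = SimResult(time=time, v_m=v_m, v_mym=v_mym, spikes=spikes,
                    thresholds=thresholds, dt=cfg.dt)
    if return_state:
        return res, state
    return res


def settle(sys: CableSystem, duration: float = 500.0, dt: float = 0.01,
           drift_tol: float = 1e-3) -> State:
    """Relax the system to rest and return the settled state.

    Runs with zero stimulus from the uniform leak-reversal state; warns
    via exception if the somatic drift at the end still exceeds
    ``drift_tol`` mV/ms.
    """
    cfg = SimConfig(duration=duration, dt=dt, record_sites=("soma",),
                    temperature=sys.temperature, theta=1.0)
    res, state = run_simulation(sys, StimulusProtocol(), cfg, return_state=True)
    v = res.v_m["soma"]
    drift = abs(v[-1] - v[-101]) / (100 * dt)
    if drift > drift_tol:
        raise SimulationError(f"did not settle: somatic drift {drift:.2e} mV/ms")
    return state


def resting_potential(sys: CableSystem, duration: float = 500.0,
                      dt: float = 0.01) -> float:
    """Somatic resting potential (mV) after settling."""
    state = settle(sys, duration=duration, dt=dt)
    soma = sys.sites["soma"]
    return float(state.vi[soma] - state.ve[soma])


def input_resistance(sys: CableSystem, state: State | None = None,
                     amp_na: float = -0.1, dur_ms: float = 100.0,
                     dt: float = 0.01) -> float:
    """Somatic input resistance (MΩ) from a small hyperpolarizing step."""
    if state is None:
        state = settle(sys, dt=dt)
    cfg = SimConfig(duration=dur_ms + 20.0, dt=dt, record_sites=("soma",),
                    temperature=sys.temperature)
    proto = StimulusProtocol(step_currents=[("soma", 10.0, dur_ms, amp_na)])
    res = run_simulation(sys, proto, cfg, init_state=state)
    v = res.v_m["soma"]
    i0 = int(round(9.0 / dt))
    i1 = int(round((10.0 + dur_ms - 2.0) / dt))
    dv = v[i1] - v[i0]
    return float(dv / amp_na)  # mV / nA = MΩ


# ---------------------------------------------------------------------------
# point-conductance OU step (exposed for testing/composition)
# ---------------------------------------------------------------------------


def ou_conductance_step(g: float, g0: float, sd: float, tau: float,
                        dt: float, noise: float) -> float:
    """Exact Ornstein-Uhlenbeck update of a fluctuating conductance.

    ``g' = g0 + (g - g0) e^(−dt/τ) + sd sqrt(1 − e^(−2dt/τ)) · noise``.
    The process state is left unclipped; clipping to zero happens where
    the conductance is evaluated into a current.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    f = math.exp(-dt / tau)
    return g0 + (g - g0) * f + sd * math.sqrt(1.0 - f * f) * noise


# ---------------------------------------------------------------------------
# spike detection and waveform measures
# ---------------------------------------------------------------------------


def detect_spikes(trace: np.ndarray, dt: float, dvdt_thresh: float = 50.0,
                  peak_min: float = 0.0, refractory: float = 1.0):
    """AP peak times from a voltage trace.

    A spike is a local maximum above ``peak_min`` mV preceded (within
    5 ms) by a crossing of the ``dvdt_thresh`` V/s (= mV/ms) rising
    slope; peaks closer than ``refractory`` ms merge into the larger
    one.  Returns ``(peak times ms, threshold voltages mV)``.
    """
    v = np.asarray(trace, dtype=float)
    if len(v) < 3:
        return np.empty(0), np.empty(0)
    dvdt = np.diff(v) / dt  # mV/ms == V/s
    above = dvdt >= dvdt_thresh
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])

    cand = np.nonzero(
        (v[1:-1] > peak_min) & (v[1:-1] >= v[:-2]) & (v[1:-1] > v[2:])
    )[0] + 1
    peaks, thresholds = [], []
    lookback = int(round(5.0 / dt))
    for pk in cand:
        prior = crossings[(crossings <= pk) & (crossings >= pk - lookback)]
        if len(prior) == 0:
            continue
        if peaks and (pk - peaks[-1]) * dt < refractory:
            if v[pk] > v[peaks[-1]]:
                peaks[-1] = pk
                thresholds[-1] = v[prior[0]]
            continue
        peaks.append(pk)
        thresholds.append(v[prior[0]])
    times = np.empty(len(peaks))
    for k, pk in enumerate(peaks):
        # sub-sample peak time by parabolic interpolation
        denom = v[pk - 1] - 2.0 * v[pk] + v[pk + 1]
        frac = 0.5 * (v[pk - 1] - v[pk + 1]) / denom if denom < 0 else 0.0
        times[k] = (pk + frac) * dt
    return times, np.array(thresholds)


def measure_ap_waveform(trace: np.ndarray, dt: float, spike_time: float,
                        dvdt_thresh: float = 50.0):
    """Amplitude (mV) and halfwidth (µs) of one AP.

    Amplitude is peak minus the voltage at the 50 V/s threshold
    crossing; halfwidth is the time spent above half-amplitude with the
    crossings linearly interpolated.
    """
    v = np.asarray(trace, dtype=float)
    pk = int(round(spike_time / dt))
    if pk <= 1 or pk >= len(v) - 2:
        raise SimulationError("spike truncated by trace edge")
    dvdt = np.diff(v) / dt
    # last upward crossing of the slope threshold before the peak
    seg = dvdt[:pk]
    idx = np.nonzero((seg[1:] >= dvdt_thresh) & (seg[:-1] < dvdt_thresh))[0]
    if len(idx) == 0:
        if seg[0] >= dvdt_thresh:
            base_i = 0
        else:
            raise SimulationError("no threshold crossing before spike peak")
    else:
        base_i = int(idx[-1] + 1)
    baseline = v[base_i]
    amp = v[pk] - baseline
    half = baseline + amp / 2.0

    i = pk
    while i > base_i and v[i - 1] > half:
        i -= 1
    if i == base_i and v[i] > half:
        raise SimulationError("spike truncated: no rising half crossing")
    t_rise = (i - 1 + (half - v[i - 1]) / (v[i] - v[i - 1])) * dt
    k = pk
    while k < len(v) - 1 and v[k + 1] > half:
        k += 1
    if k == len(v) - 1:
        raise SimulationError("spike truncated by trace edge")
    t_fall = (k + (v[k] - half) / (v[k] - v[k + 1])) * dt
    return float(amp), float((t_fall - t_rise) * 1e3)  # ms -> µs


def match_spikes(up: np.ndarray, down: np.ndarray,
                 window: tuple = (0.2, 15.0)):
    """Order-preserving greedy pairing of upstream/downstream spikes.

    Each upstream spike matches the earliest unmatched downstream spike
    whose delay lies in the causal ``window`` (ms); ties go to the
    earliest.  Returns an array of matched downstream indices (-1 for
    propagation failures).
    """
    lo, hi = window
    out = np.full(len(up), -1, dtype=np.int64)
    j = 0
    for i, t in enumerate(up):
        while j < len(down) and down[j] < t + lo:
            j += 1
        if j < len(down) and down[j] <= t + hi:
            out[i] = j
            j += 1
    return out


def conduction_velocity(res: SimResult, site_a: str, site_b: str,
                        path_length_um: float,
                        window: tuple = (0.2, 15.0)) -> np.ndarray:
    """Per-spike conduction velocities (m/s) between two recorded sites.

    ``CV = path_length / (t_peak(b) − t_peak(a))`` for order-preserving
    matched spike pairs.  Raises if any matched pair has a non-positive
    delay or if either site lacks spikes.
    """
    sa = res.spikes[site_a]
    sb = res.spikes[site_b]
    if len(sa) == 0 or len(sb) == 0:
        raise SimulationError("both sites need at least one spike")
    m = match_spikes(sa, sb, window)
    cvs = []
    for i, j in enumerate(m):
        if j < 0:
            continue
        dt_ms = sb[j] - sa[i]
        if dt_ms <= 0:
            raise SimulationError("non-positive peak delay; check detection")
        cvs.append(path_length_um / dt_ms * 1e-3)  # µm/ms -> m/s
    if not cvs:
        raise SimulationError("no causal spike pairs matched")
    return np.asarray(cvs)


def spike_to_spike_delay(propagation_ms: float, synaptic_ms: float = 1.5) -> float:
    """Total L5->POm spike-to-spike delay: propagation + synaptic delay."""
    if propagation_ms < 0 or synaptic_ms < 0:
        raise ValueError("delays must be >= 0")
    return propagation_ms + synaptic_ms


def threshold_step_current(
    sys: CableSystem, state: State, site: str = "soma", dur_ms: float = 3.0,
    lo: float = 0.2, hi: float = 12.0, tol: float = 0.05,
    probe_ms: float = 12.0, dt: float = 0.01,
) -> float:
    """Minimal step current (nA) that evokes an AIS spike, by bisection."""

    def fires(amp: float) -> bool:
        cfg = SimConfig(duration=probe_ms, dt=dt, record_sites=("ais_end",),
                        temperature=sys.temperature)
        proto = StimulusProtocol(step_currents=[(site, 1.0, dur_ms, amp)])
        res = run_simulation(sys, proto, cfg, init_state=state)
        return len(res.spikes["ais_end"]) > 0

    if fires(lo):
        return lo
    if not fires(hi):
        raise SimulationError(f"no spike up to {hi} nA")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi
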