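"""Passive properties, myelin double-cable parameters, and HH channels.

The myelin sheath is represented by a radial resistance/capacitance pair
(``R_my``, ``C_my``) between the periaxonal space and ground, derived
from the per-membrane values by counting two membranes per lamella in
series:

    R_my = 2 n R_mem,      C_my = C_mem / (2 n)

with ``R_mem`` = 8.56 kΩ cm² and ``C_mem`` = 1.00 µF/cm².  The
periaxonal space (~12 nm) contributes a longitudinal resistance
``r_pa`` = 124.9 GΩ/cm under internodes, raised 18.15-fold under the
paranodal seal.

Voltage-gated conductances follow Hodgkin-Huxley formalism.  The exact
rate equations of the study system are not published; the default
kinetics shipped in ``data/kinetics.yaml`` are drawn from the rat L5
pyramidal-neuron modelling literature (fast m³h Na⁺, persistent Na⁺,
low-threshold slowly-inactivating Kv1, delayed-rectifier Kv2/3, M-type
Kv7, high/low-threshold Ca²⁺, Ca²⁺-activated K⁺, HCN) and are fully
swappable without touching the solver.  Gating rates scale with
temperature as Q10^((T-T_ref)/10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .morphology import DOMAINS, DOMAIN_CODE, Discretization


class BiophysicsError(ValueError):
    pass


@dataclass
class PassiveSpec:
    """Passive cable parameters (uniform across domains)."""

    r_i: float = 180.0       # Ω cm, cytoplasmic resistivity
    c_m: float = 0.9         # µF/cm², membrane capacitance
    r_m: float = 2.3         # kΩ cm², membrane resistance (leak = 1/R_m)
    e_pas: float = -85.0     # mV, leak reversal
    temperature: float = 37.0  # °C

    def __post_init__(self) -> None:
        if min(self.r_i, self.c_m, self.r_m) <= 0:
            raise BiophysicsError("passive resistances/capacitance must be > 0")

    @property
    def g_pas_s_cm2(self) -> float:
        """Leak conductance in S/cm²."""
        return 1.0 / (self.r_m * 1e3)


# sentinel values for a bare (demyelinated or never-myelinated) segment:
# the sheath collapses to a near-short so the periaxonal layer sits at
# ground, and the external layer carries no capacitance.
BARE_R_MY_KOHM_CM2 = 1e-6 * 1e-3   # 1e-6 Ω cm² expressed in kΩ cm²
BARE_C_MY_UF_CM2 = 0.9
BARE_R_PA_GOHM_CM = 1e-6 * 1e-3    # 1e-6 MΩ/cm in GΩ/cm
BARE_R_PN_GOHM_CM = 1e-8 * 1e-3    # 1e-8 MΩ/cm in GΩ/cm


@dataclass
class MyelinSpec:
    """Lamella-parameterized sheath and periaxonal-space parameters."""

    n_lamellae: int = 9
    r_mem_kohm_cm2: float = 8.56
    c_mem_uf_cm2: float = 1.00
    r_pa_gohm_cm: float = 124.9
    r_pn_factor: float = 18.15

    def __post_init__(self) -> None:
        if self.n_lamellae < 0:
            raise BiophysicsError("n_lamellae must be >= 0")

    @property
    def bare(self) -> bool:
        return self.n_lamellae == 0

    @property
    def r_my_kohm_cm2(self) -> float:
        if self.bare:
            return BARE_R_MY_KOHM_CM2
        return 2.0 * self.n_lamellae * self.r_mem_kohm_cm2

    @property
    def c_my_uf_cm2(self) -> float:
        if self.bare:
            return BARE_C_MY_UF_CM2
        return self.c_mem_uf_cm2 / (2.0 * self.n_lamellae)

    @property
    def r_pn_gohm_cm(self) -> float:
        if self.bare:
            return BARE_R_PN_GOHM_CM
        return self.r_pn_factor * self.r_pa_gohm_cm

    def effective_r_pa_gohm_cm(self) -> float:
        if self.bare:
            return BARE_R_PA_GOHM_CM
        return self.r_pa_gohm_cm


def myelin_params_from_lamellae(
    n: int, r_mem: float = 8.56, c_mem: float = 1.00
) -> MyelinSpec:
    """Sheath parameters for an ``n``-lamella myelin stack.

    Each lamella contributes two membranes in radial series, so
    ``R_my = 2 n R_mem`` and ``C_my = C_mem / (2 n)``.  ``n = 0``
    returns the demyelinated sentinel (near-short sheath, bare-membrane
    capacitance).
    """
    if n < 0:
        raise BiophysicsError("lamella count must be >= 0")
    return MyelinSpec(n_lamellae=int(n), r_mem_kohm_cm2=r_mem, c_mem_uf_cm2=c_mem)


@dataclass
class CalciumDynamics:
    """First-order submembrane Ca²⁺ accumulation/decay."""

    tau_decay_ms: float = 80.0
    depth_um: float = 0.1
    ca0_mm: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.tau_decay_ms, self.depth_um, self.ca0_mm) <= 0:
            raise BiophysicsError("calcium dynamics constants must be > 0")


# ---------------------------------------------------------------------------
# rate functions / channel kinetics
# ---------------------------------------------------------------------------

RATE_TYPES = ("const", "exp", "sigmoid", "linoid", "linoid_dec", "bell", "ca_linear")
RATE_CODE = {name: i for i, name in enumerate(RATE_TYPES)}


def eval_rate(spec: dict, v, ca=0.0):
    """Evaluate one rate-function spec at voltage ``v`` (mV).

    Supported forms (all singularity-protected):

    - ``const``:      c0
    - ``exp``:        c0 · exp((v−c1)/c2)
    - ``sigmoid``:    c3 + c0 / (1 + exp(−(v−c1)/c2))
    - ``linoid``:     c0 (v−c1) / (1 − exp(−(v−c1)/c2)), limit c0·c2 at v=c1
    - ``linoid_dec``: c0 (c1−v) / (1 − exp((v−c1)/c2)), limit c0·c2 at v=c1
    - ``bell``:       c0 + c1 / (exp((v−c2)/c3) + exp(−(v−c4)/c5))
    - ``ca_linear``:  c0 · ca
    """
    v = np.asarray(v, dtype=float)
    t = spec["type"]
    c = spec
    if t == "const":
        return np.broadcast_to(np.float64(c["c0"]), v.shape).copy()
    if t == "exp":
        return c["c0"] * np.exp((v - c["c1"]) / c["c2"])
    if t == "sigmoid":
        return c.get("c3", 0.0) + c["c0"] / (1.0 + np.exp(-(v - c["c1"]) / c["c2"]))
    if t == "linoid":
        x = (v - c["c1"]) / c["c2"]
        out = np.where(
            np.abs(x) < 1e-6, c["c0"] * c["c2"] * (1.0 + x / 2.0),
            c["c0"] * (v - c["c1"]) / (1.0 - np.exp(-np.clip(x, -500, 500))),
        )
        return out
    if t == "linoid_dec":
        x = (v - c["c1"]) / c["c2"]
        out = np.where(
            np.abs(x) < 1e-6, c["c0"] * c["c2"] * (1.0 - x / 2.0),
            c["c0"] * (c["c1"] - v) / (1.0 - np.exp(np.clip(x, -500, 500))),
        )
        return out
    if t == "bell":
        return c["c0"] + c["c1"] / (
            np.exp((v - c["c2"]) / c["c3"]) + np.exp(-(v - c["c4"]) / c["c5"])
        )
    if t == "ca_linear":
        return c["c0"] * np.asarray(ca, dtype=float) * np.ones_like(v)
    raise BiophysicsError(f"unknown rate type {t!r}")


# gate modes: how (inf, tau) derive from the stored rate specs
GATE_MODE_ALPHA_BETA = 0   # inf = a/(a+b), tau = 1/(a+b)
GATE_MODE_INF_TAU = 1      # inf and tau given directly
GATE_MODE_INF_AB_TAU = 2   # inf given directly, tau = 1/(a+b)


@dataclass
class GateSpec:
    name: str
    exponent: int
    mode: int
    a: dict | None = None     # alpha (modes 0, 2)
    b: dict | None = None     # beta (modes 0, 2)
    inf: dict | None = None   # modes 1, 2
    tau: dict | None = None   # mode 1
    tau_min_ms: float = 0.02


@dataclass
class ChannelSpec:
    """One HH-style channel: gates, exponents, reversal, Q10."""

    name: str
    reversal: float
    gates: list = field(default_factory=list)
    q10: float = 2.3
    ref_temp: float = 23.0
    ca_dependent: bool = False
    is_ca_channel: bool = False

    def qt(self, temperature: float) -> float:
        return self.q10 ** ((temperature - self.ref_temp) / 10.0)


def channel_steady_state(c: ChannelSpec, v, temperature: float = 37.0, ca: float = 1e-4):
    """Steady-state activation and time constant per gating variable.

    Returns ``{gate name: (x_inf, tau_x ms)}`` with the Q10 temperature
    factor applied to the time constants.  ``x_inf`` is guaranteed in
    [0, 1] and ``tau_x`` > 0 for any finite voltage.
    """
    qt = c.qt(temperature)
    out = {}
    for g in c.gates:
        if g.mode == GATE_MODE_ALPHA_BETA:
            a = eval_rate(g.a, v, ca)
            b = eval_rate(g.b, v, ca)
            inf = a / (a + b)
            tau = 1.0 / (a + b) / qt
        elif g.mode == GATE_MODE_INF_TAU:
            inf = eval_rate(g.inf, v, ca)
            tau = eval_rate(g.tau, v, ca) / qt
        else:
            a = eval_rate(g.a, v, ca)
            b = eval_rate(g.b, v, ca)
            inf = eval_rate(g.inf, v, ca)
            tau = 1.0 / (a + b) / qt
        tau = np.maximum(tau, g.tau_min_ms)
        inf = np.clip(inf, 0.0, 1.0)
        out[g.name] = (inf, tau)
    return out


def _parse_gate(raw: dict) -> GateSpec:
    has_ab = "alpha" in raw and "beta" in raw
    has_inf = "inf" in raw
    if has_ab and has_inf:
        mode = GATE_MODE_INF_AB_TAU
    elif has_ab:
        mode = GATE_MODE_ALPHA_BETA
    elif has_inf and "tau" in raw:
        mode = GATE_MODE_INF_TAU
    else:
        raise BiophysicsError(
            f"gate {raw.get('name')!r}: need alpha/beta, inf/tau, or inf+alpha/beta"
        )
    return GateSpec(
        name=raw["name"],
        exponent=int(raw.get("exponent", 1)),
        mode=mode,
        a=raw.get("alpha"),
        b=raw.get("beta"),
        inf=raw.get("inf"),
        tau=raw.get("tau"),
        tau_min_ms=float(raw.get("tau_min_ms", 0.02)),
    )


def load_kinetics(path=None) -> dict[str, ChannelSpec]:
    """Load the channel-kinetics data file (default: packaged set)."""
    if path is None:
        text = resources.files("saltax").joinpath("data/kinetics.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    out = {}
    for name, cfg in raw.items():
        out[name] = ChannelSpec(
            name=name,
            reversal=float(cfg["reversal"]),
            gates=[_parse_gate(g) for g in cfg.get("gates", [])],
            q10=float(cfg.get("q10", 2.3)),
            ref_temp=float(cfg.get("ref_temp", 23.0)),
            ca_dependent=bool(cfg.get("ca_dependent", False)),
            is_ca_channel=bool(cfg.get("is_ca_channel", False)),
        )
    return out


# ---------------------------------------------------------------------------
# density table
# ---------------------------------------------------------------------------


@dataclass
class DensityTable:
    """Per (domain, channel) maximal-conductance profiles (pS/µm²).

    Profiles:

    - ``const``: uniform density ``value``
    - ``linear_section``: linear ramp ``from -> to`` over the section's
      own normalized length (used for the AIS Kv1/Kv7 gradients)
    - ``linear_path``: linear ramp over normalized somatofugal path
      distance across the whole dendritic (or axonal) extent
    - ``exp_path``: exponential profile ``from·(to/from)^x`` over the
      same normalized path distance (dendritic HCN gradient)
    """

    table: dict  # domain -> channel -> profile dict

    @classmethod
    def from_yaml(cls, path=None) -> "DensityTable":
        if path is None:
            text = resources.files("saltax").joinpath("data/densities.yaml").read_text()
            raw = yaml.safe_load(text)
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        return cls(table={k: (v or {}) for k, v in raw.items()})

    def channels(self) -> list[str]:
        names: list[str] = []
        for chans in self.table.values():
            for c in chans:
                if c not in names:
                    names.append(c)
        return names


@dataclass
class SegmentConductances:
    """Per-segment maximal conductance densities, pS/µm² per channel."""

    density: dict  # channel name -> (n_segments,) float array

    def channels(self) -> list[str]:
        return list(self.density)


def _profile_values(profile: dict, frac: np.ndarray) -> np.ndarray:
    kind = profile.get("profile", "const")
    if kind == "const":
        return np.full_like(frac, float(profile["value"]))
    lo = float(profile["from"])
    hi = float(profile["to"])
    if kind in ("linear_section", "linear_path"):
        return lo + (hi - lo) * frac
    if kind == "exp_path":
        lo = max(lo, 1e-12)
        return lo * (hi / lo) ** frac
    raise BiophysicsError(f"unknown density profile {kind!r}")


def assign_densities(d: Discretization, t: DensityTable) -> SegmentConductances:
    """Evaluate the density table at every segment centre.

    Every domain present in the discretization must appear in the table
    (possibly with an empty channel dict); a missing domain raises an
    error naming it.  Ramped profiles are evaluated at segment-centre
    positions; the result is deterministic.
    """
    present = set(int(c) for c in np.unique(d.domain_code))
    for code in sorted(present):
        if DOMAINS[code] not in t.table:
            raise BiophysicsError(f"domain {DOMAINS[code]!r} missing from density table")

    soma_end = d.morphology.root.length
    dend_mask = np.isin(d.domain_code, [DOMAIN_CODE["apical_dendrite"], DOMAIN_CODE["basal_dendrite"]])
    max_dend = float(d.path_dist[dend_mask].max()) if dend_mask.any() else soma_end + 1.0
    axon_mask = ~dend_mask & (d.domain_code != DOMAIN_CODE["soma"])
    max_axon = float(d.path_dist[axon_mask].max()) if axon_mask.any() else soma_end + 1.0

    # normalized somatofugal position per segment for path profiles
    path_frac = np.zeros(d.n_segments)
    span_d = max(max_dend - soma_end, 1e-9)
    span_a = max(max_axon - soma_end, 1e-9)
    path_frac[dend_mask] = np.clip((d.path_dist[dend_mask] - soma_end) / span_d, 0, 1)
    path_frac[axon_mask] = np.clip((d.path_dist[axon_mask] - soma_end) / span_a, 0, 1)

    density = {c: np.zeros(d.n_segments) for c in t.channels()}
    for code in sorted(present):
        domain = DOMAINS[code]
        mask = d.domain_code == code
        for chan, profile in t.table[domain].items():
            kind = profile.get("profile", "const")
            frac = d.rel_pos[mask] if kind == "linear_section" else path_frac[mask]
            vals = _profile_values(profile, frac)
            if (vals < 0).any():
                raise BiophysicsError(f"negative density for {chan} in {domain}")
            density[chan][mask] = vals
    return SegmentConductances(density=density)
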