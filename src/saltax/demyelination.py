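"""Demyelination, node-loss, spheroid, and decompaction transforms.

Myelin loss is modelled by neutralizing the sheath: the radial myelin
resistance collapses (R_my -> 1e-6 Ω cm²), the external-layer
capacitance reverts to bare membrane (0.9 µF/cm²), and the periaxonal
resistances become negligible, so the formerly submyelin membrane faces
the extracellular ground directly.  Bared internodal, paranodal and
juxtaparanodal membrane receives a uniform NaV density (default
200 pS/µm², the minimum that supports propagation without ectopic
spiking) and uniform Kv1/Kv7 at 15 pS/µm².  Node loss additionally
reduces nodal NaV to the same bare (internodal) density.  Axonal
spheroids are local diameter bulges; decompaction substitutes a
reduced-lamella sheath.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .biophysics import myelin_params_from_lamellae
from .cable_engine import (
    CableSystem,
    Model,
    SimConfig,
    SimulationError,
    StimulusProtocol,
    run_simulation,
    settle,
)
from .morphology import DOMAIN_CODE, REGION_CODE


class ScenarioError(ValueError):
    pass


@dataclass
class Scenario:
    """A demyelination transform applied to a built model.

    ``regions`` selects where the transform acts; ``remove_myelin``
    bares the sheathed domains there, ``remove_nodes`` additionally
    lowers nodal NaV to the bare internodal density.  ``spheroids`` is a
    list of ``(path position µm, diameter scale, length µm)`` bulges on
    the primary axon; ``decompact`` substitutes a sheath with the given
    (reduced) lamella count instead of removing it.
    """

    regions: tuple = ()
    remove_myelin: bool = False
    remove_nodes: bool = False
    bare_gna: float = 200.0     # pS/µm²
    bare_gkv1: float = 15.0
    bare_gkv7: float = 15.0
    spheroids: list = field(default_factory=list)
    decompact: int | None = None

    def __post_init__(self) -> None:
        for r in self.regions:
            if r not in REGION_CODE:
                raise ScenarioError(f"unknown region {r!r}")
        if min(self.bare_gna, self.bare_gkv1, self.bare_gkv7) < 0:
            raise ScenarioError("bare channel densities must be >= 0")
        for (_, scale, _) in self.spheroids:
            if scale <= 0:
                raise ScenarioError("spheroid diameter scale must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "regions" in raw:
            raw["regions"] = tuple(raw["regions"])
        if "spheroids" in raw:
            raw["spheroids"] = [tuple(s) for s in raw["spheroids"]]
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["regions"] = list(self.regions)
        d["spheroids"] = [list(s) for s in self.spheroids]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


#: named presets; `cpz` mirrors the cuprizone pattern used for the
#: burst-transfer simulations: gray-matter (Ctx + Thal) myelin removed,
#: nodes of Ranvier intact.
PRESETS = {
    "control": Scenario(),
    "cpz": Scenario(regions=("Ctx", "Thal"), remove_myelin=True),
    "ctx_demyel": Scenario(regions=("Ctx",), remove_myelin=True),
    "ctx_demyel_nodeloss": Scenario(
        regions=("Ctx",), remove_myelin=True, remove_nodes=True
    ),
    "wm_demyel": Scenario(regions=("WM",), remove_myelin=True),
}


def preset_scenario(name: str) -> Scenario:
    try:
        return PRESETS[name]
    except KeyError:
        raise ScenarioError(f"unknown preset {name!r}; have {sorted(PRESETS)}")


_SHEATHED = tuple(DOMAIN_CODE[d] for d in ("paranode", "juxtaparanode", "internode"))
_BARE_SPEC = myelin_params_from_lamellae(0)


def apply_scenario(model: Model, s: Scenario) -> Model:
    """Return a transformed copy of ``model``; untouched regions are
    bit-identical.  Application is idempotent (all edits are absolute
    assignments; spheroid diameters are set relative to the section's
    configured diameter, not the current one)."""
    out = model.copy()
    d = out.disc
    region_mask = np.isin(
        d.region_code, [REGION_CODE[r] for r in s.regions]
    ) if s.regions else np.zeros(d.n_segments, dtype=bool)
    sheathed = np.isin(d.domain_code, _SHEATHED)

    dens = out.conductances.density

    def _set(channel: str, mask: np.ndarray, value: float) -> None:
        if channel not in dens:
            dens[channel] = np.zeros(d.n_segments)
        dens[channel][mask] = value

    if s.remove_myelin:
        target = region_mask & sheathed
        for i in np.nonzero(target)[0]:
            out.myelin[i] = _BARE_SPEC
        _set("NaV", target, s.bare_gna)
        _set("KV1", target, s.bare_gkv1)
        _set("KV7", target, s.bare_gkv7)
    elif s.decompact is not None:
        spec = myelin_params_from_lamellae(s.decompact)
        for i in np.nonzero(region_mask & sheathed)[0]:
            out.myelin[i] = spec

    if s.remove_nodes:
        nodes = region_mask & (d.domain_code == DOMAIN_CODE["node"])
        _set("NaV", nodes, s.bare_gna)

    if s.spheroids:
        soma_len = d.morphology.root.length
        axon_len = d.morphology.axon_path_length()
        axonal = d.domain_code != DOMAIN_CODE["soma"]
        axonal &= ~np.isin(
            d.domain_code,
            [DOMAIN_CODE["apical_dendrite"], DOMAIN_CODE["basal_dendrite"]],
        )
        axon_pos = d.path_dist - soma_len
        for (pos, scale, length) in s.spheroids:
            if not (0.0 <= pos <= axon_len):
                raise ScenarioError(
                    f"spheroid position {pos} µm is off the axon (0..{axon_len:.0f})"
                )
            mask = axonal & (np.abs(axon_pos - pos) <= length / 2.0)
            for i in np.nonzero(mask)[0]:
                base = d.morphology[d.section_ids[d.seg_section[i]]].diameter
                d.diam[i] = base * scale
        d.area = np.pi * d.diam * d.length

    return out


def min_gna_search(
    model: Model,
    regions: tuple,
    candidates,
    probe_amp_na: float = 2.0,
    probe_ms: float = 30.0,
    quiet_ms: float = 150.0,
    settle_ms: float = 300.0,
    remove_nodes: bool = False,
) -> float:
    """Smallest bare NaV density enabling propagation without ectopy.

    For each candidate density (ascending) the fully demyelinated
    scenario is applied; the density passes if a single somatic-step
    evoked AP reaches the terminal bouton AND an unstimulated run stays
    silent at every monitored site.  Raises if no candidate satisfies
    both, reporting the boundary behaviour.
    """
    candidates = sorted(float(c) for c in candidates)
    sites = ("ais_end", "bouton") + tuple(
        f"node_{k}" for k in range(1, 200)
        if f"node_{k}" in model.disc.sites
    )[::5]
    last_fail = None
    for cand in candidates:
        scen = Scenario(regions=tuple(regions), remove_myelin=True,
                        remove_nodes=remove_nodes, bare_gna=cand)
        sys = CableSystem(apply_scenario(model, scen))
        try:
            state = settle(sys, duration=settle_ms)
        except SimulationError:
            last_fail = f"{cand}: no stable rest"
            continue
        quiet = run_simulation(
            sys, StimulusProtocol(),
            SimConfig(duration=quiet_ms, record_sites=sites,
                      temperature=sys.temperature),
            init_state=state,
        )
        ectopic = any(len(v) for v in quiet.spikes.values())
        if ectopic:
            last_fail = f"{cand}: ectopic spiking without stimulus"
            continue
        evoked = run_simulation(
            sys,
            StimulusProtocol(step_currents=[("soma", 1.0, 3.0, probe_amp_na)]),
            SimConfig(duration=probe_ms, record_sites=("ais_end", "bouton"),
                      temperature=sys.temperature),
            init_state=state,
        )
        if len(evoked.spikes["ais_end"]) == 0:
            last_fail = f"{cand}: no AP initiated"
            continue
        if len(evoked.spikes["bouton"]) == 0:
            last_fail = f"{cand}: propagation failed before the terminal"
            continue
        return cand
    raise ScenarioError(
        "no candidate density enables propagation without ectopic spiking; "
        f"last failure: {last_fail}"
    )
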