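"""Synthetic morphology of a layer-5 corticothalamic projection neuron.

The model cell is a reduced L5 extra-telencephalic pyramidal neuron whose
primary axon runs ~4.2 mm from the soma in cortex (Ctx), through white
matter (WM), into the thalamus (Thal), ending in a giant presynaptic
bouton on a POm relay cell.  Nine subcellular domains are distinguished
(soma, apical/basal dendrites, AIS, nodes of Ranvier, paranodes,
juxtaparanodes, internodes, collaterals) plus the terminal bouton; each
domain carries its own channel densities and, for internodal stretches,
a myelin sheath.

Sections are unbranched cylinders arranged in a rooted tree (soma is the
root).  Along the primary axon the domain sequence after the AIS is the
repeating unit ``node, paranode, juxtaparanode, internode,
juxtaparanode, paranode`` closed by a final node and the bouton.
Dendrites are equivalent cylinders (one apical trunk + tuft, several
basal sticks) sized to land near the experimentally constrained somatic
input resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

# Domain and region vocabularies.  Order is fixed: integer codes derived
# from these lists are used in the discretization arrays and the SWC
# sidecar mapping.
DOMAINS = (
    "soma",
    "apical_dendrite",
    "basal_dendrite",
    "AIS",
    "node",
    "paranode",
    "juxtaparanode",
    "internode",
    "collateral",
    "bouton",
)
REGIONS = ("Ctx", "WM", "Thal")

DOMAIN_CODE = {name: i for i, name in enumerate(DOMAINS)}
REGION_CODE = {name: i for i, name in enumerate(REGIONS)}

#: domains that belong to the axon proper (carry a path_offset)
AXONAL_DOMAINS = frozenset(
    {"AIS", "node", "paranode", "juxtaparanode", "internode", "bouton", "collateral"}
)

# SWC type codes: 1-4 standard, >=5 custom axonal subdomains.  The
# mapping is also written to the sidecar file next to every SWC export.
SWC_TYPE_OF_DOMAIN = {
    "soma": 1,
    "basal_dendrite": 3,
    "apical_dendrite": 4,
    "AIS": 5,
    "node": 6,
    "paranode": 7,
    "juxtaparanode": 8,
    "internode": 9,
    "collateral": 10,
    "bouton": 11,
}
DOMAIN_OF_SWC_TYPE = {v: k for k, v in SWC_TYPE_OF_DOMAIN.items()}


class MorphologyError(ValueError):
    """Raised when a configuration cannot produce a valid morphology."""


@dataclass
class Section:
    """One unbranched cylinder.

    Parameters
    ----------
    id : str
        Unique section identifier.
    parent_id : str or None
        Identifier of the parent section (``None`` for the soma root).
    domain : str
        One of :data:`DOMAINS`.
    region : str
        One of :data:`REGIONS`; dendrites and soma are assigned ``Ctx``.
    length, diameter : float
        Cylinder dimensions in micrometres (diameter constant per section).
    path_offset : float or None
        For axonal sections, distance in micrometres from the soma along
        the primary axon to the *start* of the section.
    """

    id: str
    parent_id: str | None
    domain: str
    region: str
    length: float
    diameter: float
    path_offset: float | None = None

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_CODE:
            raise MorphologyError(f"unknown domain {self.domain!r}")
        if self.region not in REGION_CODE:
            raise MorphologyError(f"unknown region {self.region!r}")
        if not self.length > 0:
            raise MorphologyError(f"section {self.id}: length must be > 0")
        if not self.diameter > 0:
            raise MorphologyError(f"section {self.id}: diameter must be > 0")

    @property
    def area_um2(self) -> float:
        """Lateral (cylinder side) membrane area in µm²."""
        return math.pi * self.diameter * self.length


@dataclass
class Morphology:
    """A rooted tree of :class:`Section` plus the primary-axon path."""

    sections: list[Section]
    primary_axon_path: list[str]

    def __post_init__(self) -> None:
        self._by_id = {s.id: s for s in self.sections}
        if len(self._by_id) != len(self.sections):
            raise MorphologyError("duplicate section ids")
        roots = [s for s in self.sections if s.parent_id is None]
        if len(roots) != 1 or roots[0].domain != "soma":
            raise MorphologyError("morphology must have exactly one soma root")
        for s in self.sections:
            if s.parent_id is not None and s.parent_id not in self._by_id:
                raise MorphologyError(f"section {s.id}: unknown parent {s.parent_id}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for s in self.sections:
            seen = set()
            cur: Section | None = s
            while cur is not None:
                if cur.id in seen:
                    raise MorphologyError(f"cycle through section {cur.id}")
                seen.add(cur.id)
                cur = self._by_id.get(cur.parent_id) if cur.parent_id else None

    def __getitem__(self, sec_id: str) -> Section:
        return self._by_id[sec_id]

    def __contains__(self, sec_id: str) -> bool:
        return sec_id in self._by_id

    @property
    def root(self) -> Section:
        return next(s for s in self.sections if s.parent_id is None)

    def children_of(self, sec_id: str) -> list[Section]:
        return [s for s in self.sections if s.parent_id == sec_id]

    def axon_path_length(self) -> float:
        """Total primary-axon path length (µm), soma excluded."""
        return sum(self[i].length for i in self.primary_axon_path)

    def axon_domain_sequence(self) -> list[str]:
        return [self[i].domain for i in self.primary_axon_path]


@dataclass
class SegmentationRule:
    """Spatial discretization rule (fraction of the AC length constant).

    Each section is split into the smallest odd number of equal segments
    whose length does not exceed ``d_lambda`` times the length constant
    at ``frequency``.
    """

    d_lambda: float = 0.1
    frequency: float = 2000.0

    def __post_init__(self) -> None:
        if not (0.0 < self.d_lambda <= 1.0):
            raise MorphologyError("d_lambda must be in (0, 1]")
        if not self.frequency > 0:
            raise MorphologyError("frequency must be > 0")


@dataclass
class MorphConfig:
    """Parameters of the synthetic stitched morphology.

    Axonal lengths are per region; the per-region internode lengths are
    nominal -- within each region the internode count is
    ``floor(available / (internode + 15 µm of nodal domains))`` and the
    internode length is then stretched so the region tiles exactly,
    keeping the region boundaries contiguous and the total path length
    on target.
    """

    axon_length_um: float = 4200.0
    region_lengths_um: dict = field(
        default_factory=lambda: {"Ctx": 1200.0, "WM": 1600.0, "Thal": 1400.0}
    )
    diameters_um: dict = field(
        default_factory=lambda: {"Ctx": 0.98, "WM": 1.18, "Thal": 0.98}
    )
    internode_length_um: dict = field(
        default_factory=lambda: {"Ctx": 70.0, "WM": 100.0, "Thal": 70.0}
    )
    node_length_um: float = 1.0
    paranode_length_um: float = 2.0
    juxtaparanode_length_um: float = 5.0
    ais_length_um: float = 45.0
    ais_diameter_um: float = 1.4
    bouton_length_um: float = 4.0
    bouton_diameter_um: float = 4.2
    soma_length_um: float = 25.0
    soma_diameter_um: float = 25.0
    apical_trunk_length_um: float = 620.0
    apical_trunk_diameter_um: float = 5.0
    apical_tuft_length_um: float = 400.0
    apical_tuft_diameter_um: float = 2.5
    n_basal: int = 4
    basal_length_um: float = 150.0
    basal_diameter_um: float = 2.2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "MorphConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _nodal_overhead(cfg: MorphConfig) -> float:
    """Length of the non-internodal part of one repeat unit (µm)."""
    return (
        cfg.node_length_um
        + 2.0 * cfg.paranode_length_um
        + 2.0 * cfg.juxtaparanode_length_um
    )


def count_internodes(available_um: float, internode_um: float, overhead_um: float) -> int:
    """Number of repeat units that tile ``available_um`` at nominal lengths."""
    return int(math.floor(available_um / (internode_um + overhead_um)))


def build_default_morphology(config: MorphConfig | None = None) -> Morphology:
    """Build the stitched L5->POm morphology from a :class:`MorphConfig`.

    The primary axon is AIS followed by per-region repeat units of
    ``node, paranode, juxtaparanode, internode, juxtaparanode,
    paranode`` and, after the last unit, a closing node and the giant
    bouton.  The axon diameter defaults to 0.98 µm in gray matter (Ctx,
    Thal) and 1.18 µm in the white matter.  Deterministic for a fixed
    config.
    """
    cfg = config or MorphConfig()
    overhead = _nodal_overhead(cfg)

    if abs(sum(cfg.region_lengths_um.values()) - cfg.axon_length_um) > 1.0:
        raise MorphologyError(
            "region_lengths_um must sum to axon_length_um "
            f"({sum(cfg.region_lengths_um.values()):.1f} != {cfg.axon_length_um:.1f})"
        )

    sections: list[Section] = []
    sections.append(
        Section("soma", None, "soma", "Ctx", cfg.soma_length_um, cfg.soma_diameter_um)
    )
    # dendritic equivalent cylinders
    sections.append(
        Section(
            "apical_trunk",
            "soma",
            "apical_dendrite",
            "Ctx",
            cfg.apical_trunk_length_um,
            cfg.apical_trunk_diameter_um,
        )
    )
    sections.append(
        Section(
            "apical_tuft",
            "apical_trunk",
            "apical_dendrite",
            "Ctx",
            cfg.apical_tuft_length_um,
            cfg.apical_tuft_diameter_um,
        )
    )
    for i in range(cfg.n_basal):
        sections.append(
            Section(
                f"basal_{i}",
                "soma",
                "basal_dendrite",
                "Ctx",
                cfg.basal_length_um,
                cfg.basal_diameter_um,
            )
        )

    # --- primary axon ----------------------------------------------------
    axon_ids: list[str] = []
    offset = 0.0
    parent = "soma"

    def add_axon(sec_id: str, domain: str, region: str, length: float, diam: float):
        nonlocal offset, parent
        sections.append(Section(sec_id, parent, domain, region, length, diam, offset))
        axon_ids.append(sec_id)
        offset += length
        parent = sec_id

    add_axon("AIS", "AIS", "Ctx", cfg.ais_length_um, cfg.ais_diameter_um)

    counter = 0
    for region in REGIONS:
        reg_len = float(cfg.region_lengths_um[region])
        diam = float(cfg.diameters_um[region])
        il_nom = float(cfg.internode_length_um[region])
        available = reg_len
        if region == "Ctx":
            available -= cfg.ais_length_um
        if region == "Thal":
            available -= cfg.node_length_um + cfg.bouton_length_um
        n_units = count_internodes(available, il_nom, overhead)
        if n_units < 1:
            raise MorphologyError(
                f"region {region}: length {reg_len} µm cannot tile one "
                f"node+paranode+juxtaparanode+internode unit "
                f"({il_nom + overhead:.1f} µm)"
            )
        il_actual = (available - n_units * overhead) / n_units
        for _ in range(n_units):
            counter += 1
            add_axon(f"node_{counter}", "node", region, cfg.node_length_um, diam)
            add_axon(f"para_{counter}a", "paranode", region, cfg.paranode_length_um, diam)
            add_axon(
                f"juxta_{counter}a",
                "juxtaparanode",
                region,
                cfg.juxtaparanode_length_um,
                diam,
            )
            add_axon(f"inter_{counter}", "internode", region, il_actual, diam)
            add_axon(
                f"juxta_{counter}b",
                "juxtaparanode",
                region,
                cfg.juxtaparanode_length_um,
                diam,
            )
            add_axon(f"para_{counter}b", "paranode", region, cfg.paranode_length_um, diam)

    add_axon("node_terminal", "node", "Thal", cfg.node_length_um, cfg.diameters_um["Thal"])
    add_axon("bouton", "bouton", "Thal", cfg.bouton_length_um, cfg.bouton_diameter_um)

    morph = Morphology(sections, axon_ids)
    total = morph.axon_path_length()
    if abs(total - cfg.axon_length_um) > 0.05 * cfg.axon_length_um:
        raise MorphologyError(
            f"axon path length {total:.1f} µm misses target {cfg.axon_length_um} µm by >5%"
        )
    return morph


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


def lambda_f(diameter_um: float, frequency_hz: float, r_i_ohm_cm: float,
             c_m_uf_cm2: float) -> float:
    """Frequency-dependent length constant (µm).

    ``lambda_f = (1/2) sqrt(d / (pi f R_i C_m))`` evaluated in CGS units
    and returned in micrometres.
    """
    d_cm = diameter_um * 1e-4
    c_f = c_m_uf_cm2 * 1e-6
    lam_cm = 0.5 * math.sqrt(d_cm / (math.pi * frequency_hz * r_i_ohm_cm * c_f))
    return lam_cm * 1e4


def nseg_for(length_um: float, diameter_um: float, rule: SegmentationRule,
             r_i_ohm_cm: float, c_m_uf_cm2: float, min_nseg: int = 1) -> int:
    """Smallest odd segment count meeting the d_lambda bound."""
    lam = lambda_f(diameter_um, rule.frequency, r_i_ohm_cm, c_m_uf_cm2)
    n = max(min_nseg, math.ceil(length_um / (rule.d_lambda * lam)))
    return n if n % 2 == 1 else n + 1


@dataclass
class Discretization:
    """Flat segment-level view of a morphology.

    All arrays have one entry per segment; ``parent`` encodes the tree
    (index of the upstream segment, -1 for the root).  ``path_dist`` is
    the distance (µm) from the soma root to the segment centre along the
    tree, used to evaluate distance-parameterized channel-density
    profiles.  ``sites`` maps names (``soma``, ``ais_end``, ``bouton``,
    ``node_<k>``, ``apical_50um`` ...) to segment indices.
    """

    morphology: Morphology
    section_ids: list[str]
    seg_section: np.ndarray  # (n,) int, index into section_ids
    domain_code: np.ndarray  # (n,) int
    region_code: np.ndarray  # (n,) int
    length: np.ndarray       # (n,) µm
    diam: np.ndarray         # (n,) µm
    area: np.ndarray         # (n,) µm²
    path_dist: np.ndarray    # (n,) µm from soma along the tree
    rel_pos: np.ndarray      # (n,) centre position within the section, 0..1
    parent: np.ndarray       # (n,) int
    sites: dict

    @property
    def n_segments(self) -> int:
        return len(self.length)

    def segments_of_section(self, sec_id: str) -> np.ndarray:
        idx = self.section_ids.index(sec_id)
        return np.nonzero(self.seg_section == idx)[0]

    def domain_of(self, seg: int) -> str:
        return DOMAINS[self.domain_code[seg]]


def segmentize(m: Morphology, rule: SegmentationRule, passive) -> Discretization:
    """Discretize a morphology by the d_lambda rule.

    ``passive`` must expose ``r_i`` (Ω cm) and ``c_m`` (µF/cm²); these
    set the length constant used by the rule.  Each section is split
    into an odd number of equal-length segments; segment order within a
    section runs from the proximal (parent) end outward.
    """
    if passive.r_i <= 0 or passive.c_m <= 0:
        raise MorphologyError("passive parameters must be positive")

    # order sections root-first so a parent's segments exist before its
    # children's (Hines ordering of the segment tree)
    ordered: list[Section] = []
    stack = [m.root]
    while stack:
        sec = stack.pop()
        ordered.append(sec)
        stack.extend(reversed(m.children_of(sec.id)))
    section_ids = [s.id for s in ordered]
    sec_index = {sid: i for i, sid in enumerate(section_ids)}

    seg_section, domain_code, region_code = [], [], []
    length, diam, rel_pos, parent = [], [], [], []
    path_dist = []
    last_seg_of_section: dict[str, int] = {}
    dist_to_section_start: dict[str, float] = {}

    n_total = 0
    for sec in ordered:
        # the paranodal seal carries the steepest periaxonal gradients;
        # resolve it with at least 3 segments regardless of d_lambda
        min_nseg = 3 if sec.domain == "paranode" else 1
        n = nseg_for(sec.length, sec.diameter, rule, passive.r_i, passive.c_m,
                     min_nseg=min_nseg)
        seg_len = sec.length / n
        if sec.parent_id is None:
            start_dist = 0.0
            parent_seg = -1
        else:
            start_dist = (
                dist_to_section_start[sec.parent_id] + m[sec.parent_id].length
            )
            parent_seg = last_seg_of_section[sec.parent_id]
        dist_to_section_start[sec.id] = start_dist
        for k in range(n):
            seg_section.append(sec_index[sec.id])
            domain_code.append(DOMAIN_CODE[sec.domain])
            region_code.append(REGION_CODE[sec.region])
            length.append(seg_len)
            diam.append(sec.diameter)
            rel_pos.append((k + 0.5) / n)
            path_dist.append(start_dist + (k + 0.5) * seg_len)
            parent.append(parent_seg if k == 0 else n_total + k - 1)
        last_seg_of_section[sec.id] = n_total + n - 1
        n_total += n

    length = np.asarray(length)
    diam = np.asarray(diam)
    d = Discretization(
        morphology=m,
        section_ids=section_ids,
        seg_section=np.asarray(seg_section, dtype=np.int64),
        domain_code=np.asarray(domain_code, dtype=np.int64),
        region_code=np.asarray(region_code, dtype=np.int64),
        length=length,
        diam=diam,
        area=np.pi * diam * length,
        path_dist=np.asarray(path_dist),
        rel_pos=np.asarray(rel_pos),
        parent=np.asarray(parent, dtype=np.int64),
        sites={},
    )
    d.sites = _named_sites(d)
    return d


def _named_sites(d: Discretization) -> dict:
    sites: dict[str, int] = {}
    m = d.morphology
    soma_segs = d.segments_of_section(m.root.id)
    sites["soma"] = int(soma_segs[len(soma_segs) // 2])
    if "AIS" in m:
        sites["ais_end"] = int(d.segments_of_section("AIS")[-1])
    node_no = 0
    for sid in m.primary_axon_path:
        sec = m[sid]
        if sec.domain == "node":
            node_no += 1
            sites[f"node_{node_no}"] = int(d.segments_of_section(sid)[0])
        elif sec.domain == "bouton":
            sites["bouton"] = int(d.segments_of_section(sid)[-1])
    # apical site for the fluctuating-conductance input (~50 µm from soma)
    apical = np.nonzero(d.domain_code == DOMAIN_CODE["apical_dendrite"])[0]
    if len(apical):
        soma_len = m.root.length
        target = soma_len + 50.0
        sites["apical_50um"] = int(apical[np.argmin(np.abs(d.path_dist[apical] - target))])
    return sites


# ---------------------------------------------------------------------------
# SWC input/output
# ---------------------------------------------------------------------------


def write_swc(m: Morphology, path) -> None:
    """Write a morphology as standard 7-column SWC plus a sidecar map.

    Every section is emitted as one point at its distal end whose parent
    is the distal point of the parent section; the soma root is emitted
    as two type-1 points (proximal anchor + distal end) so its length
    survives the round trip.  Domain/region labels ride on the SWC type
    field via the sidecar YAML written to ``<path>.map.yaml``.
    """
    path = str(path)
    lines = ["# saltax SWC export", "# index type x y z radius parent"]
    point_of_section: dict[str, int] = {}
    region_of_point: dict[int, str] = {}
    idx = 0

    # simple deterministic layout: axon along -y, apical +y, basals +x
    pos: dict[str, np.ndarray] = {}

    def emit(ptype, xyz, radius, parent_pt):
        nonlocal idx
        idx += 1
        lines.append(
            f"{idx} {ptype} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f} "
            f"{radius:.6f} {parent_pt}"
        )
        return idx

    root = m.root
    anchor = emit(1, (0.0, 0.0, 0.0), root.diameter / 2.0, -1)
    region_of_point[anchor] = root.region
    end = emit(1, (0.0, root.length, 0.0), root.diameter / 2.0, anchor)
    region_of_point[end] = root.region
    point_of_section[root.id] = end
    pos[root.id] = np.array([0.0, root.length, 0.0])

    order = [s for s in m.sections if s.parent_id is not None]
    # direction bookkeeping: children extend along a per-branch direction
    direction = {root.id: np.array([0.0, 1.0, 0.0])}
    basal_count = 0
    for sec in order:
        parent_pos = pos[sec.parent_id]
        if sec.domain in AXONAL_DOMAINS:
            dvec = np.array([0.0, -1.0, 0.0])
        elif sec.domain == "apical_dendrite":
            dvec = np.array([0.0, 1.0, 0.0])
        else:
            basal_count += 1
            ang = 2.0 * math.pi * basal_count / max(1, len(m.children_of("soma")))
            dvec = np.array([math.cos(ang), 0.0, math.sin(ang)])
        xyz = parent_pos + dvec * sec.length
        pt = emit(
            SWC_TYPE_OF_DOMAIN[sec.domain], xyz, sec.diameter / 2.0,
            point_of_section[sec.parent_id],
        )
        region_of_point[pt] = sec.region
        point_of_section[sec.id] = pt
        pos[sec.id] = xyz
        direction[sec.id] = dvec

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    sidecar = {
        "type_to_domain": {int(k): v for k, v in DOMAIN_OF_SWC_TYPE.items()},
        "region_of_point": {int(k): v for k, v in region_of_point.items()},
        "primary_axon_path": list(m.primary_axon_path),
        "section_of_point": {
            int(point_of_section[sid]): sid for sid in point_of_section
        },
    }
    with open(path + ".map.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


class SWCParseError(ValueError):
    pass


def read_swc(path) -> Morphology:
    """Read an SWC file (with optional sidecar mapping) into a Morphology.

    Without a sidecar, standard type codes 1-4 map to soma/dendrites and
    codes >=5 to the custom axonal subdomains; regions default to Ctx.
    A leading chain of type-1 points is merged into the soma section; a
    single-point soma is read with the spherical convention
    (length = diameter).
    """
    path = str(path)
    points: dict[int, tuple] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 7:
                raise SWCParseError(f"{path}:{lineno}: expected 7 columns")
            try:
                pid = int(parts[0]); ptype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"{path}:{lineno}: {exc}") from None
            if parent != -1 and parent not in points:
                raise SWCParseError(
                    f"{path}:{lineno}: parent {parent} not yet defined"
                )
            if ptype not in DOMAIN_OF_SWC_TYPE:
                raise SWCParseError(f"{path}:{lineno}: unknown type code {ptype}")
            points[pid] = (ptype, np.array([x, y, z]), r, parent)
            order.append(pid)

    if not order:
        raise SWCParseError(f"{path}: empty file")

    sidecar: dict = {}
    try:
        with open(path + ".map.yaml") as fh:
            sidecar = yaml.safe_load(fh) or {}
    except FileNotFoundError:
        pass
    region_of_point = sidecar.get("region_of_point", {})
    section_of_point = sidecar.get("section_of_point", {})

    roots = [pid for pid in order if points[pid][3] == -1]
    if len(roots) != 1:
        raise SWCParseError(f"{path}: expected exactly one root point")
    root_pid = roots[0]
    if points[root_pid][0] != 1:
        raise SWCParseError(f"{path}: root point must be type 1 (soma)")

    # merge the leading chain of type-1 points into one soma section
    soma_chain = [root_pid]
    cur = root_pid
    while True:
        kids = [p for p in order if points[p][3] == cur and points[p][0] == 1]
        if len(kids) == 1 and all(
            points[p][0] != 1 for p in order if points[p][3] == cur and p != kids[0]
        ):
            soma_chain.append(kids[0])
            cur = kids[0]
        else:
            break
    soma_r = points[root_pid][2]
    if len(soma_chain) == 1:
        soma_len = 2.0 * soma_r
    else:
        soma_len = sum(
            float(np.linalg.norm(points[b][1] - points[a][1]))
            for a, b in zip(soma_chain, soma_chain[1:])
        )
    soma_id = section_of_point.get(soma_chain[-1], "soma")
    sections = [Section(soma_id, None, "soma", "Ctx", soma_len, 2.0 * soma_r)]
    section_of: dict[int, str] = {p: soma_id for p in soma_chain}

    n_anon = 0
    for pid in order:
        if pid in soma_chain:
            continue
        ptype, xyz, r, parent = points[pid]
        plen = float(np.linalg.norm(xyz - points[parent][1]))
        if plen <= 0:
            plen = 1e-6
        domain = DOMAIN_OF_SWC_TYPE[ptype]
        region = region_of_point.get(pid, "Ctx")
        sid = section_of_point.get(pid)
        if sid is None:
            n_anon += 1
            sid = f"swc_{pid}"
        sections.append(
            Section(sid, section_of[parent], domain, region, plen, 2.0 * r)
        )
        section_of[pid] = sid

    axon_path = sidecar.get("primary_axon_path")
    if axon_path is None:
        # reconstruct: follow AIS chain from soma through axonal domains
        by_id = {s.id: s for s in sections}
        children: dict[str, list[str]] = {}
        for s in sections:
            if s.parent_id:
                children.setdefault(s.parent_id, []).append(s.id)
        axon_path = []
        frontier = [c for c in children.get(soma_id, []) if by_id[c].domain in AXONAL_DOMAINS]
        while frontier:
            sid = frontier[0]
            axon_path.append(sid)
            frontier = [
                c for c in children.get(sid, []) if by_id[c].domain in AXONAL_DOMAINS
            ]
    return Morphology(sections, list(axon_path))
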