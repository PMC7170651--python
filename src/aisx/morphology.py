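"""Neuron morphologies: branched trees of cylindrical sections + spherical soma.

The spherical soma is a single isopotential compartment (area π·dS²)
attached to the proximal end of its child sections; axial coupling to a
child is through the child's first half-compartment only.  Cylindrical
sections are discretized into equal compartments of at most ``dx_um``.

Builders construct the three model families used throughout:

* :func:`build_biophysical_neuron` — soma 30 µm, dendrite 6 µm × 1 mm,
  axon 1 µm × 500 µm, AIS from 5 to 35 µm with high Nav/Kv1 density
  (plus morphology variants: thick axon with rescaled soma, long axon,
  myelinated distal axon, distal branching, axon-bearing dendrite).
* :func:`build_simplified_neuron` — 50 µm soma, passive 1 µm × 300 µm
  axon, a point Nav conductance at a chosen position.
* :func:`build_passive_neuron` — soma + passive 2 mm axon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .channels import ChannelSpec, GatingVariable, simplified_nav, standard_channel_set, x_inf
from .passive import PassiveMembrane

__all__ = [
    "Section",
    "PointChannel",
    "NeuronModel",
    "DiscretizedNeuron",
    "build_biophysical_neuron",
    "build_simplified_neuron",
    "build_passive_neuron",
    "discretize",
]

# region label fallbacks for channel density lookup: distal-AIS compartments
# carry the AIS densities unless a channel targets them specifically
_REGION_FALLBACK = {"ais_distal": "ais"}


@dataclass(frozen=True)
class Section:
    """A cylindrical section of the tree.

    ``parent`` is the name of the parent section or ``"soma"``; children
    attach to the distal end of their parent.  ``region`` selects the
    channel densities; ``rm_factor``/``cm_factor`` scale the passive
    membrane locally (myelin: rm_factor=4, cm_factor=0.25).
    """

    name: str
    parent: str
    length_um: float
    diameter_um: float
    region: str
    dx_um: float = 10.0
    rm_factor: float = 1.0
    cm_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.diameter_um <= 0 or self.dx_um <= 0:
            raise ValueError("section length, diameter and dx must be positive")


@dataclass(frozen=True)
class PointChannel:
    """A channel with a fixed total conductance at a single location."""

    channel: ChannelSpec
    section: str
    x_um: float
    G_nS: float


@dataclass
class NeuronModel:
    soma_diameter_um: float
    sections: list[Section]
    membrane: PassiveMembrane
    channels: dict[str, ChannelSpec] = field(default_factory=dict)
    point_channels: list[PointChannel] = field(default_factory=list)
    soma_extra_leak_S_m2: float = 0.0

    def __post_init__(self) -> None:
        names = {"soma"} | {s.name for s in self.sections}
        if len(names) != len(self.sections) + 1:
            raise ValueError("section names must be unique")
        for s in self.sections:
            if s.parent not in names or s.parent == s.name:
                raise ValueError(f"section {s.name!r} has unknown parent {s.parent!r}")


class IntegrationError(RuntimeError):
    pass


@dataclass
class DiscretizedNeuron:
    """Compartmental arrays in Hines order (soma = compartment 0)."""

    model: NeuronModel
    N: int
    parent: np.ndarray  # int32[N], parent[0] = -1
    off: np.ndarray  # µS coupling to parent, off[0] = 0
    offsum: np.ndarray  # off[i] + sum over children
    cap: np.ndarray  # nF
    gl: np.ndarray  # µS
    el: np.ndarray  # mV
    area: np.ndarray  # µm²
    comp_section: list[str]
    comp_x: np.ndarray  # µm, center position within section (0 for soma)
    # channel metadata
    chan_names: list[str]
    erev: np.ndarray  # float64[nc]
    gmax: np.ndarray  # µS, float64[nc, N]
    gate_names: list[str]
    chan_of: np.ndarray  # int32[ng]
    powr: np.ndarray  # int32[ng]
    inact: np.ndarray  # bool_[ng]
    ftau: np.ndarray  # bool_[ng]
    vh: np.ndarray  # float64[ng]
    kk: np.ndarray
    taus: np.ndarray

    def locate(self, section: str, x_um: float = 0.0) -> int:
        """Index of the compartment of ``section`` containing position x."""
        if section == "soma":
            return 0
        idx = [i for i, s in enumerate(self.comp_section) if s == section]
        if not idx:
            raise KeyError(f"unknown section {section!r}")
        centers = self.comp_x[idx]
        return idx[int(np.argmin(np.abs(centers - x_um)))]

    def locate_distance(self, dist_um: float, *, path: tuple[str, ...]) -> int:
        """Compartment at a path distance from the soma along named sections."""
        acc = 0.0
        sec_by_name = {s.name: s for s in self.model.sections}
        for name in path:
            sec = sec_by_name[name]
            if dist_um <= acc + sec.length_um or name == path[-1]:
                return self.locate(name, min(dist_um - acc, sec.length_um))
            acc += sec.length_um
        raise ValueError("distance beyond path")  # pragma: no cover

    def resting_gates(self, V0: float) -> np.ndarray:
        """Gate states equilibrated at a uniform voltage V0."""
        x = np.empty((len(self.gate_names), self.N))
        for g in range(len(self.gate_names)):
            gv = GatingVariable(
                name=self.gate_names[g],
                V_half=self.vh[g],
                k_slope=self.kk[g],
                tau_star=self.taus[g],
                exponent=int(self.powr[g]),
                is_inactivation=bool(self.inact[g]),
                fixed_tau=bool(self.ftau[g]),
            )
            x[g, :] = x_inf(gv, V0)
        return x


def _ra_MOhm_per_um(mem: PassiveMembrane, d_um: float) -> float:
    return 4.0 * mem.Ri / (math.pi * d_um**2) * 1e-2


def discretize(model: NeuronModel) -> DiscretizedNeuron:
    """Build the compartmental arrays for a model."""
    mem = model.membrane
    parent: list[int] = [-1]
    rhalf: list[float] = [0.0]  # MΩ, half axial resistance of the compartment
    area: list[float] = [math.pi * model.soma_diameter_um**2]
    comp_section: list[str] = ["soma"]
    comp_x: list[float] = [0.0]
    region: list[str] = ["soma"]
    rm_fac: list[float] = [1.0]
    cm_fac: list[float] = [1.0]
    last_comp: dict[str, int] = {"soma": 0}

    for sec in model.sections:
        n = max(1, int(round(sec.length_um / sec.dx_um)))
        dx = sec.length_um / n
        ra = _ra_MOhm_per_um(mem, sec.diameter_um)
        for j in range(n):
            idx = len(parent)
            parent.append(last_comp[sec.parent] if j == 0 else idx - 1)
            rhalf.append(ra * dx / 2.0)
            area.append(math.pi * sec.diameter_um * dx)
            comp_section.append(sec.name)
            comp_x.append((j + 0.5) * dx)
            region.append(sec.region)
            rm_fac.append(sec.rm_factor)
            cm_fac.append(sec.cm_factor)
        last_comp[sec.name] = len(parent) - 1

    N = len(parent)
    parent_a = np.asarray(parent, dtype=np.int32)
    area_a = np.asarray(area)
    off = np.zeros(N)
    for i in range(1, N):
        off[i] = 1.0 / (rhalf[i] + rhalf[parent_a[i]])
    offsum = off.copy()
    for i in range(1, N):
        offsum[parent_a[i]] += off[i]

    cap = mem.Cm * np.asarray(cm_fac) * area_a * 1e-5  # nF
    gl = area_a / (mem.Rm * np.asarray(rm_fac)) * 1e-2  # µS
    if model.soma_extra_leak_S_m2:
        gl[0] += model.soma_extra_leak_S_m2 * area_a[0] * 1e-6
    el = np.full(N, mem.EL)

    # channels: distributed densities then point channels
    chan_names: list[str] = []
    erev: list[float] = []
    gmax_rows: list[np.ndarray] = []
    gates: list[tuple[int, GatingVariable]] = []

    def _add_channel(spec: ChannelSpec, row: np.ndarray) -> None:
        c = len(chan_names)
        chan_names.append(spec.name)
        erev.append(spec.E_rev)
        gmax_rows.append(row)
        for gv in spec.gates:
            gates.append((c, gv))

    for spec in model.channels.values():
        row = np.zeros(N)
        for i in range(N):
            reg = region[i]
            dens = spec.density_map.get(reg)
            if dens is None and reg in _REGION_FALLBACK:
                dens = spec.density_map.get(_REGION_FALLBACK[reg])
            if dens:
                row[i] = dens * area_a[i] * 1e-6  # S/m² × µm² → µS
        _add_channel(spec, row)

    disc_sections = {s.name for s in model.sections}
    for pc in model.point_channels:
        if pc.section not in disc_sections:
            raise ValueError(f"point channel on unknown section {pc.section!r}")
        row = np.zeros(N)
        # locate below needs comp_section; compute directly here
        idxs = [i for i in range(N) if comp_section[i] == pc.section]
        centers = np.asarray([comp_x[i] for i in idxs])
        row[idxs[int(np.argmin(np.abs(centers - pc.x_um)))]] = pc.G_nS * 1e-3
        _add_channel(pc.channel, row)

    ng = len(gates)
    return DiscretizedNeuron(
        model=model,
        N=N,
        parent=parent_a,
        off=off,
        offsum=offsum,
        cap=cap,
        gl=gl,
        el=el,
        area=area_a,
        comp_section=comp_section,
        comp_x=np.asarray(comp_x),
        chan_names=chan_names,
        erev=np.asarray(erev, dtype=float),
        gmax=np.ascontiguousarray(np.vstack(gmax_rows)) if chan_names else np.zeros((0, N)),
        gate_names=[gv.name for _, gv in gates],
        chan_of=np.asarray([c for c, _ in gates], dtype=np.int32),
        powr=np.asarray([gv.exponent for _, gv in gates], dtype=np.int32),
        inact=np.asarray([gv.is_inactivation for _, gv in gates], dtype=np.bool_),
        ftau=np.asarray([gv.fixed_tau for _, gv in gates], dtype=np.bool_),
        vh=np.asarray([gv.V_half for _, gv in gates], dtype=float),
        kk=np.asarray([gv.k_slope for _, gv in gates], dtype=float),
        taus=np.asarray([gv.tau_star for _, gv in gates], dtype=float),
    )


# --- builders ---------------------------------------------------------------

_BIOPHYS_KEYS = {
    "ais_start",
    "ais_length",
    "g_na_ais",
    "g_k_ais",
    "g_kv7_distal_ais",
    "kv7_kinetic",
    "axon_diameter",
    "axon_length",
    "soma_diameter",
    "dendrite_diameter",
    "dendrite_length",
    "myelinated_distal",
    "branch_exponent",
    "axon_bearing_dendrite",
    "point_ais_G_nS",
    "soma_extra_leak_S_m2",
    "dx_proximal",
    "dx_distal",
    "membrane",
}


def build_biophysical_neuron(**overrides) -> NeuronModel:
    """The biophysical model: soma + dendrite + axon with an AIS.

    Defaults: 30 µm soma, 6 µm × 1000 µm dendrite, 1 µm × 500 µm
    unmyelinated axon, AIS from 5 to 35 µm with g_Na = 3500 S/m² and
    g_Kv1 = 1500 S/m²; background Nav/Kv1 densities elsewhere.

    Variants via overrides: ``axon_diameter`` (with the soma rescaled by
    the caller, e.g. via the dS ∝ d^{3/4} electrical-equivalence rule),
    ``axon_length``, ``myelinated_distal`` (Rm ×4, Cm /4 beyond the
    AIS), ``branch_exponent`` p (distal bifurcation with
    d_main^p = d1^p + d2^p), ``axon_bearing_dendrite`` (2 µm stem
    splitting per the 3/2 law, one branch carrying the axon),
    ``point_ais_G_nS`` (replace the extended AIS by a point conductance
    of that total at ``ais_start``), ``g_kv7_distal_ais`` (static or
    kinetic hyperpolarizing conductance on the distal half of the AIS),
    ``soma_extra_leak_S_m2`` (added somatic leak).
    """
    unknown = set(overrides) - _BIOPHYS_KEYS
    if unknown:
        raise ValueError(f"unknown override keys: {sorted(unknown)}")
    p = {
        "ais_start": 5.0,
        "ais_length": 30.0,
        "g_na_ais": 3500.0,
        "g_k_ais": 1500.0,
        "g_kv7_distal_ais": 0.0,
        "kv7_kinetic": False,
        "axon_diameter": 1.0,
        "axon_length": 500.0,
        "soma_diameter": 30.0,
        "dendrite_diameter": 6.0,
        "dendrite_length": 1000.0,
        "myelinated_distal": False,
        "branch_exponent": None,
        "axon_bearing_dendrite": False,
        "point_ais_G_nS": None,
        "soma_extra_leak_S_m2": 0.0,
        "dx_proximal": 1.0,
        "dx_distal": 10.0,
        "membrane": PassiveMembrane(),
    }
    p.update(overrides)
    mem = p["membrane"]
    delta, L = p["ais_start"], p["ais_length"]
    d_ax = p["axon_diameter"]
    ais_end = delta + L
    if ais_end > p["axon_length"]:
        raise ValueError("AIS must lie within the axon")
    dxp, dxd = p["dx_proximal"], p["dx_distal"]

    sections: list[Section] = [
        Section("dendrite", "soma", p["dendrite_length"], p["dendrite_diameter"],
                "dendrite", dx_um=dxd),
    ]
    point_channels: list[PointChannel] = []

    axon_parent = "soma"
    prox_offset = 0.0
    if p["axon_bearing_dendrite"]:
        # 2 µm stem splits after 7 µm into two equal branches (Rall 3/2);
        # one branch carries the axon and its AIS.
        d_branch = 2.0 * 2.0 ** (-2.0 / 3.0)
        sections += [
            Section("stem", "soma", 7.0, 2.0, "axon", dx_um=dxp),
            Section("sister", "stem", 300.0, d_branch, "axon", dx_um=dxd),
        ]
        axon_parent = "stem"
        d_ax = d_branch if "axon_diameter" not in overrides else d_ax

    if p["point_ais_G_nS"] is not None:
        # uniform axon with a point AIS: no high-density section
        prox_len = max(ais_end + 5.0, 60.0)
        sections += [
            Section("axon", axon_parent, prox_len, d_ax, "axon", dx_um=dxp),
        ]
        _append_distal(sections, p, "axon", prox_len, d_ax, dxd)
        chans = standard_channel_set(g_na_ais=0.0, g_k_ais=p["g_k_ais"])
        chans.pop("Nav_AIS")
        nav_ais = standard_channel_set()["Nav_AIS"]
        point_channels.append(
            PointChannel(nav_ais, "axon", p["ais_start"], p["point_ais_G_nS"])
        )
    else:
        if delta > 0:
            sections.append(
                Section("axon_pre", axon_parent, delta, d_ax, "axon", dx_um=dxp)
            )
            ais_parent = "axon_pre"
        else:
            ais_parent = axon_parent
        sections += [
            Section("ais", ais_parent, L / 2.0, d_ax, "ais", dx_um=dxp),
            Section("ais_distal", "ais", L / 2.0, d_ax, "ais_distal", dx_um=dxp),
        ]
        # myelin (when present) wraps the axon from the AIS end onward
        rm_f = 4.0 if p["myelinated_distal"] else 1.0
        cm_f = 0.25 if p["myelinated_distal"] else 1.0
        post_len = min(100.0, p["axon_length"]) - ais_end
        post_parent = "ais_distal"
        if post_len > 0:
            sections.append(
                Section("axon_post", post_parent, post_len, d_ax, "axon", dx_um=dxp,
                        rm_factor=rm_f, cm_factor=cm_f)
            )
            post_parent = "axon_post"
        _append_distal(sections, p, post_parent, max(ais_end, 100.0), d_ax, dxd)
        chans = standard_channel_set(
            g_na_ais=p["g_na_ais"],
            g_k_ais=p["g_k_ais"],
            g_kv7_distal_ais=p["g_kv7_distal_ais"],
            kv7_kinetic=p["kv7_kinetic"],
        )

    return NeuronModel(
        soma_diameter_um=p["soma_diameter"],
        sections=sections,
        membrane=mem,
        channels=chans,
        point_channels=point_channels,
        soma_extra_leak_S_m2=p["soma_extra_leak_S_m2"],
    )


def _append_distal(sections, p, parent, start_um, d_ax, dxd):
    """Distal axon beyond ``start_um``: plain, myelinated, or branched."""
    remaining = p["axon_length"] - start_um
    if remaining <= 0:
        return
    rm_f = 4.0 if p["myelinated_distal"] else 1.0
    cm_f = 0.25 if p["myelinated_distal"] else 1.0
    if p["branch_exponent"] is not None:
        pexp = p["branch_exponent"]
        d_child = d_ax * 2.0 ** (-1.0 / pexp)
        half = remaining / 2.0
        sections += [
            Section("axon_distal", parent, half, d_ax, "axon", dx_um=dxd,
                    rm_factor=rm_f, cm_factor=cm_f),
            Section("branch1", "axon_distal", half, d_child, "axon", dx_um=dxd,
                    rm_factor=rm_f, cm_factor=cm_f),
            Section("branch2", "axon_distal", half, d_child, "axon", dx_um=dxd,
                    rm_factor=rm_f, cm_factor=cm_f),
        ]
    else:
        sections.append(
            Section("axon_distal", parent, remaining, d_ax, "axon", dx_um=dxd,
                    rm_factor=rm_f, cm_factor=cm_f)
        )


def build_simplified_neuron(
    *,
    ais_position_um: float = 20.0,
    G_nS: float = 350.0,
    soma_diameter_um: float = 50.0,
    axon_length_um: float = 300.0,
    axon_diameter_um: float = 1.0,
    dx_um: float = 1.0,
    membrane: PassiveMembrane | None = None,
) -> NeuronModel:
    """Reduced model: passive soma + axon, point Nav at one position.

    The Nav channel has a single non-inactivating activation gate with
    fixed τm = 53.6 µs, V₁/₂ = −35 mV, k = 5 mV, E_Na = 70 mV, and a
    total conductance G (typically 200–600 nS).  There are no K⁺
    channels; everything else is passive.
    """
    mem = membrane or PassiveMembrane()
    sections = [
        Section("axon", "soma", axon_length_um, axon_diameter_um, "axon", dx_um=dx_um)
    ]
    return NeuronModel(
        soma_diameter_um=soma_diameter_um,
        sections=sections,
        membrane=mem,
        channels={},
        point_channels=[
            PointChannel(simplified_nav(), "axon", ais_position_um, G_nS)
        ],
    )


def build_passive_neuron(
    soma_diameter_um: float = 100.0,
    axon_length_um: float = 2000.0,
    *,
    axon_diameter_um: float = 1.0,
    dx_um: float = 2.0,
    membrane: PassiveMembrane | None = None,
) -> NeuronModel:
    """Purely passive soma + axon model (small soma: 1 µm; large: 100 µm)."""
    mem = membrane or PassiveMembrane()
    sections = [
        Section("axon", "soma", axon_length_um, axon_diameter_um, "axon", dx_um=dx_um)
    ]
    return NeuronModel(
        soma_diameter_um=soma_diameter_um,
        sections=sections,
        membrane=mem,
    )
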