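"""Connectome of the four-limb spinal locomotor network.

The network consists of four cord sections (fore/hind girdle x left/right
side).  Each section contains a rhythm generator (RG) made of a flexor
(RG-F) and an extensor (RG-E) half-center, local inhibitory interneurons,
commissural interneurons (CINs: V0D, V0V with its V2a relay and IniV0V
target, V3, CINi) coupling the left and right sections of a girdle, and
long propriospinal neurons (LPNs: Sh2-Hom, Ini-Hom, V0D-diag, V0V-diag
with its V2a-diag relay) coupling the cervical (fore) and lumbar (hind)
girdles homolaterally and diagonally.  Inhibitory LPNs (Ini-Hom and
V0D-diag) are descending only, i.e. they exist only in fore sections.

This module builds the canonical intact network, applies population
deletions (output clamps) and random weight perturbations, and compiles
the network into flat arrays for the ODE right-hand side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .dynamics import CellConstants

GIRDLES = ("fore", "hind")
SIDES = ("left", "right")

#: population names present in every section
SECTION_POPULATIONS = (
    "RG-F", "RG-E", "Ini-F", "Ini-E",
    "V0D", "V2a", "V0V", "IniV0V", "V3", "CINi",
    "V2a-diag", "V0V-diag", "Sh2-Hom",
)
#: descending-only populations, present in fore sections only
FORE_ONLY_POPULATIONS = ("Ini-Hom", "V0D-diag")

RHYTHMOGENIC = ("RG-F", "RG-E")

# (source, target, weight) within one section; "fore" rows only exist in
# fore sections because their targets do.
_WITHIN_SECTION = (
    ("RG-F", "Ini-F", 0.40),
    ("RG-F", "V0D", 0.70),
    ("RG-F", "V2a", 1.00),
    ("RG-F", "V3", 0.35),
    ("RG-F", "V2a-diag", 0.50),
    ("RG-E", "Ini-E", 0.40),
    ("RG-E", "CINi", 0.40),
    ("RG-E", "Sh2-Hom", 0.50),
    ("Ini-F", "RG-E", -1.00),
    ("Ini-E", "RG-F", -0.08),
    ("V2a", "V0V", 1.00),
    ("V2a-diag", "V0V-diag", 0.90),
    ("IniV0V", "RG-F", -0.07),
)
_WITHIN_FORE_SECTION = (
    ("RG-F", "Ini-Hom", 0.70),
    ("RG-F", "V0D-diag", 0.50),
)
# source in one section -> target in the contralateral section, same girdle
_COMMISSURAL = (
    ("V0D", "RG-F", -0.07),
    ("V0V", "IniV0V", 0.60),
    ("V3", "RG-F", 0.03),
    ("CINi", "RG-F", -0.03),
)
# (source girdle, source, target, weight): same side, other girdle
_HOMOLATERAL = (
    ("fore", "Ini-Hom", "RG-F", -0.01),
    ("fore", "Sh2-Hom", "RG-F", 0.01),
    ("hind", "Sh2-Hom", "RG-F", 0.125),
)
# (source girdle, source, target, weight): other side, other girdle
_DIAGONAL = (
    ("fore", "V0D-diag", "RG-F", -0.075),
    ("fore", "V0V-diag", "RG-F", 0.02),
    ("hind", "V0V-diag", "RG-F", 0.065),
)

# brainstem drive coefficients (slope m, intercept b) keyed by population
# name; "E" = excitatory drive, "I" = inhibitory drive.  The extensor
# half-centers receive constant excitation, the flexor half-centers
# alpha-proportional excitation; the local V0D CINs, the descending
# diagonal V0D LPNs and the local V0V CINs receive alpha-proportional
# inhibition that weakens left-right/diagonal alternation with speed.
_DRIVE_E = {"RG-E": (0.0, 0.1), "RG-F": (0.1, 0.0)}
_DRIVE_I = {"V0D": (0.75, 0.0), "V0D-diag": (0.75, 0.0), "V0V": (0.15, 0.0)}

_GL_RG, _GL_OTHER = 4.5, 2.8          # leak conductance, nS
_EL_RG, _EL_OTHER = -62.5, -60.0      # leak reversal, mV
_CAPACITANCE = 10.0                   # pF


def population_id(girdle: str, side: str, name: str) -> str:
    """Canonical section-qualified identifier, e.g. ``fore-left-RG-F``."""
    return f"{girdle}-{side}-{name}"


@dataclass(frozen=True)
class PopulationSpec:
    """One neural population: location, intrinsic and drive parameters."""

    name: str
    girdle: str
    side: str
    rhythmogenic: bool
    C: float = _CAPACITANCE
    gL: float = _GL_OTHER
    EL: float = _EL_OTHER
    drive_E: tuple[float, float] = (0.0, 0.0)
    drive_I: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.girdle not in GIRDLES:
            raise ValueError(f"unknown girdle {self.girdle!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.rhythmogenic != (self.name in RHYTHMOGENIC):
            raise ValueError(
                f"{self.name}: rhythmogenic flag must hold exactly for "
                f"{RHYTHMOGENIC}")
        if self.name in FORE_ONLY_POPULATIONS and self.girdle != "fore":
            raise ValueError(f"{self.name} exists only in fore sections")

    @property
    def id(self) -> str:
        return population_id(self.girdle, self.side, self.name)


@dataclass(frozen=True)
class ConnectionSpec:
    """A directed synaptic connection with signed dimensionless weight."""

    source: str
    target: str
    weight: float


@dataclass(frozen=True)
class NetworkSpec:
    """Populations + connections + set of output-clamped ("deleted") ids.

    Deleted populations stay in the state vector and are still
    integrated; only their output f(V) is forced to zero in downstream
    synaptic sums.
    """

    populations: tuple[PopulationSpec, ...]
    connections: tuple[ConnectionSpec, ...]
    deleted: frozenset[str] = field(default_factory=frozenset)
    constants: CellConstants = field(default_factory=CellConstants)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate population ids")
        known = set(ids)
        for c in self.connections:
            for end in (c.source, c.target):
                if end not in known:
                    raise ValueError(f"connection references unknown {end!r}")
        unknown = self.deleted - known
        if unknown:
            raise ValueError(f"deleted set references unknown {sorted(unknown)}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self.populations)

    def index_of(self, pop_id: str) -> int:
        try:
            return self.ids.index(pop_id)
        except ValueError:
            raise KeyError(pop_id) from None

    def population(self, pop_id: str) -> PopulationSpec:
        return self.populations[self.index_of(pop_id)]

    def weight(self, source: str, target: str) -> float:
        """Weight of the source->target connection (0.0 if absent)."""
        for c in self.connections:
            if c.source == source and c.target == target:
                return c.weight
        return 0.0

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "populations": [
                {
                    "name": p.name, "girdle": p.girdle, "side": p.side,
                    "rhythmogenic": p.rhythmogenic, "C": p.C,
                    "gL": p.gL, "EL": p.EL,
                    "drive_E": list(p.drive_E), "drive_I": list(p.drive_I),
                }
                for p in self.populations
            ],
            "connections": [
                {"src": c.source, "dst": c.target, "w": c.weight}
                for c in self.connections
            ],
            "deleted": sorted(self.deleted),
            "constants": self.constants.to_dict(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "NetworkSpec":
        pops = tuple(
            PopulationSpec(
                name=p["name"], girdle=p["girdle"], side=p["side"],
                rhythmogenic=p["rhythmogenic"], C=p["C"], gL=p["gL"],
                EL=p["EL"], drive_E=tuple(p["drive_E"]),
                drive_I=tuple(p["drive_I"]),
            )
            for p in doc["populations"]
        )
        conns = tuple(
            ConnectionSpec(c["src"], c["dst"], c["w"])
            for c in doc["connections"]
        )
        constants = CellConstants.from_dict(doc.get("constants", {}))
        return cls(pops, conns, frozenset(doc.get("deleted", ())), constants)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "NetworkSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def compile(self) -> "CompiledNetwork":
        return CompiledNetwork.from_spec(self)


def _other(seq: Sequence[str], x: str) -> str:
    return seq[1] if x == seq[0] else seq[0]


def build_intact_network(constants: CellConstants | None = None) -> NetworkSpec:
    """The canonical intact 4-section network (56 populations, 84 edges)."""
    pops: list[PopulationSpec] = []
    for girdle in GIRDLES:
        names = SECTION_POPULATIONS + (
            FORE_ONLY_POPULATIONS if girdle == "fore" else ())
        for side in SIDES:
            for name in names:
                rg = name in RHYTHMOGENIC
                pops.append(PopulationSpec(
                    name=name, girdle=girdle, side=side, rhythmogenic=rg,
                    gL=_GL_RG if rg else _GL_OTHER,
                    EL=_EL_RG if rg else _EL_OTHER,
                    drive_E=_DRIVE_E.get(name, (0.0, 0.0)),
                    drive_I=_DRIVE_I.get(name, (0.0, 0.0)),
                ))

    conns: list[ConnectionSpec] = []
    for girdle in GIRDLES:
        for side in SIDES:
            rows = _WITHIN_SECTION + (
                _WITHIN_FORE_SECTION if girdle == "fore" else ())
            for src, dst, w in rows:
                conns.append(ConnectionSpec(
                    population_id(girdle, side, src),
                    population_id(girdle, side, dst), w))
            for src, dst, w in _COMMISSURAL:
                conns.append(ConnectionSpec(
                    population_id(girdle, side, src),
                    population_id(girdle, _other(SIDES, side), dst), w))
        # girdle loop only places section-local and commissural rows
    for side in SIDES:
        for g_src, src, dst, w in _HOMOLATERAL:
            conns.append(ConnectionSpec(
                population_id(g_src, side, src),
                population_id(_other(GIRDLES, g_src), side, dst), w))
        for g_src, src, dst, w in _DIAGONAL:
            conns.append(ConnectionSpec(
                population_id(g_src, side, src),
                population_id(_other(GIRDLES, g_src), _other(SIDES, side),
                              dst), w))

    return NetworkSpec(tuple(pops), tuple(conns),
                       constants=constants or CellConstants())


# -- selectors ---------------------------------------------------------

#: named population classes resolvable by :func:`resolve_selector`
_CLASS_SELECTORS = {
    "V0V": ("V0V", "V0V-diag"),
    "V0D": ("V0D", "V0D-diag"),
    "V2a": ("V2a", "V2a-diag"),
    "V0": ("V0V", "V0V-diag", "V0D", "V0D-diag"),
}
_DESCENDING_LPNS = ("Ini-Hom", "Sh2-Hom", "V0D-diag", "V0V-diag")
_LPN_ALIASES = {
    "descending LPNs": ("fore", _DESCENDING_LPNS),
    "cervical-to-lumbar LPNs": ("fore", _DESCENDING_LPNS),
}


def resolve_selector(net: NetworkSpec,
                     selector: str | Iterable[str]) -> frozenset[str]:
    """Resolve a population selector to a set of section-qualified ids.

    Accepted forms (per string): a full id (``fore-left-V0V``); a bare
    population name (``V0V-diag``: all sections where it exists); an
    ``all <class>`` / ``<class>`` class selector expanding CINs and LPNs
    of a genetic class (``all V0V`` = V0V + V0V-diag); a girdle-qualified
    name (``fore V0V-diag``); the aliases ``descending LPNs`` /
    ``cervical-to-lumbar LPNs``; and conjunctions joined by `` and ``
    (``all V0V and V0D``).
    """
    if isinstance(selector, str):
        selector = [selector]
    ids = set(net.ids)
    names = {p.name for p in net.populations}
    out: set[str] = set()

    def expand(token: str) -> set[str]:
        token = token.strip()
        if token in ids:
            return {token}
        if token in _LPN_ALIASES:
            girdle, members = _LPN_ALIASES[token]
            return {p.id for p in net.populations
                    if p.girdle == girdle and p.name in members}
        stripped = token.removeprefix("all ").strip()
        if stripped in _CLASS_SELECTORS:
            members = _CLASS_SELECTORS[stripped]
            return {p.id for p in net.populations if p.name in members}
        if stripped in names:
            return {p.id for p in net.populations if p.name == stripped}
        parts = stripped.split(None, 1)
        if len(parts) == 2 and parts[0] in GIRDLES:
            girdle, rest = parts
            sub = {p for p in net.populations if p.girdle == girdle}
            if rest in _CLASS_SELECTORS:
                members = _CLASS_SELECTORS[rest]
                return {p.id for p in sub if p.name in members}
            if rest in names:
                return {p.id for p in sub if p.name == rest}
        raise KeyError(f"unresolved population selector: {token!r}")

    for item in selector:
        for token in item.split(" and "):
            out |= expand(token)
    return frozenset(out)


def delete_populations(net: NetworkSpec,
                       selector: str | Iterable[str]) -> NetworkSpec:
    """Clamp the output of the selected populations to zero.

    The populations stay in the state vector and are still integrated;
    they just no longer contribute to any downstream synaptic sum.  The
    empty selector is the identity.
    """
    if not selector or (not isinstance(selector, str) and not list(selector)):
        return net
    resolved = resolve_selector(net, selector)
    return replace(net, deleted=net.deleted | resolved)


def perturb_weights(net: NetworkSpec, sigma_p: float,
                    seed: int | np.random.Generator = 0) -> NetworkSpec:
    """Multiply every connection weight by an independent N(1, sigma_p) draw.

    Draws are untruncated: at the sigma_p values of interest (<= 0.1) a
    sign flip is practically impossible, so no clipping is applied.
    """
    if sigma_p < 0:
        raise ValueError(f"sigma_p must be >= 0, got {sigma_p}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    factors = rng.normal(1.0, sigma_p, size=len(net.connections))
    conns = tuple(
        ConnectionSpec(c.source, c.target, c.weight * f)
        for c, f in zip(net.connections, factors)
    )
    return replace(net, connections=conns)


def mirror_id(pop_id: str) -> str:
    """Section-qualified id of the left-right mirror population."""
    girdle, side, name = pop_id.split("-", 2)
    return population_id(girdle, _other(SIDES, side), name)


# -- compiled form -----------------------------------------------------

@dataclass(frozen=True)
class CompiledNetwork:
    """Flat-array view of a :class:`NetworkSpec` for the ODE right-hand side.

    Excitatory and inhibitory edges are kept as separate (source, target,
    magnitude) triples so the synaptic sums use S(w)=max(w,0) and
    S(-w)=max(-w,0) directly.
    """

    spec: NetworkSpec
    ids: tuple[str, ...]
    gL: np.ndarray
    EL: np.ndarray
    C: float
    dE_m: np.ndarray
    dE_b: np.ndarray
    dI_m: np.ndarray
    dI_b: np.ndarray
    out_mask: np.ndarray          # 0.0 for deleted populations, else 1.0
    rg_idx: np.ndarray            # indices of populations carrying INaP
    exc_src: np.ndarray
    exc_tgt: np.ndarray
    exc_w: np.ndarray
    inh_src: np.ndarray
    inh_tgt: np.ndarray
    inh_w: np.ndarray             # magnitudes of negative weights
    constants: CellConstants

    @property
    def n_pop(self) -> int:
        return len(self.ids)

    @property
    def n_rg(self) -> int:
        return len(self.rg_idx)

    @property
    def n_state(self) -> int:
        return self.n_pop + self.n_rg

    def index_of(self, pop_id: str) -> int:
        try:
            return self.ids.index(pop_id)
        except ValueError:
            raise KeyError(pop_id) from None

    def indices_of(self, name: str, girdle: str | None = None,
                   side: str | None = None) -> np.ndarray:
        """Indices of populations matching name (and optional section)."""
        out = [i for i, p in enumerate(self.spec.populations)
               if p.name == name
               and (girdle is None or p.girdle == girdle)
               and (side is None or p.side == side)]
        return np.asarray(out, dtype=np.int64)

    @classmethod
    def from_spec(cls, net: NetworkSpec) -> "CompiledNetwork":
        pops = net.populations
        ids = net.ids
        idx = {pid: i for i, pid in enumerate(ids)}
        n = len(pops)
        gL = np.array([p.gL for p in pops])
        EL = np.array([p.EL for p in pops])
        caps = {p.C for p in pops}
        if len(caps) != 1:
            raise ValueError("per-population capacitance must be uniform")
        dE_m = np.array([p.drive_E[0] for p in pops])
        dE_b = np.array([p.drive_E[1] for p in pops])
        dI_m = np.array([p.drive_I[0] for p in pops])
        dI_b = np.array([p.drive_I[1] for p in pops])
        out_mask = np.array([0.0 if p.id in net.deleted else 1.0
                             for p in pops])
        rg_idx = np.array([i for i, p in enumerate(pops) if p.rhythmogenic],
                          dtype=np.int64)
        es, et, ew, isrc, itgt, iw = [], [], [], [], [], []
        for c in net.connections:
            if c.weight >= 0:
                es.append(idx[c.source]); et.append(idx[c.target])
                ew.append(c.weight)
            else:
                isrc.append(idx[c.source]); itgt.append(idx[c.target])
                iw.append(-c.weight)
        return cls(
            spec=net, ids=ids, gL=gL, EL=EL, C=caps.pop(),
            dE_m=dE_m, dE_b=dE_b, dI_m=dI_m, dI_b=dI_b,
            out_mask=out_mask, rg_idx=rg_idx,
            exc_src=np.array(es, dtype=np.int64),
            exc_tgt=np.array(et, dtype=np.int64),
            exc_w=np.array(ew, dtype=float),
            inh_src=np.array(isrc, dtype=np.int64),
            inh_tgt=np.array(itgt, dtype=np.int64),
            inh_w=np.array(iw, dtype=float),
            constants=net.constants,
        )
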