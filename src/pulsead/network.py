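"""Branched vessel-network geometry for the quasi-1D solver.

A :class:`NetworkGeometry` is a set of axially gridded segments joined at
junctions, with a boundary condition at every free end.  A dissected
descending aorta is represented by a true-lumen (TL) segment in the main
flow path and a false-lumen (FL) segment that communicates with the rest
of the network only through a single entry-tear orifice at a junction; the
FL distal end is closed (no re-entry tear).

All geometric quantities are SI (m, m², m²/Pa, Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .units import MMHG_TO_PA
from .windkessel import WK3Params
from .waveform import Waveform


@dataclass
class VesselSegment1D:
    """Axially gridded compliant vessel segment.

    ``A0`` and ``C_A`` may be given as scalars (uniform segment) or arrays
    on the grid.  ``A0`` is the reference area at p = p_ext.
    """

    name: str
    length: float
    n_nodes: int = 8
    A0: float | np.ndarray = 0.0
    C_A: float | np.ndarray = 0.0
    p_ext: float = 76.0 * MMHG_TO_PA

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if self.n_nodes < 8:
            raise ValueError(f"{self.name}: need at least 8 grid nodes")
        self.A0 = np.broadcast_to(np.asarray(self.A0, dtype=float), (self.n_nodes,)).copy()
        self.C_A = np.broadcast_to(np.asarray(self.C_A, dtype=float), (self.n_nodes,)).copy()
        if np.any(self.A0 <= 0):
            raise ValueError(f"{self.name}: A0 must be positive everywhere")
        if np.any(self.C_A < 0):
            raise ValueError(f"{self.name}: C_A must be non-negative")

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_nodes)

    @property
    def dx(self) -> float:
        return self.length / (self.n_nodes - 1)

    def mean_A0(self) -> float:
        return float(np.trapezoid(self.A0, self.x) / self.length)

    def diameter(self) -> float:
        """Mean diameter (m) implied by the reference area profile."""
        return 2.0 * float(np.sqrt(self.mean_A0() / np.pi))


@dataclass(frozen=True)
class TearOrifice:
    """Quasi-steady entry-tear orifice between TL side and FL."""

    A_tear: float = 18.5e-6  # m²
    Cd: float = 0.6

    def __post_init__(self) -> None:
        if self.A_tear <= 0:
            raise ValueError("tear area must be positive")
        if not (0 < self.Cd <= 1):
            raise ValueError("discharge coefficient must be in (0, 1]")


@dataclass
class Junction:
    """Node shared by segment ends: ('seg_name', 'prox'|'dist') pairs."""

    ends: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for seg, side in self.ends:
            if side not in ("prox", "dist"):
                raise ValueError(f"junction end side must be prox/dist, got {side!r}")
        if len(self.ends) < 2:
            raise ValueError("junction needs at least two ends")


@dataclass
class BoundaryCondition:
    """Condition at a free segment end.

    kind: 'inflow' (prescribed Q into the segment), 'outflow' (prescribed Q
    leaving the segment), 'wk3' (Windkessel coupling) or 'closed' (Q = 0).
    """

    kind: str
    segment: str
    side: str  # 'prox' | 'dist'
    wk3: WK3Params | None = None
    waveform: Waveform | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("inflow", "outflow", "wk3", "closed"):
            raise ValueError(f"unknown boundary kind {self.kind!r}")
        if self.side not in ("prox", "dist"):
            raise ValueError("boundary side must be prox/dist")
        if self.kind == "wk3" and self.wk3 is None:
            raise ValueError(f"{self.segment}: wk3 boundary needs parameters")


@dataclass
class Dissection:
    tl: str
    fl: str
    tear: TearOrifice = field(default_factory=TearOrifice)
    tear_junction: int = -1  # index into NetworkGeometry.junctions


@dataclass
class NetworkGeometry:
    segments: list[VesselSegment1D]
    junctions: list[Junction]
    boundaries: list[BoundaryCondition]
    dissection: Dissection | None = None

    def segment(self, name: str) -> VesselSegment1D:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def validate(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names")
        # every segment end is either in exactly one junction or one boundary
        ends: dict[tuple[str, str], int] = {}
        for j in self.junctions:
            for e in j.ends:
                ends[e] = ends.get(e, 0) + 1
        for b in self.boundaries:
            ends[(b.segment, b.side)] = ends.get((b.segment, b.side), 0) + 1
        if self.dissection is not None:
            ends[(self.dissection.fl, "prox")] = ends.get((self.dissection.fl, "prox"), 0) + 1
        for s in self.segments:
            for side in ("prox", "dist"):
                c = ends.get((s.name, side), 0)
                if c != 1:
                    raise ValueError(
                        f"segment end ({s.name}, {side}) attached {c} times; expected 1"
                    )
        if self.dissection is not None:
            d = self.dissection
            if d.tl not in names or d.fl not in names:
                raise ValueError("dissection refers to unknown segments")
            if not (0 <= d.tear_junction < len(self.junctions)):
                raise ValueError("dissection tear_junction index out of range")
            fl_dist = [
                b for b in self.boundaries if b.segment == d.fl and b.side == "dist"
            ]
            if len(fl_dist) != 1 or fl_dist[0].kind != "closed":
                raise ValueError("FL distal end must carry a 'closed' boundary (no re-entry)")

    def wk3_outlets(self) -> dict[str, WK3Params]:
        return {b.segment: b.wk3 for b in self.boundaries if b.kind == "wk3"}

    def set_wk3(self, params: dict[str, WK3Params]) -> None:
        """Install tuned Windkessel parameters on the matching outlets."""
        for b in self.boundaries:
            if b.kind == "wk3" and b.segment in params:
                b.wk3 = params[b.segment]


# ---------------------------------------------------------------------------
# YAML serialization (geometry only; boundary waveforms are external CSVs)


def geometry_to_dict(geom: NetworkGeometry) -> dict:
    d: dict = {
        "segments": [
            {
                "name": s.name,
                "length_m": float(s.length),
                "nodes": int(s.n_nodes),
                "A0_profile": [float(v) for v in s.A0],
                "CA_profile": [float(v) for v in s.C_A],
                "p_ext_mmHg": float(s.p_ext / MMHG_TO_PA),
            }
            for s in geom.segments
        ],
        "junctions": [{"ends": [list(e) for e in j.ends]} for j in geom.junctions],
        "boundaries": [
            {
                "kind": b.kind,
                "segment": b.segment,
                "side": b.side,
                **(
                    {"wk3": {"R1": b.wk3.R1, "R2": b.wk3.R2, "C": b.wk3.C}}
                    if b.wk3 is not None
                    else {}
                ),
            }
            for b in geom.boundaries
        ],
    }
    if geom.dissection is not None:
        d["dissection"] = {
            "tl": geom.dissection.tl,
            "fl": geom.dissection.fl,
            "tear_area_mm2": geom.dissection.tear.A_tear * 1e6,
            "cd": geom.dissection.tear.Cd,
            "tear_junction": geom.dissection.tear_junction,
        }
    return d


def geometry_from_dict(d: dict) -> NetworkGeometry:
    try:
        segments = [
            VesselSegment1D(
                name=s["name"],
                length=float(s["length_m"]),
                n_nodes=int(s.get("nodes", 8)),
                A0=np.asarray(s["A0_profile"], dtype=float),
                C_A=np.asarray(s.get("CA_profile", 0.0), dtype=float),
                p_ext=float(s.get("p_ext_mmHg", 76.0)) * MMHG_TO_PA,
            )
            for s in d["segments"]
        ]
        junctions = [Junction(ends=[tuple(e) for e in j["ends"]]) for j in d["junctions"]]
        boundaries = []
        for b in d["boundaries"]:
            wk3 = None
            if "wk3" in b:
                wk3 = WK3Params(R1=b["wk3"]["R1"], R2=b["wk3"]["R2"], C=b["wk3"]["C"])
            boundaries.append(
                BoundaryCondition(kind=b["kind"], segment=b["segment"], side=b["side"], wk3=wk3)
            )
        dissection = None
        if "dissection" in d:
            dd = d["dissection"]
            dissection = Dissection(
                tl=dd["tl"],
                fl=dd["fl"],
                tear=TearOrifice(A_tear=float(dd["tear_area_mm2"]) * 1e-6, Cd=float(dd["cd"])),
                tear_junction=int(dd["tear_junction"]),
            )
    except KeyError as exc:
        raise ValueError(f"geometry config missing key: {exc}") from exc
    geom = NetworkGeometry(segments, junctions, boundaries, dissection)
    geom.validate()
    return geom


def write_geometry_yaml(geom: NetworkGeometry, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(geometry_to_dict(geom), fh, sort_keys=False)


def read_geometry_yaml(path) -> NetworkGeometry:
    with open(path) as fh:
        return geometry_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Lumped (0D) equivalent of a 1D geometry

def lumped_equivalent(
    geom: NetworkGeometry,
    mu: float = 4e-3,
    rho: float = 1056.0,
    include_fl: bool = True,
):
    """Collapse each 1D segment into one inertance–resistance block.

    Standard lumped-parameter identities for a tube of length l and area A0:
    L = rho*l/A0 (blood inertia) and R = 8*pi*mu*l/A0**2 (Poiseuille),
    converted to clinical units.  Junction i becomes node ``Ji``; free ends
    become nodes ``<segment>:<side>``.  WK3 terminals keep their segment
    name as the outlet name.  Returns a :class:`pulsead.windkessel.LumpedNetwork`
    without sources (the caller attaches inflow/withdrawal waveforms) plus a
    map from boundary segment name to its network node.
    """
    from .units import RES_CLIN_TO_SI
    from .windkessel import LRBlock, LumpedNetwork, NamedBlock

    geom.validate()
    end_node: dict[tuple[str, str], str] = {}
    for i, j in enumerate(geom.junctions):
        for e in j.ends:
            end_node[e] = f"J{i}"
    if geom.dissection is not None:
        end_node[(geom.dissection.fl, "prox")] = f"J{geom.dissection.tear_junction}"
    for b in geom.boundaries:
        end_node.setdefault((b.segment, b.side), f"{b.segment}:{b.side}")

    blocks: list[NamedBlock] = []
    for s in geom.segments:
        if geom.dissection is not None and s.name == geom.dissection.fl and not include_fl:
            continue
        A0 = s.mean_A0()
        L = rho * s.length / A0 / RES_CLIN_TO_SI
        R = 8.0 * np.pi * mu * s.length / A0**2 / RES_CLIN_TO_SI
        blocks.append(
            NamedBlock(
                name=s.name,
                block=LRBlock(L=L, R=R),
                from_node=end_node[(s.name, "prox")],
                to_node=end_node[(s.name, "dist")],
            )
        )

    terminals: dict[str, tuple[str, WK3Params]] = {}
    bc_nodes: dict[str, str] = {}
    for b in geom.boundaries:
        node = end_node[(b.segment, b.side)]
        bc_nodes[b.segment] = node
        if b.kind == "wk3":
            if b.wk3 is None:
                raise ValueError(f"{b.segment}: wk3 boundary has no parameters")
            terminals[b.segment] = (node, b.wk3)

    return LumpedNetwork(blocks=blocks, terminals=terminals, sources=[]), bc_nodes
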