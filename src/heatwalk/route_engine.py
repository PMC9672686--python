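"""Street graphs, budget-constrained route search and walkability maps.

Streets are an undirected graph in planar metre coordinates; every edge
carries a length and a UTCI range (its worst-case value decides the
heat-stress level, see :mod:`heatwalk.stress_model`). Routes are simple
paths — one-way walks, no revisits — whose total length must stay within a
distance budget (default 900 m, i.e. a 15-minute walk at 1 m/s).

The search objective is the terminal remaining tolerant heat discomfort
R_t = H - S_t: the best route maximises R_t, equivalently minimises the
accumulated stress S_t. Because every edge adds nonnegative stress and
strictly positive distance, removing a cycle from a walk never worsens
either criterion, so a Pareto label-setting search over (stress, distance)
states with dominance pruning finds the simple-path optimum exactly.

:func:`walkability_map` extends this to every edge reachable from an
origin: the value of an edge is the best terminal R_t over feasible routes
that *end by traversing that edge*. Its labels carry visited sets and use
subset-aware dominance, which keeps the search exact under the simple-path
constraint.
"""

from __future__ import annotations

import heapq
import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .errors import InvalidInputError, SchemaError
from .stress_model import (
    HeatStressScale,
    StressTrajectory,
    ToleranceParams,
    evaluate_route,
    segment_level,
    walk_duration,
)

__all__ = [
    "DEFAULT_BUDGET_M",
    "DEFAULT_RT_CUTPOINTS",
    "StreetGraph",
    "RouteResult",
    "WalkabilityMap",
    "edge_key",
    "load_network",
    "save_network",
    "best_tolerance_route",
    "walkability_map",
    "bin_rt",
    "save_map",
    "load_map",
    "duration_budget_m",
]

#: Default maximum walkable distance: 15 min at 1 m/s.
DEFAULT_BUDGET_M = 900.0

#: Default R_t bin cut points (stress-minutes) for map display and siting.
DEFAULT_RT_CUTPOINTS = (45.0, 30.0, 15.0)

_EPS = 1e-9

EdgeKey = Tuple[str, str]


def edge_key(u: str, v: str) -> EdgeKey:
    """Canonical undirected edge identifier."""
    return (u, v) if str(u) <= str(v) else (v, u)


def duration_budget_m(minutes: float, params: Optional[ToleranceParams] = None) -> float:
    """Convert a walking-time budget (minutes) to a distance budget (m)."""
    params = params or ToleranceParams()
    if not (math.isfinite(minutes) and minutes > 0):
        raise InvalidInputError(f"budget must be > 0 minutes, got {minutes}")
    return minutes * 60.0 * params.walking_speed


class StreetGraph:
    """Undirected street network with per-edge lengths and UTCI summaries.

    Thin wrapper over a :class:`networkx.Graph`; node attributes ``x``/``y``
    are planar metre coordinates, edge attributes are ``edge_id``,
    ``length_m``, ``utci_min``, ``utci_max`` and an optional ``geometry``
    coordinate list for curved streets. ``entrances`` marks the nodes used
    as neighbourhood starting points.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()
        self.entrances: List[str] = []

    # -- construction -------------------------------------------------

    def add_node(self, node_id: str, x: float, y: float) -> None:
        self.graph.add_node(str(node_id), x=float(x), y=float(y))

    def add_edge(
        self,
        edge_id: str,
        u: str,
        v: str,
        length_m: float,
        utci_min: Optional[float] = None,
        utci_max: Optional[float] = None,
        geometry: Optional[List[Tuple[float, float]]] = None,
    ) -> None:
        u, v = str(u), str(v)
        for n in (u, v):
            if n not in self.graph:
                raise InvalidInputError(f"edge {edge_id} references unknown node {n}")
        if not (math.isfinite(length_m) and length_m > 0):
            raise InvalidInputError(f"edge {edge_id}: length must be > 0, got {length_m}")
        if utci_min is not None and utci_max is not None and utci_min > utci_max:
            raise InvalidInputError(f"edge {edge_id}: utci_min > utci_max")
        self.graph.add_edge(
            u,
            v,
            edge_id=str(edge_id),
            length_m=float(length_m),
            utci_min=None if utci_min is None else float(utci_min),
            utci_max=None if utci_max is None else float(utci_max),
            geometry=geometry,
        )

    def set_entrances(self, node_ids) -> None:
        for n in node_ids:
            if str(n) not in self.graph:
                raise InvalidInputError(f"entrance {n} is not a node of the graph")
        self.entrances = [str(n) for n in node_ids]

    # -- views ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_keys(self) -> List[EdgeKey]:
        return sorted(edge_key(u, v) for u, v in self.graph.edges)

    def node_xy(self, node_id: str) -> Tuple[float, float]:
        d = self.graph.nodes[str(node_id)]
        return d["x"], d["y"]

    def _edge_cost(self, u, v, scale, params) -> Tuple[float, float, float]:
        """(stress, duration, length) of traversing edge (u, v)."""
        data = self.graph.edges[u, v]
        if data.get("utci_min") is None or data.get("utci_max") is None:
            raise InvalidInputError(
                f"edge {data.get('edge_id')} has no UTCI attributes; "
                "sample a UTCI field or set utci_min/utci_max first"
            )
        level = segment_level(data["utci_min"], data["utci_max"], scale)
        dur = walk_duration(data["length_m"], params)
        return round(level * dur, 9), dur, data["length_m"]


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------


def load_network(
    path,
    snap_tolerance: float = 0.5,
    entrances: Optional[List[str]] = None,
) -> StreetGraph:
    """Read a street network from a GeoJSON FeatureCollection.

    LineString features become edges and must carry ``utci_min`` and
    ``utci_max`` properties; ``length_m`` is taken from the properties or
    computed from the geometry. Endpoints within ``snap_tolerance`` metres
    are merged into one node; ``from_node``/``to_node`` properties, when
    present, name the nodes explicitly. Point features with a truthy
    ``entrance`` property (or the ``entrances`` argument) mark starting
    nodes.
    """
    with open(path) as f:
        data = json.load(f)
    if not isinstance(data, dict) or data.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    features = data.get("features", [])
    line_feats = [f for f in features if f.get("geometry", {}).get("type") == "LineString"]
    point_feats = [f for f in features if f.get("geometry", {}).get("type") == "Point"]
    if not line_feats:
        raise SchemaError(f"{path}: no LineString features (empty network)")

    sg = StreetGraph()
    registry: List[Tuple[str, float, float]] = []  # (node_id, x, y)
    counter = itertools.count()

    def resolve(x: float, y: float, wanted: Optional[str]) -> str:
        if wanted is not None:
            wanted = str(wanted)
            if wanted not in sg.graph:
                sg.add_node(wanted, x, y)
                registry.append((wanted, x, y))
            return wanted
        for nid, nx_, ny_ in registry:
            if math.hypot(x - nx_, y - ny_) <= snap_tolerance:
                return nid
        nid = f"n{next(counter)}"
        sg.add_node(nid, x, y)
        registry.append((nid, x, y))
        return nid

    for i, feat in enumerate(line_feats):
        props = feat.get("properties") or {}
        eid = str(props.get("edge_id", props.get("id", f"e{i}")))
        for key in ("utci_min", "utci_max"):
            if key not in props or props[key] is None:
                raise SchemaError(f"feature {eid}: missing required property {key!r}")
        coords = feat["geometry"]["coordinates"]
        if len(coords) < 2:
            raise SchemaError(f"feature {eid}: LineString needs >= 2 coordinates")
        length = props.get("length_m")
        if length is None:
            length = LineString(coords).length
        u = resolve(coords[0][0], coords[0][1], props.get("from_node"))
        v = resolve(coords[-1][0], coords[-1][1], props.get("to_node"))
        sg.add_edge(
            eid,
            u,
            v,
            float(length),
            float(props["utci_min"]),
            float(props["utci_max"]),
            geometry=[tuple(c) for c in coords],
        )

    marks: List[str] = []
    for feat in point_feats:
        props = feat.get("properties") or {}
        if not (props.get("entrance") or props.get("entrance_id")):
            continue
        nid = props.get("node_id")
        if nid is not None:
            if str(nid) not in sg.graph:
                raise InvalidInputError(f"entrance point references unknown node {nid}")
            marks.append(str(nid))
            continue
        x, y = feat["geometry"]["coordinates"][:2]
        best, best_d = None, math.inf
        for node, nx_, ny_ in registry:
            d = math.hypot(x - nx_, y - ny_)
            if d < best_d:
                best, best_d = node, d
        if best is None or best_d > snap_tolerance:
            raise InvalidInputError(
                f"entrance point at ({x}, {y}) snaps to no node within {snap_tolerance} m"
            )
        marks.append(best)
    if entrances:
        for n in entrances:
            if str(n) not in sg.graph:
                raise InvalidInputError(f"entrance {n} is not a node of the network")
            marks.append(str(n))
    sg.entrances = list(dict.fromkeys(marks))
    return sg


def save_network(sg: StreetGraph, path) -> None:
    """Write a street network as a GeoJSON FeatureCollection (round-trip safe)."""
    features = []
    for u, v, data in sorted(sg.graph.edges(data=True), key=lambda t: t[2]["edge_id"]):
        coords = data.get("geometry")
        if not coords:
            coords = [sg.node_xy(u), sg.node_xy(v)]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [list(c) for c in coords]},
                "properties": {
                    "edge_id": data["edge_id"],
                    "from_node": u,
                    "to_node": v,
                    "length_m": data["length_m"],
                    "utci_min": data["utci_min"],
                    "utci_max": data["utci_max"],
                },
            }
        )
    for n in sg.entrances:
        x, y = sg.node_xy(n)
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {"entrance": True, "node_id": n},
            }
        )
    with open(path, "w") as f:
        json.dump({"type": "FeatureCollection", "features": features}, f, indent=1)


# ---------------------------------------------------------------------------
# Route search
# ---------------------------------------------------------------------------


@dataclass
class RouteResult:
    """Outcome of a route search: node sequence, trajectory, feasibility."""

    origin: str
    dest: str
    feasible: bool
    nodes: List[str] = field(default_factory=list)
    edge_ids: List[str] = field(default_factory=list)
    trajectory: Optional[StressTrajectory] = None
    total_length_m: float = 0.0

    @property
    def terminal_rt(self) -> Optional[float]:
        if not self.feasible:
            return None
        return self.trajectory.terminal_rt if self.trajectory else None


def _trajectory_for_path(sg: StreetGraph, nodes, scale, params) -> StressTrajectory:
    segs = []
    for u, v in zip(nodes, nodes[1:]):
        data = sg.graph.edges[u, v]
        segs.append((data["edge_id"], data["utci_min"], data["utci_max"], data["length_m"]))
    return evaluate_route(segs, scale, params)


def best_tolerance_route(
    sg: StreetGraph,
    origin: str,
    dest: str,
    scale: Optional[HeatStressScale] = None,
    params: Optional[ToleranceParams] = None,
    budget_m: float = DEFAULT_BUDGET_M,
) -> RouteResult:
    """Best simple path from origin to dest within the distance budget.

    "Best" maximises the terminal R_t (minimises accumulated stress); ties
    break by shorter distance, then lexicographic node sequence. Returns an
    infeasible :class:`RouteResult` when no path fits the budget.
    """
    scale = scale or HeatStressScale()
    params = params or ToleranceParams()
    origin, dest = str(origin), str(dest)
    for n in (origin, dest):
        if n not in sg.graph:
            raise InvalidInputError(f"node {n} not in graph")
    if origin == dest:
        return RouteResult(
            origin=origin,
            dest=dest,
            feasible=True,
            nodes=[origin],
            edge_ids=[],
            trajectory=StressTrajectory(
                segments=[],
                cumulative_stress=np.array([], dtype=float),
                remaining=np.array([], dtype=float),
                params=params,
            ),
            total_length_m=0.0,
        )

    costs = {
        edge_key(u, v): sg._edge_cost(u, v, scale, params) for u, v in sg.graph.edges
    }
    frontier: Dict[str, List[Tuple[float, float]]] = {origin: [(0.0, 0.0)]}
    heap = [(0.0, 0.0, (origin,))]
    while heap:
        stress, dist, path = heapq.heappop(heap)
        node = path[-1]
        if node == dest:
            traj = _trajectory_for_path(sg, list(path), scale, params)
            return RouteResult(
                origin=origin,
                dest=dest,
                feasible=True,
                nodes=list(path),
                edge_ids=[s.segment_id for s in traj.segments],
                trajectory=traj,
                total_length_m=dist,
            )
        for nbr in sorted(sg.graph.neighbors(node)):
            if nbr in path:
                continue
            e_stress, _, e_len = costs[edge_key(node, nbr)]
            nd = round(dist + e_len, 9)
            if nd > budget_m + _EPS:
                continue
            ns = round(stress + e_stress, 9)
            labels = frontier.setdefault(nbr, [])
            if any(s <= ns + _EPS and d <= nd + _EPS for s, d in labels):
                continue
            labels[:] = [(s, d) for s, d in labels if not (ns <= s + _EPS and nd <= d + _EPS)]
            labels.append((ns, nd))
            heapq.heappush(heap, (ns, nd, path + (nbr,)))
    return RouteResult(origin=origin, dest=dest, feasible=False)


@dataclass
class WalkabilityMap:
    """Per-edge best terminal R_t over budget-feasible routes from one origin."""

    origin: str
    budget_m: float
    h: float
    statistic: str
    values: Dict[EdgeKey, float]
    edge_ids: Dict[EdgeKey, str]
    unreachable: List[EdgeKey]

    def reachable(self, key: EdgeKey) -> bool:
        return key in self.values

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "edge_id": self.edge_ids[k],
                "from_node": k[0],
                "to_node": k[1],
                "r_t": self.values.get(k),
                "reachable": k in self.values,
            }
            for k in sorted(set(self.values) | set(self.unreachable))
        ]
        return pd.DataFrame(rows)


def walkability_map(
    sg: StreetGraph,
    origin: str,
    scale: Optional[HeatStressScale] = None,
    params: Optional[ToleranceParams] = None,
    budget_m: float = DEFAULT_BUDGET_M,
    statistic: str = "max",
) -> WalkabilityMap:
    """Score every edge by the terminal R_t of routes ending on it.

    For each edge, the value is the max (default) or min terminal R_t at
    the edge's far end over simple paths from the origin that finish by
    traversing that edge with total distance within the budget. Edges no
    feasible route ends on are reported unreachable.

    The max statistic uses subset-aware Pareto pruning; the min statistic
    must keep every non-duplicate label and is exponential in the worst
    case — use it on small graphs only.
    """
    scale = scale or HeatStressScale()
    params = params or ToleranceParams()
    origin = str(origin)
    if origin not in sg.graph:
        raise InvalidInputError(f"node {origin} not in graph")
    if statistic not in ("max", "min"):
        raise InvalidInputError(f"statistic must be 'max' or 'min', got {statistic!r}")

    costs = {
        edge_key(u, v): sg._edge_cost(u, v, scale, params) for u, v in sg.graph.edges
    }
    better = max if statistic == "max" else min
    values: Dict[EdgeKey, float] = {}
    frontier: Dict[str, List[Tuple[float, float, frozenset]]] = {
        origin: [(0.0, 0.0, frozenset([origin]))]
    }
    heap = [(0.0, 0.0, (origin,))]
    while heap:
        stress, dist, path = heapq.heappop(heap)
        node = path[-1]
        visited = frozenset(path)
        for nbr in sorted(sg.graph.neighbors(node)):
            if nbr in visited:
                continue
            ek = edge_key(node, nbr)
            e_stress, _, e_len = costs[ek]
            nd = round(dist + e_len, 9)
            if nd > budget_m + _EPS:
                continue
            ns = round(stress + e_stress, 9)
            rt = round(params.h - ns, 9)
            values[ek] = rt if ek not in values else better(values[ek], rt)
            nvis = visited | {nbr}
            labels = frontier.setdefault(nbr, [])
            if statistic == "max":
                if any(
                    s <= ns + _EPS and d <= nd + _EPS and vis <= nvis
                    for s, d, vis in labels
                ):
                    continue
            else:
                if any(s == ns and d == nd and vis == nvis for s, d, vis in labels):
                    continue
            labels.append((ns, nd, nvis))
            heapq.heappush(heap, (ns, nd, path + (nbr,)))

    edge_ids = {edge_key(u, v): d["edge_id"] for u, v, d in sg.graph.edges(data=True)}
    unreachable = [k for k in sg.edge_keys() if k not in values]
    return WalkabilityMap(
        origin=origin,
        budget_m=budget_m,
        h=params.h,
        statistic=statistic,
        values=values,
        edge_ids=edge_ids,
        unreachable=unreachable,
    )


# ---------------------------------------------------------------------------
# R_t binning and map I/O
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def bin_rt(
    r_t: float,
    cutpoints: Tuple[float, ...] = DEFAULT_RT_CUTPOINTS,
    h: float = 60.0,
) -> str:
    """Bin an R_t value for display: 45-60 / 30-45 / 15-30 / 0-15 / exhausted.

    Bins are half-open with the boundary going to the upper bin (mirroring
    the level classifier convention); negative R_t means the stress budget
    is exhausted before the end of the route.
    """
    r_t = float(r_t)
    if not math.isfinite(r_t):
        raise InvalidInputError("r_t must be finite")
    if r_t > h + _EPS:
        raise InvalidInputError(f"r_t {r_t} exceeds the budget H={h}")
    cuts = sorted(float(c) for c in cutpoints)
    if r_t < 0:
        return "exhausted"
    edges = [0.0] + cuts + [float(h)]
    for lo, hi in zip(edges[-2::-1], edges[::-1]):
        if r_t >= lo:
            return f"{_fmt(lo)}-{_fmt(hi)}"
    return f"{_fmt(edges[0])}-{_fmt(edges[1])}"


def save_map(wmap: WalkabilityMap, sg: StreetGraph, path, cutpoints=DEFAULT_RT_CUTPOINTS) -> None:
    """Write a walkability map as GeoJSON with r_t, bin and reachable per edge."""
    features = []
    for u, v, data in sorted(sg.graph.edges(data=True), key=lambda t: t[2]["edge_id"]):
        k = edge_key(u, v)
        rt = wmap.values.get(k)
        coords = data.get("geometry") or [sg.node_xy(u), sg.node_xy(v)]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [list(c) for c in coords]},
                "properties": {
                    "edge_id": data["edge_id"],
                    "from_node": k[0],
                    "to_node": k[1],
                    "r_t": rt,
                    "bin": None if rt is None else bin_rt(rt, cutpoints, wmap.h),
                    "reachable": rt is not None,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "origin": wmap.origin,
            "budget_m": wmap.budget_m,
            "h": wmap.h,
            "statistic": wmap.statistic,
        },
        "features": features,
    }
    with open(path, "w") as f:
        json.dump(doc, f, indent=1)


def load_map(path) -> WalkabilityMap:
    """Reload a walkability map written by :func:`save_map`."""
    with open(path) as f:
        doc = json.load(f)
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    meta = doc.get("properties") or {}
    values: Dict[EdgeKey, float] = {}
    edge_ids: Dict[EdgeKey, str] = {}
    unreachable: List[EdgeKey] = []
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if "from_node" not in props:
            continue
        k = edge_key(props["from_node"], props["to_node"])
        edge_ids[k] = props.get("edge_id", f"{k[0]}-{k[1]}")
        if props.get("r_t") is None:
            unreachable.append(k)
        else:
            values[k] = float(props["r_t"])
    return WalkabilityMap(
        origin=str(meta.get("origin")),
        budget_m=float(meta.get("budget_m", DEFAULT_BUDGET_M)),
        h=float(meta.get("h", 60.0)),
        statistic=str(meta.get("statistic", "max")),
        values=values,
        edge_ids=edge_ids,
        unreachable=unreachable,
    )
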