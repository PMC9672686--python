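"""Shared fixtures and independent brute-force oracles.

The oracles re-derive stress doses and route optima from first principles
(closed-form band counting, tenth-minute ceilings, exhaustive depth-first
path enumeration) without touching the package's classifiers or search,
so implementation and check stay on separate paths.
"""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from heatwalk import StreetGraph
from heatwalk.examples import EXAMPLE_POPULATIONS_K, EXAMPLE_ROUTE_SEGMENTS, example_route_graph

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BREAKPOINTS = (26.0, 32.0, 38.0, 46.0)


# ---------------------------------------------------------------------------
# independent single-segment arithmetic
# ---------------------------------------------------------------------------


def oracle_level(utci_max: float) -> int:
    """Level = number of thresholds at or below the worst UTCI."""
    return sum(1 for b in BREAKPOINTS if utci_max >= b)


def oracle_duration(length_m: float, speed: float = 1.0) -> float:
    """Walking time in minutes, ceiled to tenth-minutes."""
    tenths = length_m / speed / 6.0
    n = math.ceil(tenths - 1e-9)
    return n / 10.0


def oracle_edge_stress(utci_max: float, length_m: float) -> float:
    return oracle_level(utci_max) * oracle_duration(length_m)


def oracle_route_stress(segments) -> float:
    """Straight single-pass dose sum over (id, umin, umax, length) tuples."""
    return sum(oracle_edge_stress(s[2], s[3]) for s in segments)


# ---------------------------------------------------------------------------
# independent exhaustive route search
# ---------------------------------------------------------------------------


def _adj(sg: StreetGraph):
    out = {}
    for u, v, d in sg.graph.edges(data=True):
        s = oracle_edge_stress(d["utci_max"], d["length_m"])
        out.setdefault(u, []).append((v, d["length_m"], s))
        out.setdefault(v, []).append((u, d["length_m"], s))
    for n in sg.graph.nodes:
        out.setdefault(n, [])
    return out


def oracle_best_route(sg: StreetGraph, origin, dest, budget_m, h=60.0):
    """(best terminal R_t, its length) over all simple paths within budget.

    Depth-first enumeration; pruning by the budget only (lengths are
    positive so an over-budget prefix can never recover). Returns None if
    no path fits.
    """
    adj = _adj(sg)
    best = None

    def dfs(node, dist, stress, visited):
        nonlocal best
        if node == dest:
            cand = (round(h - stress, 9), dist)
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
            return
        for nbr, length, s in adj[node]:
            if nbr in visited or dist + length > budget_m + 1e-9:
                continue
            dfs(nbr, round(dist + length, 9), round(stress + s, 9), visited | {nbr})

    if origin == dest:
        return (h, 0.0)
    dfs(origin, 0.0, 0.0, {origin})
    return best


def oracle_edge_values(sg: StreetGraph, origin, budget_m, h=60.0, statistic="max"):
    """Per-edge terminal R_t over simple paths ending by traversing the edge."""
    adj = _adj(sg)
    pick = max if statistic == "max" else min
    values = {}

    def key(u, v):
        return (u, v) if str(u) <= str(v) else (v, u)

    def dfs(node, dist, stress, visited):
        for nbr, length, s in adj[node]:
            if nbr in visited or dist + length > budget_m + 1e-9:
                continue
            ns = round(stress + s, 9)
            k = key(node, nbr)
            rt = round(h - ns, 9)
            values[k] = rt if k not in values else pick(values[k], rt)
            dfs(nbr, round(dist + length, 9), ns, visited | {nbr})

    dfs(origin, 0.0, 0.0, {origin})
    return values


def random_street_graph(rng: np.random.Generator, max_nodes: int = 10) -> StreetGraph:
    """A random small street graph with varied lengths and UTCI ranges."""
    n = int(rng.integers(3, max_nodes + 1))
    sg = StreetGraph()
    for i in range(n):
        sg.add_node(f"v{i}", float(rng.uniform(0, 1000)), float(rng.uniform(0, 1000)))
    eid = 0
    for i in range(1, n):  # random spanning tree keeps most graphs connected
        j = int(rng.integers(0, i))
        _rand_edge(sg, rng, f"v{i}", f"v{j}", eid)
        eid += 1
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        i, j = rng.integers(0, n, size=2)
        if i == j or sg.graph.has_edge(f"v{i}", f"v{j}"):
            continue
        _rand_edge(sg, rng, f"v{i}", f"v{j}", eid)
        eid += 1
    return sg


def _rand_edge(sg, rng, u, v, eid):
    length = round(float(rng.uniform(30, 350)), 1)
    lo = round(float(rng.uniform(24, 46)), 1)
    hi = round(lo + float(rng.uniform(0, 4)), 1)
    sg.add_edge(f"e{eid}", u, v, length, lo, hi)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def route_segments():
    return list(EXAMPLE_ROUTE_SEGMENTS)


@pytest.fixture
def route_graph():
    return example_route_graph()


@pytest.fixture
def populations():
    return dict(EXAMPLE_POPULATIONS_K)
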