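"""Bundled worked-example inputs.

A seven-segment walking route through a mixed shaded/exposed street
network (UTCI ranges in degC and lengths in metres), and populations (in
thousands) of the twelve neighbourhoods of an example fifteen-minute-city
district. Used by the README walk-through, the test suite and the
reproduction script.
"""

from __future__ import annotations

from .route_engine import StreetGraph
from .synthetic_data import gen_chain

__all__ = [
    "EXAMPLE_ROUTE_SEGMENTS",
    "EXAMPLE_POPULATIONS_K",
    "example_route_graph",
]

#: (segment_id, utci_min, utci_max, length_m) along the walk a -> h.
EXAMPLE_ROUTE_SEGMENTS = [
    ("ab", 34.0, 36.0, 71.1),
    ("bc", 38.0, 40.0, 171.7),
    ("cd", 33.0, 34.0, 44.8),
    ("de", 38.0, 40.0, 51.0),
    ("ef", 37.0, 40.0, 292.0),
    ("fg", 33.0, 36.0, 12.0),
    ("gh", 32.0, 36.0, 257.3),
]

#: Neighbourhood populations, thousands of residents.
EXAMPLE_POPULATIONS_K = {
    "A": 3.0,
    "B": 2.7,
    "C": 2.2,
    "D": 12.7,
    "E": 2.7,
    "F": 6.1,
    "G": 3.4,
    "H": 8.2,
    "I": 2.8,
    "J": 6.2,
    "K": 9.8,
    "L": 13.0,
}


def example_route_graph() -> StreetGraph:
    """The example route as a chain street graph with nodes a..h."""
    nodes = list("abcdefgh")
    sg = gen_chain([s[3] for s in EXAMPLE_ROUTE_SEGMENTS], node_ids=nodes)
    for (sid, umin, umax, _), (u, v) in zip(EXAMPLE_ROUTE_SEGMENTS, zip(nodes, nodes[1:])):
        data = sg.graph.edges[u, v]
        data["edge_id"] = sid
        data["utci_min"] = umin
        data["utci_max"] = umax
    return sg
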