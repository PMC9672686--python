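"""Street-graph I/O, budget-constrained route search and walkability maps."""

import json

import networkx as nx
import numpy as np
import pytest

from heatwalk import (
    InvalidInputError,
    SchemaError,
    StreetGraph,
    best_tolerance_route,
    bin_rt,
    duration_budget_m,
    edge_key,
    load_map,
    load_network,
    save_map,
    save_network,
    walkability_map,
)
from heatwalk.route_engine import DEFAULT_BUDGET_M

from conftest import (
    oracle_best_route,
    oracle_duration,
    oracle_edge_values,
    random_street_graph,
)


def _chain_geojson(tmp_path, route_segments, with_entrance=True):
    features = []
    x = 0.0
    for sid, umin, umax, length in route_segments:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[x, 0.0], [x + length, 0.0]],
                },
                "properties": {"edge_id": sid, "utci_min": umin, "utci_max": umax},
            }
        )
        x += length
    if with_entrance:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [0.0, 0.0]},
                "properties": {"entrance": True},
            }
        )
    path = tmp_path / "net.geojson"
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


class TestNetworkIO:
    def test_chain_snaps_to_eight_nodes(self, tmp_path, route_segments):
        sg = load_network(_chain_geojson(tmp_path, route_segments))
        assert sg.n_nodes == 8
        assert sg.n_edges == 7
        assert len(sg.entrances) == 1
        lengths = sorted(d["length_m"] for _, _, d in sg.graph.edges(data=True))
        assert lengths[0] == pytest.approx(12.0)

    def test_empty_collection_rejected(self, tmp_path):
        path = tmp_path / "empty.geojson"
        path.write_text(json.dumps({"type": "FeatureCollection", "features": []}))
        with pytest.raises(SchemaError):
            load_network(path)

    def test_missing_utci_names_feature(self, tmp_path):
        path = tmp_path / "bad.geojson"
        feat = {
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": [[0, 0], [10, 0]]},
            "properties": {"edge_id": "oops", "utci_min": 30.0},
        }
        path.write_text(json.dumps({"type": "FeatureCollection", "features": [feat]}))
        with pytest.raises(SchemaError, match="oops"):
            load_network(path)

    def test_dangling_entrance_rejected(self, tmp_path, route_segments):
        path = _chain_geojson(tmp_path, route_segments, with_entrance=False)
        with pytest.raises(InvalidInputError):
            load_network(path, entrances=["nope"])

    def test_round_trip_identity(self, tmp_path, route_graph):
        out = tmp_path / "rt.geojson"
        save_network(route_graph, out)
        back = load_network(out)
        assert back.n_nodes == route_graph.n_nodes
        assert back.entrances == route_graph.entrances
        for u, v, d in route_graph.graph.edges(data=True):
            d2 = back.graph.edges[u, v]
            for key in ("edge_id", "length_m", "utci_min", "utci_max"):
                assert d2[key] == d[key]


class TestBestRoute:
    def test_reference_chain_terminal_rt(self, route_graph):
        res = best_tolerance_route(route_graph, "a", "h")
        assert res.feasible
        assert res.nodes == list("abcdefgh")
        assert res.terminal_rt == pytest.approx(20.9)
        assert res.total_length_m == pytest.approx(899.9)

    def test_dominance_prefers_cool_parallel_edge(self):
        sg = StreetGraph()
        sg.add_node("s", 0, 0)
        sg.add_node("m1", 50, 50)
        sg.add_node("m2", 50, -50)
        sg.add_node("t", 100, 0)
        sg.add_edge("hot1", "s", "m1", 100.0, 39.0, 40.0)
        sg.add_edge("hot2", "m1", "t", 100.0, 39.0, 40.0)
        sg.add_edge("cool1", "s", "m2", 100.0, 20.0, 24.0)
        sg.add_edge("cool2", "m2", "t", 100.0, 20.0, 24.0)
        res = best_tolerance_route(sg, "s", "t")
        assert res.nodes == ["s", "m2", "t"]
        assert res.terminal_rt == 60.0

    def test_origin_equals_dest(self, route_graph):
        res = best_tolerance_route(route_graph, "a", "a")
        assert res.feasible and res.nodes == ["a"]
        assert res.terminal_rt == 60.0

    def test_disconnected_is_infeasible(self, route_graph):
        route_graph.add_node("island", 9999, 9999)
        res = best_tolerance_route(route_graph, "a", "island")
        assert not res.feasible and res.terminal_rt is None

    def test_budget_excludes_long_routes(self, route_graph):
        res = best_tolerance_route(route_graph, "a", "h", budget_m=500.0)
        assert not res.feasible

    def test_matches_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(60):
            sg = random_street_graph(rng, max_nodes=8)
            nodes = sorted(sg.graph.nodes)
            origin, dest = nodes[0], nodes[-1]
            budget = float(rng.uniform(200, 900))
            expected = oracle_best_route(sg, origin, dest, budget)
            got = best_tolerance_route(sg, origin, dest, budget_m=budget)
            if expected is None:
                assert not got.feasible
            else:
                checked += 1
                assert got.feasible
                assert got.terminal_rt == pytest.approx(expected[0], abs=1e-9)
                assert got.total_length_m <= budget + 1e-9
        assert checked > 20

    def test_budget_monotone_and_bounded_by_h(self, route_graph):
        prev = None
        for budget in (400.0, 600.0, 900.0, 2000.0):
            res = best_tolerance_route(route_graph, "a", "g", budget_m=budget)
            if not res.feasible:
                continue
            assert res.terminal_rt <= 60.0 + 1e-9
            if prev is not None:
                assert res.terminal_rt >= prev - 1e-9  # larger budget never hurts
            prev = res.terminal_rt

    def test_uniform_stress_reduces_to_shortest_path(self):
        rng = np.random.default_rng(5)
        sg = random_street_graph(rng, max_nodes=8)
        for _, _, d in sg.graph.edges(data=True):
            d["utci_min"], d["utci_max"] = 34.0, 36.0  # all level 2
        for _, _, d in sg.graph.edges(data=True):
            d["qdur"] = oracle_duration(d["length_m"])  # per-edge quantised minutes
        nodes = sorted(sg.graph.nodes)
        res = best_tolerance_route(sg, nodes[0], nodes[-1], budget_m=1e9)
        assert res.feasible
        sp_dur = nx.shortest_path_length(sg.graph, nodes[0], nodes[-1], weight="qdur")
        assert res.trajectory.terminal_stress == pytest.approx(2 * sp_dur, abs=1e-9)


class TestWalkabilityMap:
    def test_reference_chain_edge_values(self, route_graph):
        wmap = walkability_map(route_graph, "a")
        expected = dict(
            zip(
                [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f"), ("f", "g"), ("g", "h")],
                [57.6, 48.9, 47.3, 44.6, 29.9, 29.5, 20.9],
            )
        )
        assert set(wmap.values) == set(expected)
        for k, v in expected.items():
            assert wmap.values[k] == pytest.approx(v)
        assert wmap.unreachable == []

    def test_star_symmetry(self):
        sg = StreetGraph()
        sg.add_node("c", 0, 0)
        for i in range(4):
            sg.add_node(f"t{i}", 100 * (i + 1), 0)
            sg.add_edge(f"sp{i}", "c", f"t{i}", 150.0, 34.0, 37.0)
        wmap = walkability_map(sg, "c")
        vals = {round(v, 6) for v in wmap.values.values()}
        assert len(vals) == 1

    def test_matches_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            sg = random_street_graph(rng, max_nodes=7)
            origin = sorted(sg.graph.nodes)[0]
            budget = float(rng.uniform(200, 900))
            for statistic in ("max", "min"):
                expected = oracle_edge_values(sg, origin, budget, statistic=statistic)
                got = walkability_map(sg, origin, budget_m=budget, statistic=statistic)
                assert set(got.values) == set(expected)
                for k, v in expected.items():
                    assert got.values[k] == pytest.approx(v, abs=1e-9), (k, statistic)

    def test_consistent_with_point_route_search(self, route_graph):
        wmap = walkability_map(route_graph, "a")
        for (u, v), val in wmap.values.items():
            best_end = max(
                best_tolerance_route(route_graph, "a", end).terminal_rt for end in (u, v)
            )
            assert val <= best_end + 1e-9


class TestBinning:
    @pytest.mark.parametrize(
        "rt, label",
        [
            (57.6, "45-60"),
            (20.9, "15-30"),
            (45.0, "45-60"),
            (30.0, "30-45"),
            (7.0, "0-15"),
            (0.0, "0-15"),
            (-3.0, "exhausted"),
        ],
    )
    def test_default_bins(self, rt, label):
        assert bin_rt(rt) == label

    def test_above_budget_rejected(self):
        with pytest.raises(InvalidInputError):
            bin_rt(61.0)

    def test_custom_cutpoints(self):
        assert bin_rt(35.0, cutpoints=(40.0, 20.0, 10.0)) == "20-40"


class TestMapIO:
    def test_save_reload_values(self, tmp_path, route_graph):
        wmap = walkability_map(route_graph, "a")
        out = tmp_path / "map.geojson"
        save_map(wmap, route_graph, out)
        doc = json.loads(out.read_text())
        assert len(doc["features"]) == 7
        bins = {f["properties"]["edge_id"]: f["properties"]["bin"] for f in doc["features"]}
        assert bins["ab"] == "45-60" and bins["gh"] == "15-30"
        back = load_map(out)
        assert back.origin == "a"
        for k, v in wmap.values.items():
            assert back.values[k] == pytest.approx(v)


def test_duration_budget_identity():
    """A 15-minute budget at 1 m/s is the default 900 m distance budget."""
    assert duration_budget_m(15.0) == DEFAULT_BUDGET_M == 900.0
    fast = duration_budget_m(15.0, params=None)
    assert fast == 900.0
    with pytest.raises(InvalidInputError):
        duration_budget_m(0.0)


def test_edge_key_is_order_free():
    assert edge_key("b", "a") == edge_key("a", "b") == ("a", "b")
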