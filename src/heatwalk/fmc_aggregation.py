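"""District-wide (15-minute-city) walkability from per-neighbourhood maps.

Each neighbourhood contributes a walkability map computed from its own
entrance (:func:`heatwalk.route_engine.walkability_map`). The district
score of a street edge is the population-weighted convex combination of
the per-neighbourhood R_t values,

    W(e) = sum_i k_i * R_t,i(e),    k_i = P_i / sum_j P_j,

restricted — with renormalised weights — to the neighbourhoods whose
entrance can actually reach the edge within the budget. Only population
ratios matter, so populations may be given in persons or thousands.

Scored edges are then classed for public-service siting: services people
visit daily belong on the streets with the most remaining heat-stress
budget, rarely-visited ones can sit where the budget runs low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .route_engine import DEFAULT_RT_CUTPOINTS, EdgeKey, WalkabilityMap

__all__ = [
    "SERVICE_CLASSES",
    "NeighborhoodWeightTable",
    "FmcWalkabilityMap",
    "population_weights",
    "read_populations",
    "aggregate_walkability",
    "service_siting",
]

SERVICE_CLASSES = ("frequently-used", "often-used", "occasionally-used", "unsuitable")


@dataclass
class NeighborhoodWeightTable:
    """Neighbourhood populations P_i and their normalised weights k_i."""

    ids: List[str]
    populations: np.ndarray
    weights: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    def weight(self, neighborhood_id: str) -> float:
        return float(self.weights[self.ids.index(str(neighborhood_id))])

    def rounded(self, decimals: int = 2) -> pd.Series:
        """Display view of the weights; may not sum to 1 after rounding."""
        return pd.Series(np.round(self.weights, decimals), index=self.ids, name="k_i")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"population": self.populations, "k_i": self.weights}, index=self.ids
        )


def population_weights(populations, ids=None) -> NeighborhoodWeightTable:
    """Normalise neighbourhood populations into weights k_i = P_i / sum P_j.

    ``populations`` may be a sequence, dict or Series (dict/Series keys
    become the neighbourhood ids). Weights are exact (sum to 1 within
    1e-9); :meth:`NeighborhoodWeightTable.rounded` gives the 2-decimal
    presentation view.
    """
    if isinstance(populations, Mapping):
        if ids is not None:
            raise InvalidInputError("pass ids either in the mapping or separately, not both")
        ids = list(populations.keys())
        pops = np.asarray([populations[k] for k in ids], dtype=float)
    elif isinstance(populations, pd.Series):
        ids = list(populations.index) if ids is None else list(ids)
        pops = populations.to_numpy(dtype=float)
    else:
        pops = np.asarray(list(populations), dtype=float)
        ids = [f"N{i}" for i in range(len(pops))] if ids is None else list(ids)
    if pops.size == 0:
        raise InvalidInputError("need at least one neighbourhood")
    if len(ids) != pops.size:
        raise InvalidInputError("ids and populations differ in length")
    if not np.all(np.isfinite(pops)) or np.any(pops < 0):
        raise InvalidInputError("populations must be finite and >= 0")
    total = pops.sum()
    if total <= 0:
        raise InvalidInputError("total population must be > 0")
    weights = pops / total
    assert abs(weights.sum() - 1.0) < 1e-9
    return NeighborhoodWeightTable(ids=[str(i) for i in ids], populations=pops, weights=weights)


def read_populations(path) -> NeighborhoodWeightTable:
    """Load a populations CSV with columns neighborhood_id, population."""
    df = pd.read_csv(path)
    for col in ("neighborhood_id", "population"):
        if col not in df.columns:
            raise InvalidInputError(f"populations file {path} missing column {col!r}")
    return population_weights(df["population"].to_numpy(), ids=df["neighborhood_id"].astype(str))


@dataclass
class FmcWalkabilityMap:
    """Aggregated district map: weighted score W(e) per edge."""

    values: Dict[EdgeKey, float]
    contributing: Dict[EdgeKey, int]
    unscored: List[EdgeKey]
    h: float
    edge_ids: Dict[EdgeKey, str]

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(set(self.values) | set(self.unscored))
        return pd.DataFrame(
            {
                "edge_id": [self.edge_ids.get(k, f"{k[0]}-{k[1]}") for k in keys],
                "from_node": [k[0] for k in keys],
                "to_node": [k[1] for k in keys],
                "w": [self.values.get(k) for k in keys],
                "contributing": [self.contributing.get(k, 0) for k in keys],
            }
        )


def aggregate_walkability(
    maps: Mapping[str, WalkabilityMap],
    weights: NeighborhoodWeightTable,
    unreachable_as_zero: bool = False,
) -> FmcWalkabilityMap:
    """Combine per-neighbourhood walkability maps into one district map.

    ``maps`` keys are neighbourhood ids and must each have a weight. For
    every edge, W(e) is the convex combination of the R_t values of the
    neighbourhoods that reach it, with weights renormalised over that
    subset; edges reachable from no origin are flagged unscored. With
    ``unreachable_as_zero`` the alternative reading is used: unreachable
    neighbourhoods contribute R_t = 0 and no renormalisation occurs.
    """
    if not maps:
        raise InvalidInputError("need at least one walkability map")
    missing = [k for k in maps if str(k) not in weights.ids]
    if missing:
        raise InvalidInputError(f"no population weight for map origin(s) {missing}")
    h_values = {m.h for m in maps.values()}
    if len(h_values) != 1:
        raise InvalidInputError(f"maps disagree on H: {sorted(h_values)}")
    all_edges = [set(m.values) | set(m.unreachable) for m in maps.values()]
    if any(e != all_edges[0] for e in all_edges[1:]):
        raise InvalidInputError("maps cover different edge sets; they must share one graph")

    edge_ids: Dict[EdgeKey, str] = {}
    for m in maps.values():
        edge_ids.update(m.edge_ids)

    values: Dict[EdgeKey, float] = {}
    contributing: Dict[EdgeKey, int] = {}
    unscored: List[EdgeKey] = []
    for e in sorted(all_edges[0]):
        num, den, cnt = 0.0, 0.0, 0
        for nid, m in maps.items():
            k_i = weights.weight(nid)
            if e in m.values:
                num += k_i * m.values[e]
                den += k_i
                cnt += 1
            elif unreachable_as_zero:
                den += k_i
        contributing[e] = cnt
        if cnt == 0:
            unscored.append(e)
        else:
            values[e] = num / den if den > 0 else math.nan
    h = next(iter(h_values))
    return FmcWalkabilityMap(
        values=values, contributing=contributing, unscored=unscored, h=h, edge_ids=edge_ids
    )


def service_siting(
    fmc_map: FmcWalkabilityMap,
    cutpoints: Tuple[float, float, float] = DEFAULT_RT_CUTPOINTS,
) -> Dict[EdgeKey, str]:
    """Class each edge for public-service placement from its score W(e).

    Top bin (W >= 45 by default) -> frequently-used; next -> often-used;
    next -> occasionally-used; below the last cut, or unscored -> unsuitable.
    Classes are a pure function of W and the cut points: re-siting with
    different cuts needs no re-aggregation.
    """
    c1, c2, c3 = sorted((float(c) for c in cutpoints), reverse=True)
    classes: Dict[EdgeKey, str] = {}
    for e in sorted(set(fmc_map.values) | set(fmc_map.unscored)):
        w = fmc_map.values.get(e)
        if w is None or not math.isfinite(w) or w < c3:
            classes[e] = "unsuitable"
        elif w >= c1:
            classes[e] = "frequently-used"
        elif w >= c2:
            classes[e] = "often-used"
        else:
            classes[e] = "occasionally-used"
    return classes
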