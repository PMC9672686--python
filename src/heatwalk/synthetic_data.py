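"""Synthetic study inputs: UTCI rasters, street networks, survey panels.

Real inputs to the walkability pipeline are a microclimate simulation
(a UTCI raster over the district), a street network, and a walking-survey
panel. None are bundled; this module generates statistically similar
stand-ins so every other module can be exercised end to end.

The UTCI field generator does not model any physics. It reproduces the
*statistical* signature of late-afternoon summer UTCI maps of a dense
subtropical district: values in roughly the 31–41 degC band (strong to
very strong heat stress), smooth spatial correlation, cooler riverside
and tree-shaded corridors, and warmer east-west street canyons that
collect direct sun. Each qualitative feature is a boolean mask with an
additive temperature offset on top of a smoothed Gaussian random field.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString

from .errors import InvalidInputError
from .route_engine import StreetGraph
from .survey_tolerance import SurveyPanel

__all__ = [
    "DEFAULT_FEATURE_EFFECTS",
    "DEFAULT_SURVEY_ONSETS",
    "UtciField",
    "SurveyGenSpec",
    "gen_utci_field",
    "sample_edge_utci",
    "gen_network",
    "gen_chain",
    "gen_survey",
    "save_field_txt",
    "load_field_txt",
]

#: Additive UTCI offsets (degC) of the qualitative spatial features.
DEFAULT_FEATURE_EFFECTS = {"water": -3.0, "tree_shade": -2.5, "ew_canyon": 3.0}

#: Discomfort-category onset minutes (categories 2, 3, 4) per heat level,
#: as observed in 15-minute walking panels: level 1 stays "slightly
#: uncomfortable" throughout; level 4 reaches extreme discomfort at
#: minute 13.
DEFAULT_SURVEY_ONSETS = {
    1: (None, None, None),
    2: (9, None, None),
    3: (6, 12, None),
    4: (5, 8, 13),
}


@dataclass
class UtciField:
    """A UTCI raster (degC) with qualitative feature masks.

    ``values[row, col]`` covers the square cell with x in
    ``[col*cell, (col+1)*cell)`` and y in ``[row*cell, (row+1)*cell)``,
    planar metre coordinates, origin at the south-west corner.
    """

    values: np.ndarray
    cell_size: float
    masks: Dict[str, np.ndarray] = dc_field(default_factory=dict)
    seed: Optional[int] = None
    band: Tuple[float, float] = (28.0, 44.0)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> Tuple[float, float]:
        """(width, height) in metres."""
        rows, cols = self.values.shape
        return cols * self.cell_size, rows * self.cell_size

    def sample(self, x: float, y: float) -> float:
        """Nearest-cell UTCI at planar coordinates (x, y)."""
        rows, cols = self.values.shape
        col = int(x / self.cell_size)
        row = int(y / self.cell_size)
        if not (0 <= col < cols and 0 <= row < rows):
            raise InvalidInputError(f"point ({x}, {y}) outside the raster extent")
        return float(self.values[row, col])


def gen_utci_field(
    rows: int = 100,
    cols: int = 100,
    cell_size: float = 8.0,
    base: float = 36.0,
    amplitude: float = 2.0,
    corr_length_m: float = 40.0,
    effects: Optional[Dict[str, float]] = None,
    band: Tuple[float, float] = (28.0, 44.0),
    seed: Optional[int] = None,
) -> UtciField:
    """Generate a spatially correlated synthetic UTCI raster.

    A standard-normal field is smoothed with a Gaussian kernel of scale
    ``corr_length_m``, rescaled to standard deviation ``amplitude`` and
    added to ``base``; the feature masks (western riverside strip,
    scattered tree-shade blobs, periodic east-west canyon rows — mutually
    disjoint) then shift their cells by ``effects`` and the result is
    clipped to ``band``. Defaults give edge classifications spanning
    heat-stress levels 1–3 over an 800 m square at the 8 m resolution
    typical of street-canyon microclimate runs.
    """
    if rows < 1 or cols < 1:
        raise InvalidInputError(f"grid must be non-empty, got {rows}x{cols}")
    if cell_size <= 0:
        raise InvalidInputError("cell_size must be > 0")
    effects = DEFAULT_FEATURE_EFFECTS if effects is None else effects
    if any(not math.isfinite(v) for v in effects.values()):
        raise InvalidInputError("feature effects must be finite")
    rng = np.random.default_rng(seed)

    values = np.full((rows, cols), float(base))
    if amplitude > 0:
        noise = rng.standard_normal((rows, cols))
        sigma = max(corr_length_m / cell_size, 1e-6)
        smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            values = values + smooth * (amplitude / sd)
    else:
        rng.standard_normal((rows, cols))  # keep the stream position seed-stable

    water = np.zeros((rows, cols), dtype=bool)
    water[:, : max(1, cols // 10)] = True

    blob_noise = ndimage.gaussian_filter(
        rng.standard_normal((rows, cols)), sigma=max(corr_length_m / cell_size, 1e-6)
    )
    tree = (blob_noise > np.quantile(blob_noise, 0.8)) & ~water

    canyon = np.zeros((rows, cols), dtype=bool)
    stripe = max(2, rows // 10)
    for r0 in range(0, rows, 3 * stripe):
        canyon[r0 : r0 + stripe, :] = True
    canyon &= ~water & ~tree

    masks = {"water": water, "tree_shade": tree, "ew_canyon": canyon}
    for name, mask in masks.items():
        values = values + float(effects.get(name, 0.0)) * mask
    values = np.clip(values, band[0], band[1])
    return UtciField(values=values, cell_size=float(cell_size), masks=masks, seed=seed, band=band)


def save_field_txt(field: UtciField, path) -> None:
    """Write a UTCI raster as a plain-text grid with a one-line header."""
    with open(path, "w") as f:
        f.write(f"# cell_size={field.cell_size} band={field.band[0]},{field.band[1]}\n")
        np.savetxt(f, field.values, fmt="%.4f")


def load_field_txt(path) -> UtciField:
    """Reload a raster written by :func:`save_field_txt` (masks are not kept)."""
    with open(path) as f:
        header = f.readline()
        values = np.loadtxt(f)
    meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
    lo, hi = (float(x) for x in meta["band"].split(","))
    return UtciField(
        values=np.atleast_2d(values), cell_size=float(meta["cell_size"]), band=(lo, hi)
    )


def sample_edge_utci(field: UtciField, sg: StreetGraph, step: Optional[float] = None) -> StreetGraph:
    """Attach per-edge utci_min/utci_max by sampling the raster along edges.

    Each edge's polyline (its stored geometry, or the straight segment
    between its endpoints) is sampled every ``step`` metres (default: the
    cell size) plus both endpoints; the min and max of the samples become
    the edge's UTCI range. Errors name any edge leaving the raster extent.
    """
    step = field.cell_size if step is None else float(step)
    if step <= 0:
        raise InvalidInputError("step must be > 0")
    for u, v, data in sg.graph.edges(data=True):
        coords = data.get("geometry") or [sg.node_xy(u), sg.node_xy(v)]
        line = LineString(coords)
        distances = np.arange(0.0, line.length, step)
        points = [line.interpolate(d) for d in distances] + [line.interpolate(line.length)]
        try:
            samples = [field.sample(p.x, p.y) for p in points]
        except InvalidInputError as err:
            raise InvalidInputError(
                f"edge {data['edge_id']} leaves the raster extent: {err}"
            ) from None
        data["utci_min"] = float(min(samples))
        data["utci_max"] = float(max(samples))
    return sg


def gen_network(
    kind: str = "grid",
    rows: int = 5,
    cols: int = 5,
    edge_len_m: float = 100.0,
    seed: Optional[int] = None,
) -> StreetGraph:
    """Generate a planar connected street network.

    ``grid`` builds a rows x cols block grid — (rows+1)*(cols+1)
    intersections; ``rows=0`` degenerates to a chain of ``cols`` edges.
    ``radial`` builds ``cols`` straight spokes of ``rows`` edges each
    around a central node. Coordinates are planar metres; ``seed`` is
    accepted for interface symmetry with the other generators (the
    construction itself is deterministic).
    """
    if kind not in ("grid", "radial", "chain"):
        raise InvalidInputError(f"kind must be grid|radial|chain, got {kind!r}")
    if edge_len_m <= 0:
        raise InvalidInputError("edge_len_m must be > 0")
    sg = StreetGraph()
    if kind == "chain":
        return gen_chain([edge_len_m] * max(1, cols))
    if kind == "grid":
        if rows < 0 or cols < 1:
            raise InvalidInputError("grid needs rows >= 0 and cols >= 1")
        for r in range(rows + 1):
            for c in range(cols + 1):
                sg.add_node(f"n{r}_{c}", c * edge_len_m, r * edge_len_m)
        eid = 0
        for r in range(rows + 1):
            for c in range(cols + 1):
                if c < cols:
                    sg.add_edge(f"e{eid}", f"n{r}_{c}", f"n{r}_{c + 1}", edge_len_m)
                    eid += 1
                if r < rows:
                    sg.add_edge(f"e{eid}", f"n{r}_{c}", f"n{r + 1}_{c}", edge_len_m)
                    eid += 1
        sg.set_entrances(["n0_0"])
        return sg
    # radial: cols spokes of rows edges
    if rows < 1 or cols < 1:
        raise InvalidInputError("radial needs rows >= 1 and cols >= 1")
    sg.add_node("c", 0.0, 0.0)
    eid = 0
    for s in range(cols):
        angle = 2 * math.pi * s / cols
        prev = "c"
        for d in range(1, rows + 1):
            nid = f"s{s}_{d}"
            sg.add_node(nid, d * edge_len_m * math.cos(angle), d * edge_len_m * math.sin(angle))
            sg.add_edge(f"e{eid}", prev, nid, edge_len_m)
            eid += 1
            prev = nid
    sg.set_entrances(["c"])
    return sg


def gen_chain(edge_lengths_m, node_ids=None) -> StreetGraph:
    """Build a chain network from per-edge lengths (route-style fixture)."""
    lengths = [float(x) for x in edge_lengths_m]
    if not lengths:
        raise InvalidInputError("need at least one edge length")
    n = len(lengths) + 1
    if node_ids is None:
        node_ids = [f"n{i}" for i in range(n)]
    node_ids = [str(x) for x in node_ids]
    if len(node_ids) != n:
        raise InvalidInputError(f"need {n} node ids for {len(lengths)} edges")
    sg = StreetGraph()
    x = 0.0
    sg.add_node(node_ids[0], 0.0, 0.0)
    for i, length in enumerate(lengths):
        x += length
        sg.add_node(node_ids[i + 1], x, 0.0)
        sg.add_edge(f"e{i}", node_ids[i], node_ids[i + 1], length)
    sg.set_entrances([node_ids[0]])
    return sg


@dataclass(frozen=True)
class SurveyGenSpec:
    """Specification of a synthetic walking-survey panel.

    ``onsets[level]`` gives the true onset minutes of discomfort
    categories 2, 3 and 4 (None = never reached; category 1 starts at
    minute 1). Responses are the true category flipped one step up or
    down with probability ``noise_prob`` (clamped to 1–4). Defaults match
    the study conditions: 128 respondents, 15-minute protocol.
    """

    n_respondents: int = 128
    onsets: Dict[int, Tuple[Optional[int], Optional[int], Optional[int]]] = dc_field(
        default_factory=lambda: dict(DEFAULT_SURVEY_ONSETS)
    )
    noise_prob: float = 0.1
    max_minute: int = 15
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_respondents < 1:
            raise InvalidInputError("need >= 1 respondent")
        if not 0 <= self.noise_prob <= 1:
            raise InvalidInputError("noise_prob must be in [0, 1]")
        for level, ons in self.onsets.items():
            if len(ons) != 3:
                raise InvalidInputError(f"level {level}: need onsets for categories 2-4")
            seen = [o for o in ons if o is not None]
            if any(not 1 <= o <= self.max_minute for o in seen):
                raise InvalidInputError(f"level {level}: onsets must lie in 1-{self.max_minute}")
            if any(b < a for a, b in zip(seen, seen[1:])):
                raise InvalidInputError(f"level {level}: onsets must be nondecreasing")
            trailing = [o is None for o in ons]
            if trailing != sorted(trailing):
                raise InvalidInputError(
                    f"level {level}: a reached category cannot follow an unreached one"
                )
        for lo_level, hi_level in zip(sorted(self.onsets), sorted(self.onsets)[1:]):
            for a, b in zip(self.onsets[lo_level], self.onsets[hi_level]):
                if a is not None and b is not None and b > a:
                    raise InvalidInputError(
                        f"level {hi_level} onsets must not lag level {lo_level}"
                    )
                if a is not None and b is None:
                    raise InvalidInputError(
                        f"level {hi_level} must reach every category level {lo_level} reaches"
                    )


def true_category(spec: SurveyGenSpec, level: int, minute: int) -> int:
    """Noise-free discomfort category at (level, minute) under a spec."""
    ons = spec.onsets[level]
    return 1 + sum(1 for o in ons if o is not None and minute >= o)


def gen_survey(spec: Optional[SurveyGenSpec] = None) -> SurveyPanel:
    """Generate a synthetic ordinal survey panel under a :class:`SurveyGenSpec`."""
    spec = spec or SurveyGenSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    levels = sorted(spec.onsets)
    for resp in range(spec.n_respondents):
        rid = f"r{resp:03d}"
        for level in levels:
            for minute in range(1, spec.max_minute + 1):
                cat = true_category(spec, level, minute)
                if spec.noise_prob > 0 and rng.random() < spec.noise_prob:
                    cat = int(np.clip(cat + rng.choice((-1, 1)), 1, 4))
                rows.append((rid, level, minute, cat))
    df = pd.DataFrame(rows, columns=["respondent_id", "heat_level", "minute", "discomfort"])
    return SurveyPanel(df, max_minute=spec.max_minute)
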