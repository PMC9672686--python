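"""Cumulative heat-stress budget arithmetic for pedestrians.

The model tracks a walker's heat-stress *dose* along a route. Each street
segment is assigned an integer heat-stress level ``L_HS`` in 0–4 from the
UTCI (Universal Thermal Climate Index) it exposes the walker to, using the
standard UTCI heat bands:

===========  =======================  =====
UTCI (degC)  category                 level
===========  =======================  =====
<= 26        no thermal stress        0
26–32        moderate heat stress     1
32–38        strong heat stress       2
38–46        very strong heat stress  3
> 46         extreme heat stress      4
===========  =======================  =====

Walking a segment of length ``l`` at speed ``v`` for ``t = l / v`` minutes
adds ``L_HS * t`` *stress-minutes* to the cumulative stress

    S_t = sum_i L_HS,i * t_i

and the remaining tolerant heat discomfort is

    R_t = H - S_t

where ``H`` is the walker's total stress budget (default 60 stress-minutes,
calibrated from walking surveys at the extreme stress level; see
:mod:`heatwalk.survey_tolerance`). R_t is the walkability currency of a
route: when it hits zero the walker has to stop and recover.

Durations are quantised to a time quantum (default 0.1 min), rounded UP —
a 44.8 m segment at 1 m/s is booked as 0.8 min, not 0.7 — so the dose is
never understated. A segment whose UTCI varies along its length is scored
at its worst (maximum) UTCI for the same reason. Cold bands contribute no
stress: cold discomfort is outside this model.

Level-0 segments can optionally *recover* budget at ``recovery_rate``
stress-minutes per minute (floored so S_t never goes negative). The default
rate is 0, i.e. stress only accumulates or holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "DEFAULT_BREAKPOINTS",
    "DEFAULT_LEVEL_LABELS",
    "HeatStressScale",
    "ToleranceParams",
    "SegmentExposure",
    "StressTrajectory",
    "RemainingTolerance",
    "classify_level",
    "segment_level",
    "walk_duration",
    "cumulative_stress",
    "remaining_tolerance",
    "evaluate_route",
    "read_segments",
    "write_trajectory",
]

#: UTCI thresholds (degC) separating heat-stress levels 0|1|2|3|4.
DEFAULT_BREAKPOINTS = (26.0, 32.0, 38.0, 46.0)

DEFAULT_LEVEL_LABELS = (
    "no thermal stress",
    "moderate heat stress",
    "strong heat stress",
    "very strong heat stress",
    "extreme heat stress",
)

_EPS = 1e-9


@dataclass(frozen=True)
class HeatStressScale:
    """Ordered UTCI breakpoints defining heat-stress levels 0–4.

    A UTCI value exactly on a breakpoint maps to the *higher* level: the
    conservative choice for a safety-oriented dose model.
    """

    breakpoints: tuple = DEFAULT_BREAKPOINTS
    labels: tuple = DEFAULT_LEVEL_LABELS

    def __post_init__(self):
        bp = tuple(float(b) for b in self.breakpoints)
        if len(bp) != 4:
            raise InvalidInputError(
                f"expected exactly 4 breakpoints defining 5 levels, got {len(bp)}"
            )
        if any(not math.isfinite(b) for b in bp):
            raise InvalidInputError("breakpoints must be finite")
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise InvalidInputError(f"breakpoints must be strictly increasing: {bp}")
        if len(self.labels) != 5:
            raise InvalidInputError("expected 5 level labels")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "labels", tuple(self.labels))

    def classify(self, utci: float) -> int:
        return classify_level(utci, self)


@dataclass(frozen=True)
class ToleranceParams:
    """Walker parameters: stress budget and kinematics.

    Parameters
    ----------
    h : float
        Maximum tolerant heat discomfort H, in stress-minutes (default 60).
    walking_speed : float
        Walking speed in m/s (default 1.0).
    time_quantum : float
        Duration resolution in minutes (default 0.1).
    duration_rounding : str
        ``"ceil"`` (default) rounds durations up to the quantum;
        ``"nearest"`` rounds to the closest multiple.
    recovery_rate : float
        Stress-minutes recovered per minute spent on level-0 segments
        (default 0: no quantified alleviation).
    """

    h: float = 60.0
    walking_speed: float = 1.0
    time_quantum: float = 0.1
    duration_rounding: str = "ceil"
    recovery_rate: float = 0.0

    def __post_init__(self):
        if not (math.isfinite(self.h) and self.h > 0):
            raise InvalidInputError(f"H must be > 0, got {self.h}")
        if not (math.isfinite(self.walking_speed) and self.walking_speed > 0):
            raise InvalidInputError(f"walking_speed must be > 0, got {self.walking_speed}")
        if not (math.isfinite(self.time_quantum) and self.time_quantum > 0):
            raise InvalidInputError(f"time_quantum must be > 0, got {self.time_quantum}")
        if self.duration_rounding not in ("ceil", "nearest"):
            raise InvalidInputError(
                f"duration_rounding must be 'ceil' or 'nearest', got {self.duration_rounding!r}"
            )
        if not (math.isfinite(self.recovery_rate) and self.recovery_rate >= 0):
            raise InvalidInputError(f"recovery_rate must be >= 0, got {self.recovery_rate}")


@dataclass
class SegmentExposure:
    """One scored street segment: level ``L_HS``, duration ``t`` and dose."""

    segment_id: str
    length_m: float
    utci_min: float
    utci_max: float
    level: int
    duration_min: float
    stress_contrib: float

    @classmethod
    def from_range(
        cls,
        segment_id: str,
        utci_min: float,
        utci_max: float,
        length_m: float,
        scale: Optional[HeatStressScale] = None,
        params: Optional[ToleranceParams] = None,
    ) -> "SegmentExposure":
        """Score a segment from its UTCI range and length with the given settings."""
        scale = scale or HeatStressScale()
        params = params or ToleranceParams()
        level = segment_level(utci_min, utci_max, scale)
        duration = walk_duration(length_m, params)
        return cls(
            segment_id=str(segment_id),
            length_m=float(length_m),
            utci_min=float(utci_min),
            utci_max=float(utci_max),
            level=level,
            duration_min=duration,
            stress_contrib=round(level * duration, 9),
        )


@dataclass(frozen=True)
class RemainingTolerance:
    """R_t as a raw value, a clamped-at-zero view, and an exhaustion flag."""

    raw: float
    clamped: float
    exhausted: bool


@dataclass
class StressTrajectory:
    """Per-segment dose bookkeeping along a route.

    ``cumulative_stress[i]`` is S_t after segment ``i``; ``remaining[i]`` is
    R_t = H - S_t at the same point. ``exhausted_at`` is the index of the
    first segment after which R_t <= 0 (None if the budget is never spent).
    """

    segments: list
    cumulative_stress: np.ndarray
    remaining: np.ndarray
    params: ToleranceParams
    exhausted_at: Optional[int] = field(default=None)

    @property
    def terminal_stress(self) -> float:
        return float(self.cumulative_stress[-1]) if len(self.segments) else 0.0

    @property
    def terminal_rt(self) -> float:
        return float(self.remaining[-1]) if len(self.segments) else self.params.h

    @property
    def total_distance_m(self) -> float:
        return float(sum(s.length_m for s in self.segments))

    @property
    def total_duration_min(self) -> float:
        return round(sum(s.duration_min for s in self.segments), 9)

    @property
    def exhausted(self) -> bool:
        return self.exhausted_at is not None

    def to_frame(self) -> pd.DataFrame:
        """Tabulate the trajectory, one row per segment."""
        return pd.DataFrame(
            {
                "segment_id": [s.segment_id for s in self.segments],
                "utci_min": [s.utci_min for s in self.segments],
                "utci_max": [s.utci_max for s in self.segments],
                "level": [s.level for s in self.segments],
                "length_m": [s.length_m for s in self.segments],
                "duration_min": [s.duration_min for s in self.segments],
                "stress_contrib": [s.stress_contrib for s in self.segments],
                "s_t": np.asarray(self.cumulative_stress, dtype=float),
                "r_t": np.asarray(self.remaining, dtype=float),
            }
        )


def classify_level(utci: float, scale: Optional[HeatStressScale] = None) -> int:
    """Map a UTCI value (degC) to a heat-stress level 0–4.

    Values at or below the first breakpoint (including all cold bands) are
    level 0; a value exactly on a breakpoint takes the higher level.
    """
    scale = scale or HeatStressScale()
    utci = float(utci)
    if not math.isfinite(utci):
        raise InvalidInputError(f"UTCI must be finite, got {utci}")
    return int(np.searchsorted(scale.breakpoints, utci, side="right"))


def segment_level(
    utci_min: float, utci_max: float, scale: Optional[HeatStressScale] = None
) -> int:
    """Heat-stress level of a segment whose UTCI spans [utci_min, utci_max].

    The worst-case (maximum) UTCI along the segment decides the level, so a
    range straddling two bands lands in the higher one.
    """
    utci_min, utci_max = float(utci_min), float(utci_max)
    if not (math.isfinite(utci_min) and math.isfinite(utci_max)):
        raise InvalidInputError("UTCI range must be finite")
    if utci_min > utci_max:
        raise InvalidInputError(f"utci_min {utci_min} exceeds utci_max {utci_max}")
    return classify_level(utci_max, scale)


def walk_duration(length_m: float, params: Optional[ToleranceParams] = None) -> float:
    """Quantised walking duration (minutes) of a segment.

    ``length_m / walking_speed`` converted to minutes and rounded (up, by
    default) to the nearest ``time_quantum``. Exact multiples of the quantum
    are preserved rather than bumped by floating-point dust.
    """
    params = params or ToleranceParams()
    length_m = float(length_m)
    if not math.isfinite(length_m) or length_m < 0:
        raise InvalidInputError(f"length must be >= 0, got {length_m}")
    raw_min = length_m / params.walking_speed / 60.0
    k = raw_min / params.time_quantum
    k_round = round(k)
    if math.isclose(k, k_round, rel_tol=1e-9, abs_tol=1e-9):
        n = int(k_round)
    elif params.duration_rounding == "ceil":
        n = math.ceil(k)
    else:
        n = int(round(k))
    return round(n * params.time_quantum, 9)


def cumulative_stress(
    exposures: Sequence[SegmentExposure], params: Optional[ToleranceParams] = None
) -> np.ndarray:
    """Running cumulative stress S_t (stress-minutes) after each segment.

    S_t is the running sum of ``level * duration``; time on level-0 segments
    recovers ``recovery_rate`` stress-minutes per minute, floored at zero.
    With the default rate of 0 this is a plain nondecreasing dose sum.
    """
    params = params or ToleranceParams()
    trace = np.empty(len(exposures), dtype=float)
    running = 0.0
    for i, exp in enumerate(exposures):
        running += exp.stress_contrib
        if exp.level == 0 and params.recovery_rate > 0:
            running = max(0.0, running - params.recovery_rate * exp.duration_min)
        running = round(running, 9)
        trace[i] = running
    return trace


def remaining_tolerance(
    s_t: float, params: Optional[ToleranceParams] = None
) -> RemainingTolerance:
    """Remaining tolerant heat discomfort R_t = H - S_t.

    Returns the raw value (which may be negative past exhaustion), a view
    clamped at zero, and a flag set once the budget is fully spent.
    """
    params = params or ToleranceParams()
    s_t = float(s_t)
    if not math.isfinite(s_t) or s_t < 0:
        raise InvalidInputError(f"S_t must be >= 0, got {s_t}")
    raw = round(params.h - s_t, 9)
    return RemainingTolerance(raw=raw, clamped=max(0.0, raw), exhausted=raw <= _EPS)


SegmentSpec = Union[SegmentExposure, dict, tuple]


def _coerce_exposure(seg: SegmentSpec, i: int, scale, params) -> SegmentExposure:
    if isinstance(seg, SegmentExposure):
        return seg
    if isinstance(seg, dict):
        return SegmentExposure.from_range(
            seg.get("segment_id", f"s{i}"),
            seg["utci_min"],
            seg["utci_max"],
            seg["length_m"],
            scale,
            params,
        )
    if isinstance(seg, (tuple, list)):
        if len(seg) == 4:
            sid, umin, umax, length = seg
        elif len(seg) == 3:
            sid, (umin, umax, length) = f"s{i}", seg
        else:
            raise InvalidInputError(f"cannot interpret segment {seg!r}")
        return SegmentExposure.from_range(sid, umin, umax, length, scale, params)
    raise InvalidInputError(f"cannot interpret segment {seg!r}")


def evaluate_route(
    segments: Iterable[SegmentSpec],
    scale: Optional[HeatStressScale] = None,
    params: Optional[ToleranceParams] = None,
) -> StressTrajectory:
    """Score an ordered sequence of segments into a :class:`StressTrajectory`.

    Accepts ready :class:`SegmentExposure` objects, dicts with keys
    ``segment_id``/``utci_min``/``utci_max``/``length_m``, or
    ``(id, utci_min, utci_max, length_m)`` tuples. The trajectory is
    computed past exhaustion and flagged, not truncated.
    """
    scale = scale or HeatStressScale()
    params = params or ToleranceParams()
    segments = list(segments)
    if not segments:
        raise InvalidInputError("route must contain at least one segment")
    exposures = [_coerce_exposure(s, i, scale, params) for i, s in enumerate(segments)]
    s_trace = cumulative_stress(exposures, params)
    r_trace = np.round(params.h - s_trace, 9)
    below = np.nonzero(r_trace <= _EPS)[0]
    exhausted_at = int(below[0]) if below.size else None
    return StressTrajectory(
        segments=exposures,
        cumulative_stress=s_trace,
        remaining=r_trace,
        params=params,
        exhausted_at=exhausted_at,
    )


_SEGMENT_COLUMNS = ("segment_id", "utci_min", "utci_max", "length_m")


def read_segments(path) -> list:
    """Load a segment table CSV (columns segment_id, utci_min, utci_max, length_m)."""
    df = pd.read_csv(path)
    missing = [c for c in _SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"segment table {path} missing columns {missing}")
    return [
        {
            "segment_id": str(row.segment_id),
            "utci_min": float(row.utci_min),
            "utci_max": float(row.utci_max),
            "length_m": float(row.length_m),
        }
        for row in df.itertuples()
    ]


def write_trajectory(trajectory: StressTrajectory, path) -> None:
    """Write a scored trajectory as CSV with the computed dose columns."""
    trajectory.to_frame().to_csv(path, index=False)
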