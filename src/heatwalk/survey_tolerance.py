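"""Calibrating the heat-discomfort budget H from walking surveys.

The calibration experiment walks a panel of respondents for 15 minutes at
each of four constant heat-stress levels, asking every minute for an
ordinal discomfort rating:

    1 slightly uncomfortable | 2 uncomfortable | 3 very | 4 extremely

Aggregating the panel per (level, minute) gives a discomfort timeline and
the onset minute of each category. The budget H (stress-minutes) follows
from the extreme-stress condition: if extreme discomfort sets in during
minutes ``[m, 15]`` at level 4, the tolerable dose is ``4 * m`` to
``4 * 15`` stress-minutes. With onset at minute 13 this gives the band
52–60; the default policy picks the aspirational upper end, H = 60.

Internal consistency of the minute-by-minute item series is checked with
Cronbach's alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import CoverageError, InvalidInputError, UndefinedStatisticError

__all__ = [
    "DISCOMFORT_LABELS",
    "SurveyPanel",
    "DiscomfortTimeline",
    "HEstimate",
    "cronbach_alpha",
    "cronbach_alpha_by_level",
    "discomfort_timeline",
    "estimate_H",
    "calibrate_tolerance",
]

DISCOMFORT_LABELS = {
    1: "slightly uncomfortable",
    2: "uncomfortable",
    3: "very uncomfortable",
    4: "extremely uncomfortable",
}

_COLUMNS = ("respondent_id", "heat_level", "minute", "discomfort")


class SurveyPanel:
    """Ordinal discomfort responses indexed by (respondent, level, minute).

    Backed by a long-format DataFrame with columns ``respondent_id``,
    ``heat_level`` (1–4), ``minute`` (1–max_minute) and ``discomfort``
    (1–4). Panels may be incomplete per respondent, but every (level,
    minute) cell a timeline is requested for must hold at least one
    response.
    """

    def __init__(self, data: pd.DataFrame, max_minute: int = 15):
        df = pd.DataFrame(data).copy()
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise InvalidInputError(f"survey panel missing columns {missing}")
        df["heat_level"] = df["heat_level"].astype(int)
        df["minute"] = df["minute"].astype(int)
        df["discomfort"] = df["discomfort"].astype(int)
        if not df["heat_level"].between(1, 4).all():
            raise InvalidInputError("heat_level must be within 1-4")
        if not df["minute"].between(1, max_minute).all():
            raise InvalidInputError(f"minute must be within 1-{max_minute}")
        if not df["discomfort"].between(1, 4).all():
            raise InvalidInputError("discomfort must be within 1-4")
        self.data = df
        self.max_minute = int(max_minute)

    @property
    def n_respondents(self) -> int:
        return self.data["respondent_id"].nunique()

    @property
    def levels(self) -> list:
        return sorted(self.data["heat_level"].unique())

    @classmethod
    def from_csv(cls, path, max_minute: int = 15) -> "SurveyPanel":
        return cls(pd.read_csv(path), max_minute=max_minute)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def items_matrix(self, level: int) -> pd.DataFrame:
        """Respondent x minute matrix of responses at one heat level.

        Respondents with incomplete minute series at that level are
        dropped (Cronbach's alpha needs a complete matrix).
        """
        sub = self.data[self.data["heat_level"] == int(level)]
        if sub.empty:
            raise CoverageError(f"panel has no responses at heat level {level}")
        wide = sub.pivot_table(
            index="respondent_id", columns="minute", values="discomfort", aggfunc="first"
        )
        wide = wide.reindex(columns=range(1, self.max_minute + 1))
        return wide.dropna(axis=0, how="any").astype(int)


def cronbach_alpha(items) -> float:
    """Cronbach's alpha reliability of a respondent x item score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row sums),
    with sample (n-1) variances. Requires >= 2 complete items and >= 2
    respondents; a zero total-score variance leaves alpha undefined.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError("items must be a 2-D respondent x item matrix")
    n, k = X.shape
    if k < 2 or n < 2:
        raise InvalidInputError(f"need >= 2 items and >= 2 respondents, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("items matrix must be complete (no NaN)")
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedStatisticError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def cronbach_alpha_by_level(panel: SurveyPanel) -> Dict[int, float]:
    """Per-heat-level alpha over the minute-by-minute item series."""
    out = {}
    for level in panel.levels:
        try:
            out[level] = cronbach_alpha(panel.items_matrix(level))
        except UndefinedStatisticError:
            out[level] = math.nan
    return out


@dataclass
class DiscomfortTimeline:
    """Aggregate discomfort per minute at one heat level, with onsets.

    ``onsets[c]`` is the first minute whose aggregate response reaches
    category ``c`` (None if never). ``tolerated_duration`` is the last
    minute before extreme discomfort sets in (the protocol length if it
    never does); ``h_band_minutes`` is the walkable-duration band used for
    H calibration — from the extreme onset to the end of the protocol, or
    degenerate at the protocol length when extreme discomfort never
    occurs.
    """

    level: int
    per_minute: pd.Series
    onsets: Dict[int, Optional[int]]
    max_minute: int

    @property
    def tolerated_duration(self) -> int:
        onset4 = self.onsets.get(4)
        return self.max_minute if onset4 is None else onset4 - 1

    @property
    def h_band_minutes(self) -> Tuple[int, int]:
        onset4 = self.onsets.get(4)
        if onset4 is None:
            return (self.max_minute, self.max_minute)
        return (onset4, self.max_minute)


def _upper_median(values: np.ndarray) -> int:
    """Median with ties resolved to the higher category (ordinal-safe)."""
    v = np.sort(np.asarray(values))
    return int(v[len(v) // 2])


def discomfort_timeline(panel: SurveyPanel, level: int) -> DiscomfortTimeline:
    """Aggregate a panel at one heat level into a per-minute timeline.

    The per-minute aggregate is the upper median of the responses (ties
    go to the worse category). Onsets are the first minute at or above
    each category; they are automatically nondecreasing in the category.
    """
    level = int(level)
    if not 1 <= level <= 4:
        raise InvalidInputError(f"heat level must be 1-4, got {level}")
    sub = panel.data[panel.data["heat_level"] == level]
    if sub.empty:
        raise CoverageError(f"panel has no responses at heat level {level}")
    grouped = sub.groupby("minute")["discomfort"]
    agg = {}
    for minute in range(1, panel.max_minute + 1):
        if minute not in grouped.groups:
            raise CoverageError(f"no responses for (level {level}, minute {minute})")
        agg[minute] = _upper_median(grouped.get_group(minute).to_numpy())
    per_minute = pd.Series(agg, name="discomfort")
    onsets: Dict[int, Optional[int]] = {}
    for cat in (1, 2, 3, 4):
        hit = per_minute[per_minute >= cat]
        onsets[cat] = int(hit.index[0]) if len(hit) else None
    return DiscomfortTimeline(
        level=level, per_minute=per_minute, onsets=onsets, max_minute=panel.max_minute
    )


@dataclass(frozen=True)
class HEstimate:
    """Calibrated stress budget: the feasible band and the chosen value."""

    level: int
    duration_range: Tuple[float, float]
    h_range: Tuple[float, float]
    chosen: float
    policy: str


def estimate_H(
    level: int,
    tolerated_duration_range,
    policy: str = "upper",
) -> HEstimate:
    """Convert a tolerated-duration band at one stress level into H.

    Walking ``d`` minutes at level ``L`` accumulates ``L * d``
    stress-minutes, so a tolerated band ``[lo, hi]`` bounds H by
    ``[L*lo, L*hi]``. The policy picks the reported value: ``upper``
    (aspirational, default), ``midpoint`` or ``lower``.
    """
    level = int(level)
    if level == 0:
        raise InvalidInputError("H is undefined at level 0: no stress accrues")
    if not 1 <= level <= 4:
        raise InvalidInputError(f"heat level must be 1-4, got {level}")
    if policy not in ("lower", "midpoint", "upper"):
        raise InvalidInputError(f"policy must be lower|midpoint|upper, got {policy!r}")
    try:
        lo, hi = (float(tolerated_duration_range), float(tolerated_duration_range))
    except TypeError:
        lo, hi = (float(x) for x in tolerated_duration_range)
    if not (0 < lo <= hi <= 15):
        raise InvalidInputError(f"durations must lie in (0, 15], got [{lo}, {hi}]")
    h_lo, h_hi = level * lo, level * hi
    chosen = {"lower": h_lo, "upper": h_hi, "midpoint": (h_lo + h_hi) / 2}[policy]
    return HEstimate(
        level=level,
        duration_range=(lo, hi),
        h_range=(h_lo, h_hi),
        chosen=chosen,
        policy=policy,
    )


def calibrate_tolerance(
    panel: SurveyPanel, level: int = 4, policy: str = "upper"
) -> HEstimate:
    """Full calibration: timeline at ``level`` -> H band -> chosen H."""
    timeline = discomfort_timeline(panel, level)
    return estimate_H(level, timeline.h_band_minutes, policy=policy)
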