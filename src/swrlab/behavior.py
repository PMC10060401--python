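"""Behavioral measures: social discrimination, object location, elevated plus maze.

* Difference scores contrast interaction times across the three-trial
  direct social interaction test (novel 1, familiar, novel 2): the
  novelty score is N1 − F and the discrimination score is F − N2 (the
  signed form; its absolute value is also exposed, since figures often
  report the magnitude).
* The object-location discrimination ratio is
  (moved − familiar) / (moved + familiar) exploration time, bounded in
  [−1, 1] and antisymmetric under swapping the objects.
* Elevated plus maze measures are dwell times and entry counts per zone
  from a timestamped zone-transition log over a 300-s session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

EPM_SESSION_S = 300.0
EPM_ZONES = ("open", "closed", "center")

FAMILIARIZATION_CRITERION_S = 30.0
FAMILIARIZATION_MAX_S = 600.0


def difference_scores(table: pd.DataFrame, drug: str | None = None) -> pd.DataFrame:
    """Per-mouse novelty (N1 − F) and discrimination (F − N2) scores.

    ``table`` follows the behavior schema (mouse_id, genotype, virus,
    drug, trial, interaction_time).  When ``drug`` is given only that
    drug's rows are used.  A mouse missing a constituent trial gets NaN
    for the affected score rather than being dropped, so missingness
    propagates visibly into group statistics.
    """
    sub = table if drug is None else table[table["drug"] == drug]
    rows = []
    for (mouse, drg), grp in sub.groupby(["mouse_id", "drug"], sort=True):
        times = grp.set_index("trial")["interaction_time"]
        n1 = times.get("N1", math.nan)
        f = times.get("F", math.nan)
        n2 = times.get("N2", math.nan)
        meta = grp.iloc[0]
        rows.append(
            {
                "mouse_id": mouse,
                "genotype": meta["genotype"],
                "virus": meta["virus"],
                "drug": drg,
                "novelty_score": n1 - f,
                "discrimination_score": f - n2,
                "discrimination_score_abs": abs(f - n2),
            }
        )
    return pd.DataFrame(rows)


def discrimination_ratio(moved_s: float, familiar_s: float) -> float:
    """Object-location DR: (moved − familiar) / (moved + familiar).

    Undefined (raises) when the mouse explored neither object.
    """
    if moved_s < 0 or familiar_s < 0:
        raise ValueError("exploration times must be nonnegative")
    total = moved_s + familiar_s
    if total == 0:
        raise ZeroDivisionError("no object exploration: DR undefined")
    return (moved_s - familiar_s) / total


@dataclass(frozen=True)
class TimeToCriterion:
    """Time to reach the familiarization criterion, possibly censored."""

    time_s: float
    censored: bool


def familiarization_criterion(
    times_s: np.ndarray, cumulative_s: np.ndarray
) -> TimeToCriterion:
    """First time cumulative exploration reaches 30 s, censored at 600 s.

    ``cumulative_s`` must be nondecreasing.  Reaching the criterion
    exactly at the 600-s cutoff counts as reached, not censored.
    """
    times_s = np.asarray(times_s, dtype=float)
    cumulative_s = np.asarray(cumulative_s, dtype=float)
    if np.any(np.diff(cumulative_s) < 0):
        raise ValueError("cumulative exploration must be nondecreasing")
    reached = np.flatnonzero(cumulative_s >= FAMILIARIZATION_CRITERION_S)
    if reached.size:
        t = float(times_s[reached[0]])
        if t <= FAMILIARIZATION_MAX_S:
            return TimeToCriterion(time_s=t, censored=False)
    return TimeToCriterion(time_s=FAMILIARIZATION_MAX_S, censored=True)


@dataclass(frozen=True)
class EpmMeasures:
    """Elevated-plus-maze session summary over 300 s."""

    open_time: float
    closed_time: float
    center_time: float
    open_entries: int
    closed_entries: int
    percent_center: float


def epm_summarize(
    transitions: pd.DataFrame, session_s: float = EPM_SESSION_S
) -> EpmMeasures:
    """Dwell times and entry counts from a zone-transition log.

    ``transitions`` has columns (time_s, zone); each row marks the moment
    the mouse enters that zone.  The session starts with the mouse placed
    in the center, and the initial placement is not counted as an entry —
    an entry requires a transition.  Transitions must be strictly
    increasing in time and within the session.
    """
    dwell = dict.fromkeys(EPM_ZONES, 0.0)
    entries = dict.fromkeys(EPM_ZONES, 0)
    t_prev, zone_prev = 0.0, "center"
    if len(transitions):
        times = transitions["time_s"].to_numpy(dtype=float)
        zones = transitions["zone"].tolist()
        if np.any(np.diff(times) <= 0):
            raise ValueError("transition times must be strictly increasing")
        if times[0] < 0 or times[-1] > session_s:
            raise ValueError("transitions must lie within the session")
        unknown = set(zones) - set(EPM_ZONES)
        if unknown:
            raise ValueError(f"unknown zone(s) {sorted(unknown)}")
        for t, zone in zip(times, zones):
            if zone == zone_prev:
                raise ValueError("self-transition: mouse already in that zone")
            dwell[zone_prev] += t - t_prev
            entries[zone] += 1
            t_prev, zone_prev = t, zone
    dwell[zone_prev] += session_s - t_prev
    return EpmMeasures(
        open_time=dwell["open"],
        closed_time=dwell["closed"],
        center_time=dwell["center"],
        open_entries=entries["open"],
        closed_entries=entries["closed"],
        percent_center=100.0 * dwell["center"] / session_s,
    )
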