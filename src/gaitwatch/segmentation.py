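"""Bout segmentation of classified posture/stride event streams.

Bout definitions:

* **Walking bout** — a maximal run of at least 3 consecutive strides in which
  the time between two successive strides (end of one to start of the next)
  never exceeds 4 s.  The bout extends from the start of its first stride to
  the end of its last stride.  Strides outside qualifying runs are not
  counted in the daily "strides" variable.
* **Lying bout** — a maximal lying period strictly longer than 50 s.
* **Standing bout** — a period in upright position but not walking; it
  qualifies as a bout when it lasts > 50 s if the preceding state was lying
  (or the start of the recording day) and > 4 s if the preceding state was
  walking.

Sub-threshold periods contribute no bout but their time still counts toward
the state's daily total, so lying + standing + walking time always closes the
1440-min day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import DAY_SECONDS, BoutRecord, EventStream

__all__ = [
    "detect_walking_bouts", "detect_lying_bouts", "detect_standing_bouts",
    "segment", "summarize_hourly", "Segmentation",
    "MAX_STRIDE_GAP_S", "MIN_STRIDES_PER_BOUT", "MIN_STAND_AFTER_LYING_S",
    "MIN_STAND_AFTER_WALKING_S",
]

MAX_STRIDE_GAP_S = 4.0
MIN_STRIDES_PER_BOUT = 3
MIN_STAND_AFTER_LYING_S = 50.0
MIN_STAND_AFTER_WALKING_S = 4.0


def detect_walking_bouts(strides: pd.DataFrame) -> list[BoutRecord]:
    """Group time-ordered stride events into walking bouts.

    ``strides`` needs columns ``start_s`` and ``duration_ms``; events must be
    time-ordered.  Runs are split where the gap between the end of one stride
    and the start of the next exceeds 4 s; only runs of >= 3 strides qualify.
    """
    if len(strides) == 0:
        return []
    start = strides["start_s"].to_numpy(float)
    if np.any(np.diff(start) < 0):
        raise ValidationError("stride events must be time-ordered")
    end = start + strides["duration_ms"].to_numpy(float) / 1000.0
    gaps = start[1:] - end[:-1]
    breaks = np.flatnonzero(gaps > MAX_STRIDE_GAP_S)
    run_bounds = np.concatenate(([0], breaks + 1, [len(start)]))
    bouts = []
    for lo, hi in zip(run_bounds[:-1], run_bounds[1:]):
        if hi - lo >= MIN_STRIDES_PER_BOUT:
            bouts.append(BoutRecord("walking", float(start[lo]),
                                    float(end[hi - 1]), n_strides=int(hi - lo)))
    return bouts


def _merged_intervals(posture: pd.DataFrame, state: str) -> list[tuple[float, float]]:
    """Maximal intervals of one posture state (merging adjacent same-state rows)."""
    out: list[tuple[float, float]] = []
    for s, e, st in posture.itertuples(index=False):
        if st != state:
            continue
        if out and abs(out[-1][1] - s) < 1e-9:
            out[-1] = (out[-1][0], e)
        else:
            out.append((float(s), float(e)))
    return out


def detect_lying_bouts(posture: pd.DataFrame) -> list[BoutRecord]:
    """Maximal lying periods strictly longer than 50 s."""
    return [BoutRecord("lying", s, e)
            for s, e in _merged_intervals(posture, "lying")
            if e - s > MIN_STAND_AFTER_LYING_S]


def detect_standing_bouts(posture: pd.DataFrame,
                          walking_bouts: list[BoutRecord]) -> list[BoutRecord]:
    """Standing bouts: upright gaps between walking bouts, duration-qualified.

    The first gap in each upright interval follows lying (or the day start,
    treated like lying — the stricter rule) and must last > 50 s; gaps that
    start where a walking bout ended must last > 4 s.
    """
    bouts = []
    wb_iter = sorted(walking_bouts, key=lambda b: b.start_s)
    for u0, u1 in _merged_intervals(posture, "upright"):
        inside = [b for b in wb_iter if b.start_s >= u0 - 1e-9 and b.end_s <= u1 + 1e-9]
        overlapping = [b for b in wb_iter
                       if b.end_s > u0 + 1e-9 and b.start_s < u1 - 1e-9]
        if len(inside) != len(overlapping):
            raise ValidationError(
                "walking bout overlaps a non-upright interval boundary")
        t, after_walking = u0, False
        for b in inside:
            _maybe_add(bouts, t, b.start_s, after_walking)
            t, after_walking = b.end_s, True
        _maybe_add(bouts, t, u1, after_walking)
    return bouts


def _maybe_add(bouts: list[BoutRecord], start: float, end: float,
               after_walking: bool) -> None:
    dur = end - start
    if dur <= 1e-9:
        return
    threshold = (MIN_STAND_AFTER_WALKING_S if after_walking
                 else MIN_STAND_AFTER_LYING_S)
    if dur > threshold:
        bouts.append(BoutRecord("standing", start, end))


@dataclass
class Segmentation:
    """Bouts plus daily state totals for one cow-day."""

    lying_bouts: list[BoutRecord]
    standing_bouts: list[BoutRecord]
    walking_bouts: list[BoutRecord]
    lying_time_min: float
    standing_time_min: float
    walking_time_min: float

    @property
    def counted_strides(self) -> int:
        return sum(b.n_strides for b in self.walking_bouts)


def segment(stream: EventStream) -> Segmentation:
    stream.validate()
    walking = detect_walking_bouts(stream.strides)
    lying = detect_lying_bouts(stream.posture)
    standing = detect_standing_bouts(stream.posture, walking)
    lying_s = sum(e - s for s, e in _merged_intervals(stream.posture, "lying"))
    upright_s = sum(e - s for s, e in _merged_intervals(stream.posture, "upright"))
    walking_s = sum(b.duration_s for b in walking)
    return Segmentation(
        lying_bouts=lying, standing_bouts=standing, walking_bouts=walking,
        lying_time_min=lying_s / 60.0,
        standing_time_min=(upright_s - walking_s) / 60.0,
        walking_time_min=walking_s / 60.0,
    )


def _overlap_minutes(intervals, lo: float, hi: float) -> float:
    total = 0.0
    for s, e in intervals:
        total += max(0.0, min(e, hi) - max(s, lo))
    return total / 60.0


def summarize_hourly(stream: EventStream,
                     halter_hourly: pd.DataFrame | None = None) -> pd.DataFrame:
    """Convert one cow-day stream into 24 hourly summary rows.

    State durations are split across hour boundaries; bout counts are
    attributed to the hour containing the bout start; stride statistics
    (count, mean duration, mean distance) cover the counted strides — those
    inside walking bouts — starting in the hour.  Halter rows, when supplied
    (indexed 0..23), are carried through unchanged.
    """
    seg = segment(stream)
    lying_iv = _merged_intervals(stream.posture, "lying")
    upright_iv = _merged_intervals(stream.posture, "upright")
    walking_iv = [(b.start_s, b.end_s) for b in seg.walking_bouts]

    stride_start = stream.strides["start_s"].to_numpy(float)
    counted = np.zeros(len(stride_start), dtype=bool)
    for b in seg.walking_bouts:
        counted |= (stride_start >= b.start_s - 1e-9) & (stride_start <= b.end_s + 1e-9)
    sdur = stream.strides["duration_ms"].to_numpy(float)
    sdist = stream.strides["distance_cm"].to_numpy(float)

    rows = []
    for hour in range(24):
        lo, hi = hour * 3600.0, (hour + 1) * 3600.0
        walking_min = _overlap_minutes(walking_iv, lo, hi)
        upright_min = _overlap_minutes(upright_iv, lo, hi)
        in_hour = counted & (stride_start >= lo) & (stride_start < hi)
        n = int(in_hour.sum())
        rows.append({
            "cow_id": stream.cow_id, "day": stream.day, "hour": hour,
            "lying_time": _overlap_minutes(lying_iv, lo, hi),
            "standing_time": upright_min - walking_min,
            "walking_time": walking_min,
            "lying_bouts": sum(lo <= b.start_s < hi for b in seg.lying_bouts),
            "standing_bouts": sum(lo <= b.start_s < hi for b in seg.standing_bouts),
            "walking_bouts": sum(lo <= b.start_s < hi for b in seg.walking_bouts),
            "strides": n,
            "stride_duration": float(sdur[in_hour].mean()) if n else np.nan,
            "stride_distance": float(sdist[in_hour].mean()) if n else np.nan,
        })
    out = pd.DataFrame(rows)
    if halter_hourly is not None:
        halter = halter_hourly.drop(columns=[c for c in ("cow_id", "day")
                                             if c in halter_hourly.columns])
        out = out.merge(halter, on="hour", how="left")
    return out
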