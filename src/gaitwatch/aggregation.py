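"""Hourly -> daily -> averaged-summary aggregation and lameness grouping.

Daily values are sums of the 24 hourly values for every variable except
chews per minute, chews per bolus, stride duration and stride distance,
whose daily values are weighted means

    sum_h(a_h * x_h) / sum_h(x_h)

with ruminating time, boluses and strides as the respective hourly weights.
Per-cow averaged 24-hour summaries average two retained recording days
(arithmetic mean for sum variables, re-weighted mean across the two days for
the weighted variables) and recompute the derived variables from the averaged
components.  Flagged days (heat, insemination, illness) are discarded first;
a cow with fewer than two clean days is excluded.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from fractions import Fraction
from numbers import Real

import numpy as np
import pandas as pd

from .errors import ValidationError
from .variables import (BY_NAME, DERIVED_VARS, SUM_VARS, WEIGHTED_VARS,
                        lying_bout_duration, walking_speed)

__all__ = [
    "weighted_mean", "daily_summary", "averaged_summary",
    "select_days_and_sensor", "DaySelection", "compute_nrs_and_group",
    "round_nrs", "build_averaged_summaries", "NRS_GRID",
]

NRS_GRID = tuple(x / 2.0 for x in range(2, 11))   # 1.0, 1.5, ..., 5.0


def weighted_mean(values, weights) -> float:
    """sum(a_n * x_n) / sum(x_n); NaN (a flagged missing value) if no weight.

    Hours with zero weight contribute nothing; NaN values with zero weight
    are tolerated (an hour without strides has no stride duration).
    """
    a = np.asarray(values, dtype=float)
    x = np.asarray(weights, dtype=float)
    if a.shape != x.shape:
        raise ValidationError("values and weights must have equal length")
    if np.any(x < 0):
        raise ValidationError("weights must be non-negative")
    mask = x > 0
    if not mask.any():
        return float("nan")
    if np.any(np.isnan(a[mask])):
        raise ValidationError("missing value with positive weight")
    return float(np.sum(a[mask] * x[mask]) / np.sum(x[mask]))


def daily_summary(hourly: pd.DataFrame) -> dict:
    """Collapse exactly 24 hourly rows of one cow-day into a daily summary."""
    hours = sorted(hourly["hour"].tolist())
    if hours != list(range(24)):
        missing = sorted(set(range(24)) - set(hours))
        raise ValidationError(f"expected hours 0..23, missing {missing}")
    out: dict = {}
    for key in ("cow_id", "day"):
        if key in hourly.columns:
            vals = hourly[key].unique()
            if len(vals) != 1:
                raise ValidationError(f"hourly rows mix several values of {key!r}")
            out[key] = vals[0]
    for name in SUM_VARS:
        if name in hourly.columns:
            out[name] = float(hourly[name].sum())
    for name in WEIGHTED_VARS:
        wname = BY_NAME[name].weight
        if name in hourly.columns and wname in hourly.columns:
            out[name] = weighted_mean(hourly[name], hourly[wname])
    _attach_derived(out)
    return out


def _attach_derived(summary: dict) -> None:
    sd, du = summary.get("stride_distance"), summary.get("stride_duration")
    if sd is not None and du is not None and not (np.isnan(sd) or np.isnan(du)):
        summary["walking_speed_calc"] = walking_speed(sd, du)
    elif "stride_distance" in summary:
        summary["walking_speed_calc"] = float("nan")
    lt, lb = summary.get("lying_time"), summary.get("lying_bouts")
    if lt is not None and lb:
        summary["lying_bout_duration"] = lying_bout_duration(lt, lb)
    elif "lying_time" in summary:
        summary["lying_bout_duration"] = float("nan")


def averaged_summary(day_a: dict, day_b: dict) -> dict:
    """Average two daily summaries of the same cow into one record.

    Sum variables are averaged arithmetically; weighted-mean variables are
    re-weighted across the two days by their respective daily weights, which
    keeps the result equal to the statistic computed over the pooled raw
    events of both days.  Derived variables are recomputed afterwards.
    """
    if day_a.get("cow_id") != day_b.get("cow_id"):
        raise ValidationError("cannot average summaries of different cows")
    out: dict = {}
    if "cow_id" in day_a:
        out["cow_id"] = day_a["cow_id"]
    for name in SUM_VARS:
        if name in day_a and name in day_b:
            out[name] = 0.5 * (float(day_a[name]) + float(day_b[name]))
    for name in WEIGHTED_VARS:
        wname = BY_NAME[name].weight
        if name in day_a and name in day_b:
            out[name] = weighted_mean(
                [day_a[name], day_b[name]],
                [_weight_of(day_a, wname), _weight_of(day_b, wname)])
    _attach_derived(out)
    return out


def _weight_of(day: dict, wname: str) -> float:
    w = float(day.get(wname, 0.0))
    return 0.0 if np.isnan(w) else w


@dataclass(frozen=True)
class DaySelection:
    """Outcome of per-cow day/accelerometer selection (exclusion is a state)."""

    cow_id: str
    excluded: bool
    reason: str = ""
    days: tuple[int, ...] = ()
    sensor: int = 0


def _cow_rng(seed: int, cow_id: str) -> np.random.Generator:
    entropy = np.random.SeedSequence([int(seed), zlib.crc32(str(cow_id).encode())])
    return np.random.Generator(np.random.PCG64(entropy))


def select_days_and_sensor(cow_id: str, day_flags: dict[int, str], seed: int = 0,
                           n_sensors: int = 2) -> DaySelection:
    """Discard flagged days, keep 2 (random when 3 are clean), pick a sensor.

    The cow is excluded when fewer than 2 clean days remain.  All random
    choices are driven by the study seed split per cow id, so every selection
    is reproducible in isolation.
    """
    clean = sorted(d for d, f in day_flags.items() if f == "ok")
    if len(clean) < 2:
        return DaySelection(cow_id, excluded=True,
                            reason=f"only {len(clean)} clean day(s)")
    rng = _cow_rng(seed, cow_id)
    if len(clean) == 2:
        days = tuple(clean)
    else:
        days = tuple(sorted(rng.choice(clean, size=2, replace=False).tolist()))
    sensor = int(rng.integers(1, n_sensors + 1))
    return DaySelection(cow_id, excluded=False, days=days, sensor=sensor)


def round_nrs(x: Real) -> float:
    """Round a mean gait score to the nearest 0.5, ties (x.25/x.75) upward."""
    f = x if isinstance(x, Fraction) else Fraction(round(float(x) * 12), 12)
    halves = (2 * f + Fraction(1, 2)).__floor__()
    return halves / 2.0


def compute_nrs_and_group(scores) -> tuple[float, str, bool]:
    """Final gait score, lameness group and lame flag from 6 observer scores.

    The mean of the six half-point scores is rounded to the nearest 0.5;
    NRS <= 2 is non-lame (group C), 2.5–3 mildly lame (LI), 3.5 moderately
    lame (LII) and >= 4 severely lame (LIII).
    """
    scores = list(scores)
    if len(scores) != 6:
        raise ValidationError("exactly 6 observer scores are required")
    for s in scores:
        if float(s) not in NRS_GRID:
            raise ValidationError(f"score {s} outside the 1–5 half-point scale")
    mean = Fraction(int(sum(2 * float(s) for s in scores)), 12)
    nrs = round_nrs(mean)
    if nrs <= 2.0:
        group = "C"
    elif nrs <= 3.0:
        group = "LI"
    elif nrs == 3.5:
        group = "LII"
    else:
        group = "LIII"
    return nrs, group, nrs >= 2.5


def build_averaged_summaries(daily: pd.DataFrame, flags: pd.DataFrame,
                             seed: int = 0, n_sensors: int = 2,
                             sensor_col: str | None = None
                             ) -> tuple[pd.DataFrame, list[DaySelection]]:
    """Per-cow averaged summaries from a long per-cow-day daily table.

    ``daily`` needs ``cow_id``/``day`` plus variable columns (and optionally
    a sensor column when per-sensor summaries exist); ``flags`` is the
    cow-day flag table.  Returns the averaged-summary frame (one row per
    retained cow) and the per-cow selection log.
    """
    flag_map = {(r.cow_id, r.day): r.flag for r in flags.itertuples(index=False)}
    records, log = [], []
    carry = [c for c in ("group", "nrs", "lame") if c in daily.columns]
    for cow_id, sub in daily.groupby("cow_id", sort=True):
        day_ids = sorted(sub["day"].unique())
        day_flags = {d: flag_map.get((cow_id, d), "ok") for d in day_ids}
        sel = select_days_and_sensor(cow_id, day_flags, seed=seed,
                                     n_sensors=n_sensors)
        log.append(sel)
        if sel.excluded:
            continue
        picked = sub[sub["day"].isin(sel.days)]
        if sensor_col is not None and sensor_col in sub.columns:
            picked = picked[picked[sensor_col] == sel.sensor]
        rows = [r._asdict() if hasattr(r, "_asdict") else dict(r)
                for r in (picked.iloc[i] for i in range(len(picked)))]
        rows = [{**dict(r), "cow_id": cow_id} for r in rows]
        avg = averaged_summary(rows[0], rows[1])
        for c in carry:
            avg[c] = sub[c].iloc[0]
        avg["day_a"], avg["day_b"] = sel.days
        avg["sensor"] = sel.sensor
        records.append(avg)
    return pd.DataFrame(records), log
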