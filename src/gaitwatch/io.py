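"""Readers and writers for the interchange tables.

CSV is the native format; XLSX workbooks (the layout the sensor supplier's
toolchain exports) are accepted through the same reader.  Column headers are
matched through a normalised-name dictionary, so "Eating time, min/d",
"eating_time" and "Eating time" all map to the canonical ``eating_time``;
unmapped columns are reported, never silently dropped.  Times are serialised
in minutes with 2-decimal precision, durations in ms, distances in cm.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import EventStream
from .variables import BY_NAME, VARIABLES

log = logging.getLogger("gaitwatch")

__all__ = [
    "read_summary_table", "write_summary_table", "normalize_header",
    "write_event_streams", "read_event_streams", "COLUMN_ALIASES",
]

_UNIT_SUFFIXES = (
    "min_d", "1_d", "1000_d", "1_min", "1_bolus", "min_bout", "ms", "cm",
    "m_s", "s_stride", "m_stride", "min",
)


def normalize_header(header: str) -> str:
    s = re.sub(r"[^0-9a-z]+", "_", str(header).strip().lower()).strip("_")
    return s


def _alias_map() -> dict[str, str]:
    aliases: dict[str, str] = {}
    for key, canon in (("cow", "cow_id"), ("cow_id", "cow_id"),
                       ("animal", "cow_id"), ("animal_id", "cow_id"),
                       ("id", "cow_id"), ("day", "day"), ("date", "day"),
                       ("hour", "hour"), ("sensor", "sensor"),
                       ("accelerometer", "sensor"), ("nrs", "nrs"),
                       ("gait_score", "nrs"), ("group", "group"),
                       ("lame", "lame"), ("flag", "flag"),
                       ("day_a", "day_a"), ("day_b", "day_b")):
        aliases[key] = canon
    for var in VARIABLES:
        aliases[var.name] = var.name
        aliases[normalize_header(var.label)] = var.name
        aliases[normalize_header(f"{var.label}, {var.unit}")] = var.name
    # spellings seen in supplier exports
    aliases["walking_speed_calc"] = "walking_speed_calc"
    aliases["walking_speed"] = "walking_speed_calc"
    aliases["boluses"] = "bolus"
    aliases["rumination_boluses"] = "bolus"
    return aliases


COLUMN_ALIASES = _alias_map()

_MANDATORY = {
    "hourly": ("cow_id", "day", "hour"),
    "daily": ("cow_id", "day"),
    "averaged": ("cow_id",),
}

_TIME_VARS = tuple(v.name for v in VARIABLES if v.unit.startswith("min"))


def map_columns(columns) -> tuple[dict[str, str], list[str]]:
    """Map raw headers to canonical names; return (mapping, unmapped)."""
    mapping, unmapped = {}, []
    for col in columns:
        norm = normalize_header(col)
        canon = COLUMN_ALIASES.get(norm)
        if canon is None:
            for suffix in _UNIT_SUFFIXES:
                if norm.endswith("_" + suffix):
                    canon = COLUMN_ALIASES.get(norm[: -len(suffix) - 1])
                    if canon:
                        break
        if canon is None:
            unmapped.append(str(col))
        else:
            mapping[col] = canon
    return mapping, unmapped


def read_summary_table(path: str | Path, level: str = "averaged") -> pd.DataFrame:
    """Load and validate an hourly / daily / averaged summary table.

    Accepts CSV or XLSX.  Raises on empty input, missing mandatory columns
    and negative times; logs unmapped columns and basic row/cow counts.
    """
    if level not in _MANDATORY:
        raise ValidationError(f"unknown summary level {level!r}")
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        try:
            raw = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise ValidationError(f"{path}: empty input file") from exc
    if raw.empty:
        raise ValidationError(f"{path}: empty input file")
    mapping, unmapped = map_columns(raw.columns)
    if unmapped:
        log.warning("%s: unmapped columns kept as-is: %s", path.name, unmapped)
    frame = raw.rename(columns=mapping)
    for col in _MANDATORY[level]:
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing mandatory column {col!r}")
    for name in _TIME_VARS:
        if name in frame.columns and (frame[name].dropna() < 0).any():
            raise ValidationError(f"{path}: negative times in {name!r}")
    log.info("%s: %d rows, %d cows", path.name, len(frame),
             frame["cow_id"].nunique())
    return frame


def write_summary_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Serialise a summary table: times at 2 decimals, other floats at 6 sig."""
    out = frame.copy()
    for col in out.columns:
        if col in _TIME_VARS or col == "lying_bout_duration":
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{float(v):.2f}")
        elif out[col].dtype.kind == "f":
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{float(v):.6g}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


_STREAM_COLUMNS = ("cow_id", "day", "channel", "start_s", "end_s", "state",
                   "duration_ms", "distance_cm")


def write_event_streams(streams: list[EventStream], path: str | Path) -> None:
    """Event-stream CSV: one row per posture interval or stride event."""
    rows = []
    for s in streams:
        for r in s.posture.itertuples(index=False):
            rows.append((s.cow_id, s.day, "posture", round(r.start_s, 3),
                         round(r.end_s, 3), r.state, "", ""))
        for r in s.strides.itertuples(index=False):
            rows.append((s.cow_id, s.day, "stride", round(r.start_s, 3), "",
                         "", round(r.duration_ms, 3), round(r.distance_cm, 3)))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=_STREAM_COLUMNS).to_csv(path, index=False)


def read_event_streams(path: str | Path) -> list[EventStream]:
    frame = pd.read_csv(path)
    missing = set(_STREAM_COLUMNS[:4]) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    streams = []
    for (cow, day), sub in frame.groupby(["cow_id", "day"], sort=True):
        pos = sub[sub["channel"] == "posture"].sort_values("start_s")
        st = sub[sub["channel"] == "stride"].sort_values("start_s")
        stream = EventStream(
            cow_id=str(cow), day=int(day),
            posture=pos[["start_s", "end_s", "state"]].reset_index(drop=True)
            .astype({"start_s": float, "end_s": float}),
            strides=st[["start_s", "duration_ms", "distance_cm"]]
            .reset_index(drop=True).astype(float),
        )
        stream.validate()
        streams.append(stream)
    return streams


def frame_nan_report(frame: pd.DataFrame) -> dict[str, int]:
    """Count missing values per behavioural variable column."""
    return {c: int(frame[c].isna().sum()) for c in frame.columns
            if c in BY_NAME and frame[c].isna().any()}
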