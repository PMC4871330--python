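"""Shared in-memory containers for event streams and bouts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

DAY_SECONDS = 86400.0

POSTURE_COLUMNS = ("start_s", "end_s", "state")
STRIDE_COLUMNS = ("start_s", "duration_ms", "distance_cm")


@dataclass
class EventStream:
    """Classified posture/stride events for one cow-day.

    ``posture`` holds non-overlapping, contiguous intervals covering
    [0, 86400) s with state ``lying`` or ``upright``; ``strides`` holds one
    row per stride (start time within the day, duration in ms, distance in
    cm).  Strides can only occur while the cow is upright.
    """

    cow_id: str
    day: int
    posture: pd.DataFrame
    strides: pd.DataFrame

    def validate(self) -> None:
        pos = self.posture
        if list(pos.columns) != list(POSTURE_COLUMNS):
            raise ValidationError(f"posture columns must be {POSTURE_COLUMNS}")
        start = pos["start_s"].to_numpy(float)
        end = pos["end_s"].to_numpy(float)
        if len(pos) == 0:
            raise ValidationError("empty posture track")
        if not (np.all(np.diff(start) > 0) and np.all(end > start)):
            raise ValidationError("posture intervals must be ordered with end > start")
        if abs(start[0]) > 1e-6 or abs(end[-1] - DAY_SECONDS) > 1e-6:
            raise ValidationError("posture intervals must cover [0, 86400) s")
        if not np.allclose(end[:-1], start[1:], atol=1e-6):
            raise ValidationError("posture intervals must be contiguous")
        bad = set(pos["state"]) - {"lying", "upright"}
        if bad:
            raise ValidationError(f"unknown posture states: {sorted(bad)}")
        st = self.strides
        if list(st.columns) != list(STRIDE_COLUMNS):
            raise ValidationError(f"stride columns must be {STRIDE_COLUMNS}")
        if len(st):
            t = st["start_s"].to_numpy(float)
            if np.any(np.diff(t) < 0):
                raise ValidationError("stride events must be time-ordered")
            if np.any(st["duration_ms"].to_numpy(float) <= 0):
                raise ValidationError("stride durations must be positive")
            if np.any(st["distance_cm"].to_numpy(float) <= 0):
                raise ValidationError("stride distances must be positive")
            # every stride must fall in an upright interval
            idx = np.searchsorted(start, t, side="right") - 1
            states = pos["state"].to_numpy()
            if np.any(states[idx] != "upright") or np.any(t >= end[idx] + 1e-6):
                raise ValidationError("stride events must fall inside upright intervals")


@dataclass(frozen=True)
class BoutRecord:
    """One behavioural bout. ``n_strides`` is set for walking bouts only."""

    type: str          # "lying" | "standing" | "walking"
    start_s: float
    end_s: float
    n_strides: int = 0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SimCow:
    """One synthetic cow: identity, gait scores and per-day behavioural targets."""

    cow_id: str
    group: str                       # subgroup label C/LI/LII/LIII
    nrs_scores: tuple[float, ...]    # six observer scores
    nrs_final: float
    lame: bool
    days: list[dict] = field(default_factory=list)  # day -> variable targets
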