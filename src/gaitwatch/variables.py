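"""Registry of the behavioural variables recorded by the halter and leg sensors.

Every downstream stage (hourly -> daily -> averaged-summary aggregation, the
group comparisons and the lameness models) is driven by this table rather than
by hard-coded column lists.  Three aggregation kinds exist:

``sum``
    Daily value is the sum of the 24 hourly values (times, counts).
``weighted``
    Daily value is a weighted mean of the hourly values,
    sum(a_h * x_h) / sum(x_h), where ``x`` is the hourly value of the
    companion weight variable (ruminating time, boluses or strides).
``derived``
    Recomputed from other daily variables after aggregation
    (walking speed from the stride statistics, mean lying bout duration
    from lying time and lying bout count).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Variable:
    name: str
    label: str
    unit: str
    kind: str               # "sum" | "weighted" | "derived"
    source: str             # "halter" | "accelerometer" | "derived"
    weight: str | None = None   # weight variable for kind == "weighted"
    or_increment: float = 1.0   # odds-ratio scaling step used in model reports
    lower: float = 0.0
    upper: float = float("inf")
    integer: bool = False


VARIABLES: tuple[Variable, ...] = (
    # halter (noseband sensor)
    Variable("eating_time", "Eating time", "min/d", "sum", "halter",
             or_increment=30.0, upper=1440.0),
    Variable("ruminating_time", "Ruminating time", "min/d", "sum", "halter",
             or_increment=30.0, upper=1440.0),
    Variable("eating_chews", "Eating chews", "1/d", "sum", "halter",
             or_increment=1000.0, integer=True),
    Variable("ruminating_chews", "Ruminating chews", "1/d", "sum", "halter",
             or_increment=1000.0, integer=True),
    Variable("bolus", "Bolus", "1/d", "sum", "halter",
             or_increment=10.0, integer=True),
    Variable("chews_per_minute", "Chews per minute", "1/min", "weighted",
             "halter", weight="ruminating_time"),
    Variable("chews_per_bolus", "Chews per bolus", "1/bolus", "weighted",
             "halter", weight="bolus"),
    # accelerometer
    Variable("lying_time", "Lying time", "min/d", "sum", "accelerometer",
             or_increment=30.0, upper=1440.0),
    Variable("standing_time", "Standing time", "min/d", "sum", "accelerometer",
             or_increment=30.0, upper=1440.0),
    Variable("walking_time", "Walking time", "min/d", "sum", "accelerometer",
             or_increment=30.0, upper=1440.0),
    Variable("lying_bouts", "Lying bouts", "1/d", "sum", "accelerometer",
             or_increment=10.0, integer=True),
    Variable("standing_bouts", "Standing bouts", "1/d", "sum", "accelerometer",
             or_increment=10.0, integer=True),
    Variable("walking_bouts", "Walking bouts", "1/d", "sum", "accelerometer",
             or_increment=10.0, integer=True),
    Variable("strides", "Strides", "1/d", "sum", "accelerometer",
             or_increment=100.0, integer=True),
    Variable("stride_duration", "Stride duration", "ms", "weighted",
             "accelerometer", weight="strides", or_increment=100.0),
    Variable("stride_distance", "Stride distance", "cm", "weighted",
             "accelerometer", weight="strides", or_increment=10.0),
    # derived
    Variable("lying_bout_duration", "Lying bout duration", "min/bout",
             "derived", "derived", or_increment=30.0),
    Variable("walking_speed_calc", "Walking speed_calc", "m/s", "derived",
             "derived", or_increment=0.1),
)

BY_NAME: dict[str, Variable] = {v.name: v for v in VARIABLES}

SUM_VARS = tuple(v.name for v in VARIABLES if v.kind == "sum")
WEIGHTED_VARS = tuple(v.name for v in VARIABLES if v.kind == "weighted")
DERIVED_VARS = tuple(v.name for v in VARIABLES if v.kind == "derived")
HALTER_VARS = tuple(v.name for v in VARIABLES if v.source == "halter")
ACCEL_VARS = tuple(v.name for v in VARIABLES
                   if v.source in ("accelerometer", "derived"))


def walking_speed(stride_distance_cm: float, stride_duration_ms: float) -> float:
    """Mean daily walking speed in m/s: 10 * stride distance (cm) / duration (ms)."""
    return 10.0 * stride_distance_cm / stride_duration_ms


def lying_bout_duration(lying_time_min: float, lying_bouts: float) -> float:
    """Mean daily lying bout duration (min/bout)."""
    return lying_time_min / lying_bouts
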