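"""Default cohort parameters for the synthetic study population.

The defaults encode the published per-group moments of the averaged 24-hour
summaries of the study herd (12 non-lame cows, group C, and 41 lame cows,
group L, subdivided 19/11/11 into mildly / moderately / severely lame, groups
LI/LII/LIII).  Thirteen variables are sampled directly; the remaining five are
structural:

* ``walking_time``    = strides · stride_duration + (strides − walking_bouts) ·
  inter-stride gap.  The device defines walking time as the summed extent of
  the walking bouts, so it is determined by the stride variables up to the
  mean inter-stride gap, which is solved from the published group means
  (≈0.56 s non-lame, ≈0.46 s lame) and jittered per day.  The published
  walking-time SDs (5.99 / 7.06 min) emerge from this construction,
* ``standing_time``   = 1440 − lying_time − walking_time (daily time budget),
* ``standing_bouts``  = lying_bouts + walking_bouts − skipped, where ``skipped``
  counts lying-down events not preceded by a qualifying standing period
  (Binomial(lying_bouts, SKIP_PROB)).  This reproduces the published moments
  of standing bouts and the very high (r ≈ 0.98) standing~walking bout
  correlation as an emergent property of the bout definitions,
* ``stride_distance`` = walking_speed · stride_duration / 10,
* ``lying_bout_duration`` = lying_time / lying_bouts.

Group C stride-duration SD is 84 ms.  The published group-C dispersion for
this variable is typographically corrupted (it is an order of magnitude larger
than both the printed interquartile range and the value consistent with the
printed p-value); 84 ms restores internal consistency.

Subgroup means for walking bouts and walking speed split the group-L totals so
that (a) the L subgroups average exactly to the pooled group-L mean and (b)
group C separates from LII/LIII but not LI on bout counts, while separating
from every L subgroup on walking speed — the qualitative subgroup pattern the
study reports.  Within-subgroup SDs are shrunk so the pooled group-L SD equals
the published value.  No other variable carries subgroup structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: probability that a lying-down event is not preceded by a qualifying
#: standing bout (cow lies down within 4 s of ending a walking bout)
SKIP_PROB = 0.14

#: day-to-day within-cow SD as a fraction of the between-cow SD (free
#: parameter of the generator; the source tables publish only between-cow
#: dispersion of 2-day averages)
DAY_SD_FRACTION = 0.2

#: day-to-day SD of the mean inter-stride gap, seconds
GAP_DAY_SD = 0.1

#: variables sampled directly (order fixed for reproducibility)
DRAWN_VARS = (
    "eating_time", "ruminating_time", "eating_chews", "ruminating_chews",
    "bolus", "chews_per_minute", "chews_per_bolus",
    "lying_time", "lying_bouts", "walking_bouts",
    "strides", "stride_duration", "walking_speed_calc",
)


@dataclass
class GroupParams:
    """Location/scale targets for one lameness group of the synthetic cohort.

    ``means``/``sds`` are on the scale of the averaged 24-hour summaries (the
    per-cow 2-day averages).  ``correlations`` lists (var_a, var_b, spearman)
    constraints imposed through a Gaussian copula on the sampled variables;
    the default cohort needs none because its only strong dependence
    (standing ~ walking bouts) is structural.
    """

    group_label: str                      # "C", "LI", "LII" or "LIII"
    n_cows: int
    means: dict[str, float]
    sds: dict[str, float]
    nrs_probs: dict[float, float]         # target NRS -> probability
    correlations: list[tuple[str, str, float]] = field(default_factory=list)

    def validate(self) -> None:
        from .errors import ConfigError
        if self.n_cows < 1:
            raise ConfigError(f"group {self.group_label}: n_cows must be >= 1")
        for name in DRAWN_VARS + ("walking_time",):
            if name not in self.means or name not in self.sds:
                raise ConfigError(
                    f"group {self.group_label}: missing mean/SD for {name!r}")
            if self.sds[name] < 0:
                raise ConfigError(
                    f"group {self.group_label}: negative SD for {name!r}")
        for a, b, rho in self.correlations:
            if abs(rho) > 1:
                raise ConfigError(
                    f"group {self.group_label}: |rho|>1 for ({a}, {b})")
        budget = (self.means["lying_time"] + self.means["walking_time"])
        # standing time is structural; lying + walking must leave room for it
        if not 0.0 <= budget <= 1440.0:
            raise ConfigError(
                f"group {self.group_label}: lying+walking time {budget:.1f} "
                "min/d is outside the 1440-min daily budget")
        gap = self.mean_stride_gap()
        if not 0.0 < gap <= 4.0:
            raise ConfigError(
                f"group {self.group_label}: walking time, strides and stride "
                f"duration imply a mean inter-stride gap of {gap:.2f} s, "
                "outside the (0, 4] s the bout definition allows")

    def mean_stride_gap(self) -> float:
        """Mean inter-stride gap (s) implied by the walking-time target."""
        strides = self.means["strides"]
        bouts = self.means["walking_bouts"]
        if strides <= bouts:
            return 0.0
        walking_s = self.means["walking_time"] * 60.0
        stride_s = strides * self.means["stride_duration"] / 1000.0
        return (walking_s - stride_s) / (strides - bouts)


def _lame_means(walking_bouts: float, walking_speed: float) -> dict[str, float]:
    means = {
        "eating_time": 301.93, "ruminating_time": 537.37,
        "eating_chews": 22320.0, "ruminating_chews": 36900.0,
        "bolus": 533.96, "chews_per_minute": 73.97, "chews_per_bolus": 69.85,
        "lying_time": 784.38, "walking_time": 37.85, "lying_bouts": 9.54,
        "strides": 950.82, "stride_duration": 1970.0,
    }
    means["walking_bouts"] = walking_bouts
    means["walking_speed_calc"] = walking_speed
    return means


def _lame_sds(walking_bouts_sd: float, walking_speed_sd: float) -> dict[str, float]:
    sds = {
        "eating_time": 57.16, "ruminating_time": 59.63,
        "eating_chews": 4780.0, "ruminating_chews": 5780.0,
        "bolus": 120.76, "chews_per_minute": 5.65, "chews_per_bolus": 13.91,
        "lying_time": 130.56, "walking_time": 7.06, "lying_bouts": 3.35,
        "strides": 176.15, "stride_duration": 150.0,
    }
    sds["walking_bouts"] = walking_bouts_sd
    sds["walking_speed_calc"] = walking_speed_sd
    return sds


NONLAME_PARAMS = GroupParams(
    group_label="C",
    n_cows=12,
    means={
        "eating_time": 378.61, "ruminating_time": 583.23,
        "eating_chews": 29270.0, "ruminating_chews": 40760.0,
        "bolus": 614.50, "chews_per_minute": 75.74, "chews_per_bolus": 65.87,
        "lying_time": 679.65, "walking_time": 41.74, "lying_bouts": 9.79,
        "walking_bouts": 111.17, "strides": 1075.17,
        "stride_duration": 1830.0, "walking_speed_calc": 0.72,
    },
    sds={
        "eating_time": 71.40, "ruminating_time": 56.28,
        "eating_chews": 7210.0, "ruminating_chews": 4190.0,
        "bolus": 60.74, "chews_per_minute": 4.70, "chews_per_bolus": 3.80,
        "lying_time": 74.13, "walking_time": 5.99, "lying_bouts": 1.60,
        "walking_bouts": 16.28, "strides": 151.51,
        "stride_duration": 84.0, "walking_speed_calc": 0.09,
    },
    nrs_probs={1.0: 0.125, 1.5: 0.25, 2.0: 0.625},
)

# Within-subgroup SDs chosen so that the pooled group-L SD (19/11/11 mixture)
# equals the published 16.97 (walking bouts) and 0.10 m/s (walking speed).
MILD_PARAMS = GroupParams(
    group_label="LI", n_cows=19,
    means=_lame_means(walking_bouts=96.80, walking_speed=0.56),
    sds=_lame_sds(walking_bouts_sd=15.67, walking_speed_sd=0.0981),
    nrs_probs={2.5: 0.5, 3.0: 0.5},
)
MODERATE_PARAMS = GroupParams(
    group_label="LII", n_cows=11,
    means=_lame_means(walking_bouts=83.80, walking_speed=0.53),
    sds=_lame_sds(walking_bouts_sd=15.67, walking_speed_sd=0.0981),
    nrs_probs={3.5: 1.0},
)
SEVERE_PARAMS = GroupParams(
    group_label="LIII", n_cows=11,
    means=_lame_means(walking_bouts=83.67, walking_speed=0.5155),
    sds=_lame_sds(walking_bouts_sd=15.67, walking_speed_sd=0.0981),
    nrs_probs={4.0: 0.5, 4.5: 0.5},
)

#: pooled group-L moments (published), used by tests and two-group simulations
LAME_POOLED_MEANS = _lame_means(walking_bouts=89.79, walking_speed=0.54)
LAME_POOLED_SDS = _lame_sds(walking_bouts_sd=16.97, walking_speed_sd=0.10)

DEFAULT_GROUPS = (NONLAME_PARAMS, MILD_PARAMS, MODERATE_PARAMS, SEVERE_PARAMS)
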