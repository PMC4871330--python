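"""Synthetic cohort and event-stream generator.

Two-level design: :func:`simulate_cohort` draws per-cow, per-day *daily
targets* for all behavioural variables (truncated-normal marginals at the
configured group moments, optional Gaussian-copula correlation constraints,
structural derivation of standing time, standing bouts, stride distance and
lying bout duration); :func:`simulate_event_stream` then realises one cow-day
as a concrete posture/stride event stream whose segmentation reproduces the
targets.  All randomness flows from a single seed, split per cow with
``numpy.random.SeedSequence`` so any cow is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, GenerationError
from .params import (DAY_SD_FRACTION, DEFAULT_GROUPS, DRAWN_VARS, GAP_DAY_SD,
                     SKIP_PROB, GroupParams)
from .types import DAY_SECONDS, EventStream, SimCow
from .variables import BY_NAME

__all__ = [
    "SimConfig", "default_config", "simulate_cohort", "simulate_event_stream",
    "simulate_halter_hourly", "inject_day_flags", "cohort_to_frame",
    "DEFAULT_FLAG_RATES",
]

DEFAULT_FLAG_RATES = {"heat": 0.02, "insemination": 0.01, "ill": 0.02}

_INTEGER_VARS = tuple(n for n in DRAWN_VARS if BY_NAME[n].integer)


@dataclass
class SimConfig:
    groups: tuple[GroupParams, ...] = DEFAULT_GROUPS
    seed: int = 0
    days_per_cow: int = 3
    accelerometers_per_cow: int = 2
    hourly_resolution: int = 60          # minutes
    day_sd_fraction: float = DAY_SD_FRACTION
    flag_rates: dict = field(default_factory=lambda: dict(DEFAULT_FLAG_RATES))

    def validate(self) -> None:
        if self.days_per_cow < 2:
            raise ConfigError("days_per_cow must be >= 2")
        if self.accelerometers_per_cow < 1:
            raise ConfigError("accelerometers_per_cow must be >= 1")
        if not 0.0 <= self.day_sd_fraction < 1.0:
            raise ConfigError("day_sd_fraction must be in [0, 1)")
        for g in self.groups:
            g.validate()


def default_config(seed: int = 0, **kwargs) -> SimConfig:
    """Study-sized default cohort: 12 non-lame + 41 lame cows (19/11/11)."""
    return SimConfig(seed=seed, **kwargs)


# --------------------------------------------------------------------------
# cohort-level simulation


def _copula_chol(params: GroupParams) -> np.ndarray | None:
    """Cholesky factor of the Gaussian-copula correlation matrix, or None."""
    if not params.correlations:
        return None
    k = len(DRAWN_VARS)
    idx = {n: i for i, n in enumerate(DRAWN_VARS)}
    corr = np.eye(k)
    for a, b, rho_s in params.correlations:
        if a not in idx or b not in idx:
            raise ConfigError(f"correlation names a non-sampled variable: {a}, {b}")
        # Spearman -> Gaussian-copula Pearson parameter
        rho = 2.0 * np.sin(np.pi * rho_s / 6.0)
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigError("correlation spec is not positive definite") from exc


def _trunc_bounds(name: str) -> tuple[float, float]:
    var = BY_NAME[name]
    lo = 1.0 if name == "lying_bouts" else var.lower
    return lo, var.upper


def _sample_latents(params: GroupParams, n: int, day_sd_fraction: float,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-cow latent means with truncated-normal marginals.

    Latent SD is shrunk to sd*sqrt(1 - f^2/2) so that the 2-day averages the
    analysis operates on recover the configured between-cow SD exactly once
    the day-level noise (f * sd per day) is added back.
    """
    chol = _copula_chol(params)
    z = rng.standard_normal((n, len(DRAWN_VARS)))
    if chol is not None:
        z = z @ chol.T
    u = stats.norm.cdf(z)
    out: dict[str, np.ndarray] = {}
    shrink = np.sqrt(1.0 - day_sd_fraction ** 2 / 2.0)
    for j, name in enumerate(DRAWN_VARS):
        mean, sd = params.means[name], params.sds[name] * shrink
        lo, hi = _trunc_bounds(name)
        if sd == 0:
            out[name] = np.full(n, np.clip(mean, lo, hi))
            continue
        a, b = (lo - mean) / sd, (hi - mean) / sd
        out[name] = stats.truncnorm.ppf(u[:, j], a, b, loc=mean, scale=sd)
    return out


def _derive_day(day: dict[str, float], rng: np.random.Generator,
                mean_gap_s: float) -> dict[str, float]:
    """Attach the structurally derived variables to one day's targets."""
    # keep the stride/bout counts jointly realisable (>= 3 strides per bout)
    day["walking_bouts"] = float(min(int(day["walking_bouts"]),
                                     int(day["strides"]) // 3))
    if day["walking_bouts"] == 0:
        day["strides"] = 0.0
    gap = float(np.clip(rng.normal(mean_gap_s, GAP_DAY_SD), 0.02, 3.9))
    walking_s = (day["strides"] * day["stride_duration"] / 1000.0
                 + (day["strides"] - day["walking_bouts"]) * gap)
    day["walking_time"] = walking_s / 60.0
    day["lying_time"] = min(day["lying_time"], 1440.0 - day["walking_time"])
    day["standing_time"] = 1440.0 - day["lying_time"] - day["walking_time"]
    skipped = int(rng.binomial(int(day["lying_bouts"]), SKIP_PROB))
    day["standing_bouts"] = max(
        0.0, day["lying_bouts"] + day["walking_bouts"] - skipped)
    day["stride_distance"] = (
        day["walking_speed_calc"] * day["stride_duration"] / 10.0)
    day["lying_bout_duration"] = day["lying_time"] / day["lying_bouts"]
    return day


def _draw_nrs_scores(target: float, rng: np.random.Generator,
                     max_tries: int = 200) -> tuple[float, ...]:
    """Six half-point observer scores whose rounded mean equals ``target``."""
    from .aggregation import round_nrs
    for _ in range(max_tries):
        jitter = rng.choice([-0.5, 0.0, 0.5], size=6, p=[0.25, 0.5, 0.25])
        scores = np.clip(target + jitter, 1.0, 5.0)
        if round_nrs(float(scores.mean())) == target:
            return tuple(float(s) for s in scores)
    return tuple([target] * 6)


def simulate_cohort(config: SimConfig, seed: int | None = None) -> list[SimCow]:
    """Draw the cohort: per-cow gait scores and per-day behavioural targets."""
    config.validate()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    cohort: list[SimCow] = []
    group_seeds = root.spawn(len(config.groups))
    for params, gseed in zip(config.groups, group_seeds):
        grng = np.random.Generator(np.random.PCG64(gseed))
        mean_gap = params.mean_stride_gap()
        latents = _sample_latents(params, params.n_cows,
                                  config.day_sd_fraction, grng)
        nrs_levels = np.array(sorted(params.nrs_probs))
        nrs_p = np.array([params.nrs_probs[v] for v in nrs_levels])
        nrs_p = nrs_p / nrs_p.sum()
        cow_seeds = gseed.spawn(params.n_cows)
        for i, cseed in enumerate(cow_seeds):
            crng = np.random.Generator(np.random.PCG64(cseed))
            target_nrs = float(crng.choice(nrs_levels, p=nrs_p))
            scores = _draw_nrs_scores(target_nrs, crng)
            days = []
            for _d in range(config.days_per_cow):
                day: dict[str, float] = {}
                for name in DRAWN_VARS:
                    sd = params.sds[name]
                    val = latents[name][i] + crng.normal(0.0, config.day_sd_fraction * sd)
                    lo, hi = _trunc_bounds(name)
                    val = float(np.clip(val, lo, hi))
                    if name in _INTEGER_VARS:
                        val = float(round(val))
                    day[name] = val
                days.append(_derive_day(day, crng, mean_gap))
            cohort.append(SimCow(
                cow_id=f"{params.group_label}{i + 1:03d}",
                group=params.group_label,
                nrs_scores=scores,
                nrs_final=target_nrs,
                lame=target_nrs >= 2.5,
                days=days,
            ))
    return cohort


def cohort_to_frame(cohort: list[SimCow]) -> pd.DataFrame:
    """Long per-cow-day table of daily targets (one row per cow and day)."""
    rows = []
    for cow in cohort:
        for d, day in enumerate(cow.days, start=1):
            row = {"cow_id": cow.cow_id, "group": cow.group,
                   "nrs": cow.nrs_final, "lame": cow.lame, "day": d}
            row.update(day)
            rows.append(row)
    return pd.DataFrame(rows)


def inject_day_flags(cohort: list[SimCow], rates: dict | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Per-day status flags: heat / insemination / ill / ok.

    Flagged days are discarded before day selection, mirroring the study's
    exclusion of oestrus, insemination and illness days.
    """
    rates = dict(DEFAULT_FLAG_RATES if rates is None else rates)
    causes = ("heat", "insemination", "ill")
    p = np.array([rates.get(c, 0.0) for c in causes], dtype=float)
    if np.any(p < 0) or np.any(p > 1) or p.sum() > 1:
        raise ConfigError("flag rates must be probabilities with sum <= 1")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    labels = causes + ("ok",)
    probs = np.append(p, 1.0 - p.sum())
    rows = []
    for cow in cohort:
        for d in range(1, len(cow.days) + 1):
            flag = str(rng.choice(labels, p=probs))
            rows.append({"cow_id": cow.cow_id, "day": d, "flag": flag})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# event-stream realisation


def simulate_event_stream(daily_targets: dict, seed: int = 0,
                          cow_id: str = "cow", day: int = 1) -> EventStream:
    """Realise one cow-day as posture intervals plus stride events.

    The schedule alternates lying and upright periods (one upright period per
    lying bout); walking bouts are spread round-robin over the upright
    periods, each bout being a run of equally spaced strides whose inter-
    stride gap is solved from the walking-time target (and must come out in
    [0, 4] s, otherwise the targets are infeasible and a
    :class:`GenerationError` names the violated constraint).  Standing-bout
    counts below lying+walking bouts are realised by ending the corresponding
    number of upright periods with a sub-4-s standing gap (cow lies down
    almost immediately after walking), which removes those trailing periods
    from the standing-bout count without touching the standing-time budget.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    lt = float(daily_targets["lying_time"]) * 60.0
    wt = float(daily_targets["walking_time"]) * 60.0
    lb = int(round(daily_targets["lying_bouts"]))
    wb = int(round(daily_targets["walking_bouts"]))
    n_str = int(round(daily_targets["strides"]))
    dur_s = float(daily_targets["stride_duration"]) / 1000.0
    dist_cm = float(daily_targets.get(
        "stride_distance",
        daily_targets.get("walking_speed_calc", 0.0) * daily_targets["stride_duration"] / 10.0))
    st = DAY_SECONDS - lt - wt
    if st < 0:
        raise GenerationError("lying + walking time exceeds the 1440-min day")
    if lt > 0 and lb == 0:
        raise GenerationError("positive lying time with zero lying bouts")
    if lb > 0 and lt / lb <= 50.0:
        raise GenerationError(
            "lying time too small for requested lying bouts (bout would be <= 50 s)")
    if wb == 0:
        if n_str > 0:
            raise GenerationError("strides requested but zero walking bouts")
        if wt > 1e-9:
            raise GenerationError("walking time requested but zero walking bouts")
        gap = 0.0
    else:
        if dur_s <= 0:
            raise GenerationError("walking bouts require a positive stride duration")
        if n_str < 3 * wb:
            raise GenerationError(
                "fewer than 3 strides per walking bout (minimum-stride rule)")
        gap = (wt - n_str * dur_s) / (n_str - wb)
        if gap < -1e-9:
            raise GenerationError(
                "walking time too small for requested strides at requested stride duration")
        if gap > 4.0 + 1e-9:
            raise GenerationError(
                "walking time too large: inter-stride gap would exceed 4 s")
        gap = min(max(gap, 0.0), 4.0)

    n_periods = lb if lb > 0 else 1
    # walking bouts per upright period, round-robin
    bouts_per_period = [wb // n_periods] * n_periods
    for k in range(wb % n_periods):
        bouts_per_period[k] += 1
    # strides per walking bout
    strides_per_bout = [n_str // wb] * wb if wb else []
    for k in range(n_str % wb if wb else 0):
        strides_per_bout[k] += 1

    # standing-bout bookkeeping: each upright period contributes
    # 1 (post-lying) + n_bouts - 1 (inter-walk) + 1 (post-walk trailing)
    # standing bouts; "skipped" periods end with a <=4 s trailing gap instead.
    target_sb = daily_targets.get("standing_bouts")
    skippable = [p for p in range(n_periods) if bouts_per_period[p] > 0]
    n_skip = 0
    if target_sb is not None:
        n_skip = int(round(lb + wb - float(target_sb)))
        n_skip = max(0, min(n_skip, len(skippable)))
    skip_set = set(rng.permutation(skippable)[:n_skip]) if n_skip else set()

    lead_base, inter_base, trail_base, trail_skip = 55.0, 5.0, 5.0, 3.0
    base_total = 0.0
    for p in range(n_periods):
        m = bouts_per_period[p]
        base_total += lead_base
        if m > 0:
            base_total += (m - 1) * inter_base
            base_total += trail_skip if p in skip_set else trail_base
    extra = st - base_total
    if extra < 0:
        raise GenerationError(
            "standing time too small for the requested bout structure")
    lead_extra = extra / n_periods

    posture_rows: list[tuple[float, float, str]] = []
    stride_rows: list[tuple[float, float, float]] = []
    t = 0.0
    lying_dur = lt / lb if lb else 0.0
    bout_idx = 0
    for p in range(n_periods):
        if lb:
            posture_rows.append((t, t + lying_dur, "lying"))
            t += lying_dur
        up_start = t
        t += lead_base + lead_extra
        m = bouts_per_period[p]
        for j in range(m):
            k = strides_per_bout[bout_idx]
            for s in range(k):
                stride_rows.append((t + s * (dur_s + gap), dur_s * 1000.0, dist_cm))
            t += k * dur_s + (k - 1) * gap
            bout_idx += 1
            if j < m - 1:
                t += inter_base
            else:
                t += trail_skip if p in skip_set else trail_base
        posture_rows.append((up_start, t, "upright"))
    # absorb floating-point residue into the final interval
    s0, _e0, state0 = posture_rows[-1]
    posture_rows[-1] = (s0, DAY_SECONDS, state0)

    stream = EventStream(
        cow_id=cow_id, day=day,
        posture=pd.DataFrame(posture_rows, columns=["start_s", "end_s", "state"]),
        strides=pd.DataFrame(stride_rows,
                             columns=["start_s", "duration_ms", "distance_cm"]),
    )
    stream.validate()
    return stream


def simulate_halter_hourly(daily_targets: dict, seed: int = 0) -> pd.DataFrame:
    """24 hourly rows of the noseband-sensor variables realising the daily targets.

    Sum variables are spread over the day with jittered near-uniform weights
    (kept well below the 60-min hourly cap); the two weighted-mean variables
    (chews per minute / per bolus) are jittered and then recentred so their
    weighted daily means reproduce the targets exactly.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    hours = np.arange(24)
    out = pd.DataFrame({"hour": hours})
    weights = {}
    for name in ("eating_time", "ruminating_time", "eating_chews",
                 "ruminating_chews", "bolus"):
        w = 1.0 + 0.5 * (rng.random(24) - 0.5)
        w /= w.sum()
        weights[name] = w
        total = float(daily_targets[name])
        vals = total * w
        if BY_NAME[name].integer:
            vals = np.floor(vals)
            vals[0] += total - vals.sum()   # preserve the daily sum exactly
        out[name] = vals
    for name, wname in (("chews_per_minute", "ruminating_time"),
                        ("chews_per_bolus", "bolus")):
        target = float(daily_targets[name])
        w = out[wname].to_numpy(float)
        vals = target * (1.0 + 0.05 * (rng.random(24) - 0.5))
        if w.sum() > 0:
            vals += target - float(np.sum(vals * w) / w.sum())
        out[name] = vals
    return out
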