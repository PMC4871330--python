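"""Study-level replication experiments on synthetic cohorts.

Two entry points:

* :func:`scaled_study_metrics` — simulate the cohort at the published group
  moments, scaled up from the study's 12 + 41 cows to stabilise the
  estimates, push it through day-exclusion/selection and averaging, and
  evaluate the published frozen model, the univariable thresholds and the
  descriptives.  Metrics are averaged over a few independent replicates to
  reduce Monte-Carlo error; they estimate the population value of each
  statistic under the study conditions.
* :func:`selection_replication` — repeat the full study-sized analysis
  (significance screen, correlation filter, backward selection, subgroup
  letter display) across many seeds and tabulate which accelerometer model
  is selected and how often groups C and LI share a significance letter for
  standing bouts.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter

import numpy as np
import pandas as pd

from . import aggregation, classifier, group_stats, synth
from .params import DEFAULT_GROUPS
from .variables import ACCEL_VARS, VARIABLES

__all__ = ["scaled_study_metrics", "selection_replication",
            "simulate_averaged_cohort"]

ALL_VARS = tuple(v.name for v in VARIABLES)


def simulate_averaged_cohort(seed: int, scale: int = 1) -> pd.DataFrame:
    """Cohort at the published moments -> averaged 24-h summaries.

    ``scale`` multiplies every group's cow count (scale=1 is the study's
    12 + 41).  Daily targets go straight into day-flagging, day/sensor
    selection and 2-day averaging; the event-stream level is exercised by
    the segmentation tests and the pipeline, not needed here.
    """
    groups = tuple(dataclasses.replace(g, n_cows=g.n_cows * scale)
                   for g in DEFAULT_GROUPS)
    cfg = synth.SimConfig(groups=groups, seed=seed)
    cohort = synth.simulate_cohort(cfg)
    daily = synth.cohort_to_frame(cohort)
    flags = synth.inject_day_flags(cohort, cfg.flag_rates, seed=seed + 1)
    averaged, _log = aggregation.build_averaged_summaries(
        daily, flags, seed=seed, n_sensors=cfg.accelerometers_per_cow)
    return averaged


def _cohort_metrics(averaged: pd.DataFrame) -> dict[str, float]:
    lame = averaged["lame"].astype(bool).to_numpy()
    out: dict[str, float] = {}
    ev = classifier.score_frozen("A", averaged, labels=lame)
    out["frozen_a_sensitivity"] = ev.metrics["sensitivity"]
    out["frozen_a_specificity"] = ev.metrics["specificity"]
    out["frozen_a_auc"] = ev.auc
    ws = averaged["walking_speed_calc"].to_numpy(float)
    out["walking_speed_auc"] = classifier.roc_analysis(-ws, lame).auc
    tc = classifier.threshold_classify(ws, 0.65, "below", lame)
    out["walking_speed_sensitivity_at_0.65"] = tc["sensitivity"]
    tc = classifier.threshold_classify(
        averaged["eating_time"].to_numpy(float), 297.4, "below", lame)
    out["eating_time_specificity_at_297.4"] = tc["specificity"]
    rho = group_stats.spearman_matrix(
        averaged, ["standing_bouts", "walking_bouts"]).iloc[0, 1]
    out["spearman_standing_walking_bouts"] = float(rho)
    out["lame_mean_eating_time"] = float(
        averaged.loc[lame, "eating_time"].mean())
    out["n_cows"] = float(len(averaged))
    return out


def scaled_study_metrics(seed: int, scale: int = 20,
                         replicates: int = 3) -> dict[str, float]:
    """Replicate-averaged study statistics (see module docstring)."""
    seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2 ** 31 - 1)
    acc: dict[str, list[float]] = {}
    for s in seeds:
        averaged = simulate_averaged_cohort(int(s), scale=scale)
        for k, v in _cohort_metrics(averaged).items():
            acc.setdefault(k, []).append(v)
    out = {k: float(np.mean(v)) for k, v in acc.items()}
    out["n_cows"] = float(np.sum(acc["n_cows"]))
    out["replicates"] = float(replicates)
    return out


def _one_selection(seed: int) -> tuple[tuple[str, ...], bool] | None:
    averaged = simulate_averaged_cohort(seed, scale=1)
    lame = averaged["lame"].astype(bool).to_numpy()
    if lame.sum() < 5 or (~lame).sum() < 5:
        return None
    comp = group_stats.two_group_table(averaged, list(ALL_VARS))
    candidates = [v for v in comp.loc[comp["significant"], "variable"]
                  if v in ACCEL_VARS]
    if not candidates:
        return None
    sel = classifier.build_multivariable(averaged, candidates, lame)
    groups = {g: sub["standing_bouts"].dropna().to_numpy()
              for g, sub in averaged.groupby("group", sort=True)}
    res = group_stats.four_group_compare(groups, variable="standing_bouts")
    share = bool(set(res.letters.get("C", "")) & set(res.letters.get("LI", "")))
    return tuple(sorted(sel.variables)), share


def selection_replication(n_seeds: int = 500, base_seed: int = 0) -> dict:
    """Tabulate model selection and C-vs-LI letter sharing over many seeds."""
    counts: Counter = Counter()
    shares: list[bool] = []
    used = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_seeds):
            rep = _one_selection(base_seed + 1000 * k)
            if rep is None:
                continue
            counts[rep[0]] += 1
            shares.append(rep[1])
            used += 1
    return {
        "model_counts": counts,
        "plurality_model": counts.most_common(1)[0][0] if counts else None,
        "share_rate_c_li": float(np.mean(shares)) if shares else float("nan"),
        "replicates_used": used,
    }
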