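"""End-to-end pipeline: simulate -> segment -> aggregate -> compare -> model.

`run_pipeline` reproduces the full analysis chain on a synthetic cohort (or,
when ``averaged_path`` points at an existing averaged-summary table, runs the
statistics and models on that table directly).  Every random decision (day
pair, accelerometer) is seeded from the single study seed and recorded in
the run log, so two runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregation, classifier, group_stats, io, synth
from .errors import GaitwatchError
from .variables import ACCEL_VARS, VARIABLES

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]

ALL_VARS = tuple(v.name for v in VARIABLES)


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str | Path = "results/pipeline"
    alpha: float = 0.05
    exact_threshold: int = 10
    sim: synth.SimConfig = field(default_factory=synth.default_config)
    averaged_path: str | Path | None = None   # skip simulation when given
    write_streams: bool = False               # event-stream CSV is bulky

    def validate(self) -> None:
        from .errors import ConfigError
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        self.sim.validate()


def _simulate_tables(config: PipelineConfig) -> dict:
    """Cohort -> event streams -> hourly -> daily -> averaged summaries."""
    sim = config.sim
    cohort = synth.simulate_cohort(sim, seed=config.seed)
    flags = synth.inject_day_flags(cohort, sim.flag_rates, seed=config.seed + 1)
    root = np.random.SeedSequence([config.seed, 2])
    stream_seeds = iter(root.generate_state(
        len(cohort) * sim.days_per_cow * (sim.accelerometers_per_cow + 1)))
    daily_rows, streams, hourly_frames = [], [], []
    from .segmentation import summarize_hourly
    for cow in cohort:
        nrs, group, lame = aggregation.compute_nrs_and_group(cow.nrs_scores)
        for d, targets in enumerate(cow.days, start=1):
            halter = synth.simulate_halter_hourly(
                targets, seed=int(next(stream_seeds) % 2**31))
            for sensor in range(1, sim.accelerometers_per_cow + 1):
                stream = synth.simulate_event_stream(
                    targets, seed=int(next(stream_seeds) % 2**31),
                    cow_id=cow.cow_id, day=d)
                hourly = summarize_hourly(stream, halter)
                summary = aggregation.daily_summary(hourly)
                summary.update({"cow_id": cow.cow_id, "day": d,
                                "sensor": sensor, "group": group,
                                "nrs": nrs, "lame": lame})
                daily_rows.append(summary)
                if sensor == 1:
                    hourly_frames.append(hourly)
                    if config.write_streams:
                        streams.append(stream)
    daily = pd.DataFrame(daily_rows)
    averaged, log = aggregation.build_averaged_summaries(
        daily, flags, seed=config.seed, n_sensors=sim.accelerometers_per_cow,
        sensor_col="sensor")
    return {"cohort": cohort, "flags": flags, "daily": daily,
            "hourly": pd.concat(hourly_frames, ignore_index=True),
            "averaged": averaged, "selection_log": log, "streams": streams}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; write the artifact tables; return the bundle."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config_seed": config.seed}

    if config.averaged_path is not None:
        averaged = io.read_summary_table(config.averaged_path, "averaged")
        bundle["selection_log"] = []
    else:
        tables = _simulate_tables(config)
        averaged = tables["averaged"]
        bundle.update(tables)
        io.write_summary_table(tables["daily"], out / "daily_summaries.csv")
        io.write_summary_table(tables["hourly"], out / "hourly_summaries.csv")
        tables["flags"].to_csv(out / "day_flags.csv", index=False)
        if config.write_streams and tables["streams"]:
            io.write_event_streams(tables["streams"], out / "event_streams.csv")
    bundle["averaged"] = averaged
    io.write_summary_table(averaged, out / "averaged_summaries.csv")

    if "lame" not in averaged.columns or averaged["lame"].astype(bool).nunique() < 2:
        bundle["note"] = "fewer than two outcome classes; analysis stages skipped"
        (out / "run_log.json").write_text(render_log(bundle))
        return bundle

    labels = averaged["lame"].astype(bool).to_numpy()
    variables = [v for v in ALL_VARS if v in averaged.columns
                 and averaged[v].notna().sum() >= 6]
    comparison = group_stats.two_group_table(averaged, variables,
                                             alpha=config.alpha)
    bundle["comparison"] = comparison
    comparison.to_csv(out / "two_group_comparison.csv", index=False,
                      float_format="%.6g")

    if "group" in averaged.columns and averaged["group"].nunique() >= 3:
        letters_rows = []
        for name in ("standing_bouts", "walking_speed_calc"):
            groups = {g: sub[name].dropna().to_numpy()
                      for g, sub in averaged.groupby("group", sort=True)}
            res = group_stats.four_group_compare(groups, alpha=config.alpha,
                                                 variable=name)
            for g, letter in res.letters.items():
                letters_rows.append({"variable": name, "group": g,
                                     "letters": letter, "test": res.test,
                                     "omnibus_p": res.p_value})
        bundle["letters"] = pd.DataFrame(letters_rows)
        bundle["letters"].to_csv(out / "subgroup_letters.csv", index=False,
                                 float_format="%.6g")

    candidates = comparison.loc[comparison["significant"], "variable"].tolist()
    bundle["univariable"] = classifier.univariable_table(
        averaged, candidates, labels)
    bundle["univariable"].to_csv(out / "univariable_models.csv", index=False,
                                 float_format="%.6g")
    try:
        accel_candidates = [v for v in candidates if v in ACCEL_VARS]
        bundle["multivariable"] = classifier.build_multivariable(
            averaged, candidates, labels, alpha=config.alpha)
        bundle["multivariable_accel"] = classifier.build_multivariable(
            averaged, accel_candidates, labels, alpha=config.alpha)
    except GaitwatchError as exc:
        bundle["multivariable_error"] = str(exc)

    frozen_rows = []
    for mid, fm in classifier.FROZEN_MODELS.items():
        if not set(fm.coefficients) <= set(averaged.columns):
            continue
        for cutoff in fm.cutoffs:
            ev = classifier.score_frozen(fm, averaged, cutoff=cutoff,
                                         labels=labels)
            frozen_rows.append({"model": mid, "cutoff": cutoff,
                                "auc": ev.auc, **(ev.metrics or {})})
        roc = classifier.roc_analysis(fm.score(averaged), labels)
        roc.table.to_csv(out / f"roc_frozen_{mid}.csv", index=False,
                         float_format="%.6g")
    bundle["frozen"] = pd.DataFrame(frozen_rows)
    bundle["frozen"].to_csv(out / "frozen_model_evaluation.csv", index=False,
                            float_format="%.6g")

    (out / "run_log.json").write_text(render_log(bundle))
    (out / "report.txt").write_text(render_report(bundle))
    return bundle


def render_log(bundle: dict) -> str:
    log = {"seed": bundle.get("config_seed"),
           "selections": [
               {"cow_id": s.cow_id, "excluded": s.excluded,
                "reason": s.reason, "days": [int(d) for d in s.days],
                "sensor": int(s.sensor)}
               for s in bundle.get("selection_log", [])]}
    return json.dumps(log, indent=2) + "\n"


def _fmt_table(frame: pd.DataFrame) -> str:
    return frame.to_string(index=False, float_format=lambda v: f"{v:.4g}")


def render_report(bundle: dict) -> str:
    """Human-readable summary mirroring the descriptive table layout."""
    parts = [f"gaitwatch pipeline report (seed {bundle.get('config_seed')})"]
    if "note" in bundle:
        parts.append(bundle["note"])
    for key, title in (("comparison", "Two-group comparison (C vs L)"),
                       ("letters", "Subgroup letter display"),
                       ("univariable", "Univariable logistic models"),
                       ("frozen", "Frozen-model evaluation")):
        parts.append(f"\n== {title} ==")
        if key in bundle:
            parts.append(_fmt_table(bundle[key]))
        else:
            parts.append("[section skipped]")
    parts.append("\n== Multivariable selection ==")
    for key in ("multivariable", "multivariable_accel"):
        sel = bundle.get(key)
        if sel is None:
            parts.append("[section skipped]")
            continue
        scope = "all candidates" if key == "multivariable" else "accelerometer only"
        parts.append(f"{scope}: variables={sel.variables} AUC={sel.auc:.3f} "
                     f"note={sel.note or '-'}")
    return "\n".join(parts) + "\n"
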