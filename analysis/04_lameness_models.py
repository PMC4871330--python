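#!/usr/bin/env python
"""Lameness classification models on the averaged summaries from step 02.

Univariable logistic models with optimal-cutoff ROC metrics, the
correlation-filtered backward-selected multivariable model, and the two
published frozen model equations at their published cutoffs.
"""

import warnings
from pathlib import Path

from gaitwatch import classifier, group_stats, io
from gaitwatch.variables import ACCEL_VARS, VARIABLES

IN = Path("results/pipeline/averaged_summaries.csv")
OUT = Path("results/models")


def main() -> None:
    averaged = io.read_summary_table(IN, "averaged")
    labels = averaged["lame"].astype(bool).to_numpy()
    OUT.mkdir(parents=True, exist_ok=True)
    variables = [v.name for v in VARIABLES if v.name in averaged.columns]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comp = group_stats.two_group_table(averaged, variables)
        candidates = comp.loc[comp["significant"], "variable"].tolist()

        uni = classifier.univariable_table(averaged, candidates, labels)
        uni.to_csv(OUT / "univariable_models.csv", index=False,
                   float_format="%.6g")
        best = uni.sort_values("auc", ascending=False).iloc[0]
        print(f"best univariable predictor: {best['variable']} "
              f"(AUC {best['auc']:.2f}, sens {best['sensitivity']:.1f}%, "
              f"spec {best['specificity']:.1f}% at cutoff {best['cutoff']:.4g})")

        accel = [v for v in candidates if v in ACCEL_VARS]
        sel = classifier.build_multivariable(averaged, accel, labels)
        print(f"accelerometer-only backward selection kept {sel.variables} "
              f"(AUC {sel.auc:.3f}); intercept {sel.model.intercept:.3f}, "
              + ", ".join(f"{k} {v:+.4f}"
                          for k, v in sel.model.coefficients.items()))

        for mid in ("A", "B"):
            fm = classifier.FROZEN_MODELS[mid]
            ev = classifier.score_frozen(fm, averaged, labels=labels)
            m = ev.metrics
            print(f"published model {mid} at cutoff {fm.default_cutoff:g}: "
                  f"sens {m['sensitivity']:.1f}% spec {m['specificity']:.1f}% "
                  f"correct {m['proportion_correct']:.1f}% AUC {ev.auc:.3f}")
            roc = classifier.roc_analysis(fm.score(averaged), labels)
            roc.table.to_csv(OUT / f"roc_frozen_{mid}.csv", index=False,
                             float_format="%.6g")
    print(f"tables in {OUT}/")


if __name__ == "__main__":
    main()
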