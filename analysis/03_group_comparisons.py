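#!/usr/bin/env python
"""Group comparisons on the averaged summaries from step 02.

Reproduces the descriptive layout (mean, SD, median, IQR per group, routed
test, p) for every behavioural variable, then the four-group subgroup
comparison with the compact letter display for standing bouts and walking
speed.
"""

import warnings
from pathlib import Path

import pandas as pd

from gaitwatch import group_stats, io
from gaitwatch.variables import VARIABLES

IN = Path("results/pipeline/averaged_summaries.csv")
OUT = Path("results/stats")


def main() -> None:
    averaged = io.read_summary_table(IN, "averaged")
    OUT.mkdir(parents=True, exist_ok=True)
    variables = [v.name for v in VARIABLES if v.name in averaged.columns]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = group_stats.two_group_table(averaged, variables)
    table.to_csv(OUT / "two_group_comparison.csv", index=False,
                 float_format="%.6g")
    sig = table[table["significant"]]
    print(f"{len(sig)}/{len(table)} variables separate lame from non-lame "
          "cows at p < 0.05:")
    for row in sig.itertuples(index=False):
        print(f"  {row.variable:<22s} {row.test:<14s} p={row.p_value:.4g}  "
              f"C {row.c_mean:.2f}±{row.c_sd:.2f} vs L {row.l_mean:.2f}"
              f"±{row.l_sd:.2f}")

    rows = []
    for name in ("standing_bouts", "walking_speed_calc"):
        groups = {g: sub[name].dropna().to_numpy()
                  for g, sub in averaged.groupby("group", sort=True)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = group_stats.four_group_compare(groups, variable=name)
        letters = " ".join(f"{g}:{l}" for g, l in res.letters.items())
        print(f"subgroups, {name}: {res.test} omnibus p={res.p_value:.2g} "
              f"letters [{letters}]")
        for g, l in res.letters.items():
            rows.append({"variable": name, "group": g, "letters": l,
                         "omnibus_p": res.p_value, "test": res.test})
    pd.DataFrame(rows).to_csv(OUT / "subgroup_letters.csv", index=False,
                              float_format="%.6g")
    print(f"tables in {OUT}/")


if __name__ == "__main__":
    main()
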