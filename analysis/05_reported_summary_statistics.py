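#!/usr/bin/env python
"""Recompute the study's test statistics from its printed group summaries.

Everything here is deterministic: inputs are the means ± SEM, group sizes
and category counts bundled in somatomap.reference; outputs are t and F
statistics, Fisher p-values, percent span expansions, percent density
reductions and planar focus shifts. Writes
results/reported_statistics.json.
"""

import json
import sys
from pathlib import Path

from somatomap import reference as ref
from somatomap.morpho import percent_change, planar_shift
from somatomap.stats import fisher_exact, one_way_anova, t_test

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    payload = {}

    res = t_test(ref.AXON_COUNTS["control"], ref.AXON_COUNTS["stoml3"])
    payload["axon_count_t"] = {"t": res.statistic, "df": res.df, "p": res.p}
    print(f"myelinated axon counts: t({res.df:.0f}) = {abs(res.statistic):.4f}, "
          f"p = {res.p:.4f}")

    for name, groups in (("abeta_cv", ref.CV_ABETA), ("sam_cv", ref.CV_SAM),
                         ("ram_cv", ref.CV_RAM), ("adelta_cv", ref.CV_ADELTA),
                         ("ram_threshold", ref.RAM_VIBRATION_THRESHOLDS)):
        res = one_way_anova(groups)
        payload[f"{name}_anova"] = {"F": res.statistic, "df": res.df, "p": res.p}
        print(f"{name:14s} F({res.df[0]}, {res.df[1]}) = {res.statistic:.3f}, "
              f"p = {res.p:.4g}")

    spans = {}
    for field in ("left", "right"):
        for axis in ("ML", "RC", "DV"):
            c, m = ref.SPANS[field][axis]
            res = t_test(c, m)
            spans[f"{field}_{axis}"] = {
                "percent_change": percent_change(c.mean, m.mean),
                "t": res.statistic, "df": res.df, "p": res.p,
            }
    payload["spans"] = spans
    print(f"\nspan expansions: ML +{spans['left_ML']['percent_change']:.0f}% (left), "
          f"+{spans['right_ML']['percent_change']:.0f}% (right); "
          f"RC +{spans['left_RC']['percent_change']:.0f}%")

    densities = {}
    for field in ("left", "right"):
        c, m = ref.DENSITY_DV[field]
        res = t_test(c, m)
        densities[field] = {
            "percent_change": percent_change(c.mean, m.mean),
            "t": res.statistic, "df": res.df, "p": res.p,
        }
    payload["densities_dv"] = densities
    print(f"density reductions: {-densities['left']['percent_change']:.0f}% (left), "
          f"{-densities['right']['percent_change']:.0f}% (right)")

    payload["focus_shifts_um"] = {
        field: planar_shift(*ref.FOCUS_SHIFT_COMPONENTS_UM[field])
        for field in ("left", "right")
    }
    print(f"planar focus shifts: {payload['focus_shifts_um']['left']:.1f} µm, "
          f"{payload['focus_shifts_um']['right']:.1f} µm")

    fisher = {}
    for name, table in (("abeta_insensitive", ref.INSENSITIVE_COUNTS["Abeta"]),
                        ("adelta_insensitive", ref.INSENSITIVE_COUNTS["Adelta"]),
                        ("tap_units", ref.TAP_UNIT_COUNTS)):
        res = fisher_exact(table)
        fisher[name] = {"p": res.p, "odds_ratio": res.statistic}
        print(f"Fisher {name:18s} p = {res.p:.2g}")
    payload["fisher"] = fisher

    out = ROOT / "results" / "reported_statistics.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(payload, indent=2))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    sys.exit(main())
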