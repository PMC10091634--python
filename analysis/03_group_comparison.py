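"""Compare CI and HC on each cognitive test.

For the CDT, the Phototest, and the RSVP global AM/AB, reports group means
with standard errors, the exact Mann-Whitney U (minimum-of-two convention),
the two-sided p-value, and the common-language effect size.
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from rsvp_screen import cohort as ch
from rsvp_screen import group_stats as gs
from rsvp_screen import performance as pf


def comparison_row(name, ci_vals, hc_vals):
    res = gs.mann_whitney(ci_vals, hc_vals)
    return {
        "test": name,
        "mean_ci": float(np.mean(ci_vals)),
        "sem_ci": gs.sem(ci_vals),
        "mean_hc": float(np.mean(hc_vals)),
        "sem_hc": gs.sem(hc_vals),
        "p_value": res.p_two_sided,
        "u_value": res.u_reported,
        "effect_size": res.effect_size,
        "significant": res.p_two_sided <= 0.05,
        "method": res.method,
    }


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = ch.read_cohort(args.cohort)
    with warnings.catch_warnings():
        warnings.simplefilter("default")
        g = {
            r.participant_id: pf.compute_global_imputed(
                pf.compute_curve(r.outcomes), participant_id=r.participant_id
            )
            for r in cohort
        }

    def split(getter):
        return (
            [getter(r) for r in cohort if r.group == "CI"],
            [getter(r) for r in cohort if r.group == "HC"],
        )

    rows = [
        comparison_row("CDT", *split(lambda r: r.cdt_score)),
        comparison_row("Phototest", *split(lambda r: r.phototest_score)),
        comparison_row("RSVP (global AM)", *split(lambda r: g[r.participant_id].global_am)),
        comparison_row("RSVP (global AB)", *split(lambda r: g[r.participant_id].global_ab)),
    ]
    pd.DataFrame(rows).to_csv(args.out / "group_comparison.csv", index=False)
    (args.out / "group_comparison.json").write_text(json.dumps(rows, indent=1))

    print("group comparison (exact Mann-Whitney, CLES effect size):")
    for r in rows:
        star = "*" if r["significant"] else " "
        print(
            f"  {r['test']:<18} CI {r['mean_ci']:6.2f} ± {r['sem_ci']:.2f}  "
            f"HC {r['mean_hc']:6.2f} ± {r['sem_hc']:.2f}  "
            f"p={r['p_value']:.3f}{star} U={r['u_value']:g} ES={r['effect_size']:.2f}"
        )
    print(f"wrote group_comparison.csv/.json to {args.out}/")


if __name__ == "__main__":
    main()
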