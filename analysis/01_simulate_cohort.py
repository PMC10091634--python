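"""Simulate the study cohort.

Generates the default synthetic cohort — 13 cognitively impaired (CI) and 9
healthy control (HC) participants, each with 70 scored RSVP trials (10 per
separation) plus CDT and Phototest scores — and writes it, together with the
generative model, under the output directory.
"""

import argparse
from pathlib import Path

from rsvp_screen import cohort as ch


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=8)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    config = ch.CohortConfig(seed=args.seed)
    cohort = ch.simulate_cohort(config)
    ch.write_cohort(cohort, args.out)
    ch.model_to_json(config.model, args.out / "model.json")

    n_ci = sum(r.group == "CI" for r in cohort)
    n_hc = len(cohort) - n_ci
    print(f"simulated cohort (seed={args.seed}): {n_ci} CI + {n_hc} HC participants")
    print(f"trials per participant: {len(cohort[0].outcomes)} (10 per separation)")
    for g in ("CI", "HC"):
        ab, am = config.model.analytic_global(g)
        print(f"  {g}: model-implied global AB {ab:.2f}, global AM {am:.2f}")
    print(f"wrote participants.csv, outcomes.csv, model.json to {args.out}/")


if __name__ == "__main__":
    main()
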