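#!/usr/bin/env python
"""Step 1 — simulate the synthetic field study.

Generates the road network, subject profiles, 15-s GPS fixes, per-minute
true time-activity labels, 1-min PB-PAH concentrations, hourly weather
and the baseline questionnaire, and writes the raw study files under
``results/raw/``. Everything downstream (steps 02-06) reads only these
files, never in-memory objects, so each step can be rerun in isolation.
"""

import argparse
from pathlib import Path

import pandas as pd

from pbpah import io as pio
from pbpah import synthetic_data as sd

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--subjects", type=int, default=28)
    ap.add_argument("--spike-prob", type=float, default=0.02,
                    help="per-minute probability of an indoor source spike")
    ap.add_argument("--truncation-prob", type=float, default=0.05,
                    help="probability a sampling day ends early (<6 h)")
    ap.add_argument("--outdir", type=Path, default=RESULTS / "raw")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    # contamination switched on so the QA step (04) has work to do
    cfg = sd.SimulationConfig(
        n_subjects=args.subjects,
        seed=args.seed,
        indoor_spike_prob=args.spike_prob,
        day_truncation_prob=args.truncation_prob,
    )
    cohort = sd.simulate_cohort(cfg)

    cohort["network"].to_geojson(args.outdir / "network.geojson")
    pio.write_fixes_csv(cohort["fixes"], args.outdir / "fixes.csv")
    pio.write_minutes_csv(cohort["truth_minutes"], args.outdir / "truth_minutes.csv")
    pio.write_pah_csv(cohort["pah"], args.outdir / "pah.csv")
    cohort["questionnaire"].to_csv(args.outdir / "questionnaire.csv", index=False)

    weather = cohort["weather"].copy()
    weather["timestamp"] = weather["timestamp"].dt.tz_convert("UTC")
    weather.to_csv(args.outdir / "weather.csv", index=False)

    # dwell anchors (home, work) for the rule-based classifier in step 02
    rows = []
    for p in cohort["profiles"]:
        rows.append({"subject_id": p.subject_id, "kind": "home",
                     "x": p.home_location[0], "y": p.home_location[1]})
        if p.works:
            rows.append({"subject_id": p.subject_id, "kind": "work",
                         "x": p.work_location[0], "y": p.work_location[1]})
    pd.DataFrame(rows).to_csv(args.outdir / "anchors.csv", index=False)

    fixes, truth = cohort["fixes"], cohort["truth_minutes"]
    days = truth.groupby("subject_id")["minute"].apply(lambda m: m.dt.normalize().nunique())
    print(f"cohort: {cfg.n_subjects} subjects, {days.sum()} sampling days "
          f"({days.min()}-{days.max()} per subject)")
    print(f"fixes: {len(fixes)} at 15 s; labelled minutes: {len(truth)}")
    print("true time-activity fractions:")
    print(truth["category"].value_counts(normalize=True).round(4).to_string())
    print(f"road segments: {len(cohort['network'])}; files in {args.outdir}")


if __name__ == "__main__":
    main()
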