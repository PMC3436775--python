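#!/usr/bin/env python
"""Step 5 — aggregate minutes into the three analysis tables.

Builds the person-day, subject and subject-by-activity tables (outcome =
sqrt of the period-mean concentration), joining day-mean weather and the
baseline questionnaire, and prints geometric summaries of the minute
concentrations per time-activity category. Writes the tables under
``results/tables/``.
"""

import argparse
from pathlib import Path

import pandas as pd

from pbpah import io as pio
from pbpah.aggregation import (
    build_person_day_table,
    build_subject_activity_table,
    build_subject_table,
    summarize_exposure,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--raw", type=Path, default=RESULTS / "raw")
    ap.add_argument("--interim", type=Path, default=RESULTS / "interim")
    ap.add_argument("--outdir", type=Path, default=RESULTS / "tables")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    minutes = pio.read_minutes_csv(args.interim / "minutes_qa.csv")
    weather = pd.read_csv(args.raw / "weather.csv")
    weather["timestamp"] = (
        pd.to_datetime(weather["timestamp"], utc=True).dt.tz_convert(pio.STUDY_TZ)
    )
    questionnaire = pd.read_csv(args.raw / "questionnaire.csv")

    print("1-min PB-PAH concentration by classified category (ng/m^3):")
    rows = [("all", summarize_exposure(minutes["pah_ng_m3"]))]
    for cat, grp in minutes.groupby("category"):
        rows.append((cat, summarize_exposure(grp["pah_ng_m3"])))
    summary = pd.DataFrame(
        [
            {"category": cat, "n": s.n, "mean": s.mean, "sd": s.sd,
             "gm": s.gm, "gsd": s.gsd, "skewness": s.skewness}
            for cat, s in rows
        ]
    )
    print(summary.round(2).to_string(index=False))
    summary.to_csv(args.outdir / "exposure_summary.csv", index=False)

    person_day = build_person_day_table(minutes, weather, questionnaire)
    subject = build_subject_table(minutes, questionnaire)
    activity = build_subject_activity_table(minutes)

    for name, tab in [("person_day", person_day), ("subject", subject),
                      ("subject_activity", activity)]:
        path = args.outdir / f"{name}.csv"
        tab.to_csv(path, index=False)
        print(f"{name}: {len(tab)} rows -> {path}")
    print(f"sqrt_pah (person-day): mean {person_day['sqrt_pah'].mean():.2f}, "
          f"sd {person_day['sqrt_pah'].std():.2f}")


if __name__ == "__main__":
    main()
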