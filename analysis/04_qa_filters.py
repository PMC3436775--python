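#!/usr/bin/env python
"""Step 4 — quality-assurance filters on the linked minute records.

Applies, in order: removal of suspect vehicle clusters (bounding radius
< 100 m and mean speed < 10 km/h), removal of indoor minutes above
1000 ng/m^3, and removal of days with under 6 h of valid data. Writes
``results/interim/minutes_qa.csv`` and a JSON accounting report.
"""

import argparse
from pathlib import Path

from pbpah import io as pio
from pbpah.qa_filters import apply_qa

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--interim", type=Path, default=RESULTS / "interim")
    args = ap.parse_args()

    minutes = pio.read_minutes_csv(args.interim / "minutes_traffic.csv")
    filtered, report = apply_qa(minutes)

    print(f"input minutes:              {report.n_input_minutes}")
    print(f"vehicle-cluster removed:    {report.n_vehicle_cluster_removed}")
    print(f"indoor outliers removed:    {report.n_indoor_outliers_removed}")
    print(f"incomplete-day removed:     {report.n_incomplete_day_minutes_removed}")
    print(f"output minutes:             {report.n_output_minutes} "
          f"(removed fraction {report.removed_fraction:.4f})")

    pio.write_minutes_csv(filtered, args.interim / "minutes_qa.csv")
    report.to_json(args.interim / "qa_report.json")
    print(f"wrote {args.interim / 'minutes_qa.csv'} and qa_report.json")


if __name__ == "__main__":
    main()
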