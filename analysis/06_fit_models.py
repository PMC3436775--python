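#!/usr/bin/env python
"""Step 6 — select and fit the exposure models at all three levels.

Runs the modelling recipe (correlation screen, LASSO-path selection with
AIC, unpenalized OLS refit; plus a subject random-intercept/random-slope
mixed model at the daily level) on the tables from step 05. Writes the
coefficient tables under ``results/tables/`` and a JSON summary.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from pbpah.exposure_models import run_model_suite

RESULTS = Path(__file__).resolve().parent.parent / "results"

CANDIDATES_DAILY = [
    "pct_invehicle", "pct_indoor", "pct_daytime", "pct_rush",
    "lw_aadt_500", "density_300", "mean_gps_speed", "weekday",
    "work_related_exposure", "working",
    "temperature_c", "wind_speed_ms", "humidity_pct",
]
CANDIDATES_SUBJECT = [
    "pct_invehicle", "pct_indoor", "pct_weekday", "mean_gps_speed",
    "lw_aadt_500", "work_related_exposure", "working",
]
CANDIDATES_ACTIVITY = ["sqrt_speed", "indoor_indicator", "pct_daytime"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--tables", type=Path, default=RESULTS / "tables")
    args = ap.parse_args()

    person_day = pd.read_csv(args.tables / "person_day.csv")
    subject = pd.read_csv(args.tables / "subject.csv")
    activity = pd.read_csv(args.tables / "subject_activity.csv")

    report = run_model_suite(
        person_day, subject, activity,
        CANDIDATES_DAILY, CANDIDATES_SUBJECT, CANDIDATES_ACTIVITY,
    )

    summary = {}
    for level in ("daily", "subject", "activity"):
        res = report[level]
        print(f"\n== {level} model ==")
        print(f"screen retained: {res['screen'].retained}")
        print(f"selected (AIC):  {res['selected']}")
        fit = res["ols"]
        if fit is None:
            continue
        frame = fit.to_frame()
        print(frame.round(4).to_string(index=False))
        print(f"R^2 = {fit.r2:.3f} (adj {fit.adj_r2:.3f}), n = {fit.n}")
        frame.to_csv(args.tables / f"model_{level}.csv", index=False)
        summary[level] = {"selected": res["selected"], "r2": fit.r2,
                          "adj_r2": fit.adj_r2, "n": fit.n}
        if level == "daily" and "mixed" in res:
            mx = res["mixed"]
            print(f"mixed model (slope on {mx.slope_term}): "
                  f"var_intercept {mx.var_intercept:.3f}, "
                  f"var_slope {mx.var_slope if mx.var_slope is None else round(mx.var_slope, 3)}, "
                  f"var_residual {mx.var_residual:.3f}")
            for name, beta, se, p in mx.terms:
                print(f"  {name:>22s}  beta {beta:10.4g}  se {se:.4g}  p {p:.3g}")
            summary["daily_mixed"] = {
                "terms": [(n, b) for n, b, *_ in mx.terms],
                "var_intercept": mx.var_intercept,
                "var_slope": mx.var_slope,
                "var_residual": mx.var_residual,
                "converged": mx.converged,
            }

    with open(args.tables / "models_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"\nwrote model_*.csv and models_summary.json in {args.tables}")


if __name__ == "__main__":
    main()
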