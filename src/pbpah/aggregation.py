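"""Build the three analysis tables from QA-filtered minute records.

Exposure is averaged at three levels, mirroring the study design:

1. person-day — one row per subject and calendar day;
2. subject — one row per subject, minute-weighted over all sampling days;
3. subject × time-activity category — one row per subject and category
   (indoor / in-vehicle / other) with at least 60 min of data.

The outcome at every level is the square root of the period-mean 1-min
concentration (sqrt applied after averaging, never to individual minutes:
for skewed exposures the two differ). Percent-time covariates (indoor,
in-vehicle, daytime, rush-hour, weekday) are stored as fractions in
[0, 1]; continuous covariates are averaged over the same minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spatial_traffic import RoadNetwork, kernel_density_at, length_weighted_aadt

__all__ = [
    "temporal_flags",
    "attach_traffic_metrics",
    "build_person_day_table",
    "build_subject_table",
    "build_subject_activity_table",
    "summarize_exposure",
    "ExposureSummary",
]

DETECTION_LIMIT = 1.0  # ng/m^3, instrument floor used for geometric statistics

DAYTIME = (6, 19)  # [06:00, 19:00)
RUSH = ((6, 8), (16, 19))  # [06:00, 08:00) u [16:00, 19:00)


def temporal_flags(timestamps) -> pd.DataFrame:
    """Weekday / daytime / rush-hour indicators for tz-aware timestamps.

    weekday: Monday-Friday. daytime: [06:00, 19:00). rush: [06:00, 08:00)
    and [16:00, 19:00). All intervals are half-open at minute resolution.
    Timezone-naive input raises.
    """
    ts = pd.DatetimeIndex(pd.Series(timestamps))
    if ts.tz is None:
        raise ValueError("timestamps must be timezone-aware")
    hour = ts.hour + ts.minute / 60.0
    weekday = (ts.dayofweek < 5).astype(int)
    daytime = ((hour >= DAYTIME[0]) & (hour < DAYTIME[1])).astype(int)
    rush = np.zeros(len(ts), dtype=int)
    for lo, hi in RUSH:
        rush |= ((hour >= lo) & (hour < hi)).astype(int)
    return pd.DataFrame({"weekday": weekday, "daytime": daytime, "rush": rush})


def attach_traffic_metrics(
    minutes: pd.DataFrame,
    network: RoadNetwork,
    density_radius: float = 300.0,
    aadt_radius: float = 500.0,
) -> pd.DataFrame:
    """Add per-minute traffic covariates at the minute mean position.

    Columns added: ``density_300`` (kernel density at ``density_radius``)
    and ``lw_aadt_500`` (length-weighted AADT within ``aadt_radius``;
    NaN where no roadway intersects the buffer).
    """
    out = minutes.copy()
    dens = np.empty(len(out))
    lw = np.empty(len(out))
    for i, (x, y) in enumerate(zip(out["mean_x"], out["mean_y"])):
        dens[i] = kernel_density_at((x, y), network, density_radius)
        v = length_weighted_aadt((x, y), network, aadt_radius)
        lw[i] = np.nan if v is None else v
    out["density_300"] = dens
    out["lw_aadt_500"] = lw
    return out


def _link_weather_day(minutes_day: pd.DataFrame, weather: pd.DataFrame, max_gap_h: int = 3):
    """Day-mean weather from the nearest station, nearest-hour filled <= 3 h."""
    mx, my = minutes_day["mean_x"].mean(), minutes_day["mean_y"].mean()
    stations = weather.groupby("station_id")[["x", "y"]].first()
    dists = np.hypot(stations["x"] - mx, stations["y"] - my)
    st = weather[weather["station_id"] == dists.idxmin()]
    st_hours = st["timestamp"]
    vals = {"temperature_c": [], "wind_speed_ms": [], "humidity_pct": []}
    incomplete = False
    for hour in minutes_day["minute"].dt.floor("h").unique():
        gaps = (st_hours - hour).abs()
        if len(gaps) == 0 or gaps.min() > pd.Timedelta(hours=max_gap_h):
            incomplete = True
            continue
        row = st.loc[gaps.idxmin()]
        for k in vals:
            vals[k].append(row[k])
    means = {k: (float(np.mean(v)) if v else np.nan) for k, v in vals.items()}
    return means, incomplete


SESSION_CATEGORICALS = [
    "work_related_exposure",
    "pregnancy",
    "working",
    "housing",
    "vehicle_type",
    "income",
    "language",
]


def _covariate_row(grp: pd.DataFrame) -> dict:
    """Fraction-of-time and mean continuous covariates over a minute group."""
    flags = temporal_flags(grp["minute"])
    n = len(grp)
    row = {
        "sqrt_pah": float(np.sqrt(grp["pah_ng_m3"].mean())),
        "pct_indoor": float((grp["category"] == "indoor").sum() / n),
        "pct_invehicle": float((grp["category"] == "in_vehicle").sum() / n),
        "pct_other": float((grp["category"] == "other").sum() / n),
        "pct_daytime": float(flags["daytime"].mean()),
        "pct_rush": float(flags["rush"].mean()),
        "mean_gps_speed": float(grp["mean_speed_kmh"].mean()),
        "mean_elevation": float(grp["mean_altitude_m"].mean()),
        "n_minutes": n,
    }
    row["sqrt_speed"] = float(np.sqrt(row["mean_gps_speed"]))
    for col in ("lw_aadt_500", "density_300"):
        if col in grp:
            row[col] = float(grp[col].mean())
    return row


def build_person_day_table(
    minutes: pd.DataFrame,
    weather: pd.DataFrame | None = None,
    questionnaire: pd.DataFrame | None = None,
    sessions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per (subject, calendar day): outcome and covariates.

    ``sessions`` maps (subject_id, date) -> session for the questionnaire
    join; when absent every day belongs to session 1. ``questionnaire`` is
    keyed by (subject_id, session). Days whose weather cannot be filled
    within 3 h are flagged ``incomplete_covariate``.
    """
    rows = []
    day = minutes["minute"].dt.normalize()
    for (sid, d), grp in minutes.groupby([minutes["subject_id"], day], sort=True):
        row = {"subject_id": sid, "date": d}
        row.update(_covariate_row(grp))
        row["weekday"] = int(d.dayofweek < 5)
        row["incomplete_covariate"] = False
        if weather is not None:
            met, incomplete = _link_weather_day(grp, weather)
            row.update(met)
            row["incomplete_covariate"] = incomplete
        rows.append(row)
    table = pd.DataFrame(rows)
    if questionnaire is not None and len(table):
        if sessions is not None:
            table = table.merge(sessions, on=["subject_id", "date"], how="left")
            table["session"] = table["session"].fillna(1).astype(int)
        else:
            table["session"] = 1
        table = table.merge(
            questionnaire[["subject_id", "session"] + SESSION_CATEGORICALS],
            on=["subject_id", "session"],
            how="left",
        )
    return table


def build_subject_table(
    minutes: pd.DataFrame,
    questionnaire: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per subject, minute-weighted over every sampling day.

    The outcome is sqrt of the mean over all valid minutes (identical to
    the minute-weighted recombination of person-day means). ``weekday``
    becomes the fraction of minutes on weekdays (``pct_weekday``).
    Categorical covariates come from the subject's first session.
    """
    rows = []
    for sid, grp in minutes.groupby("subject_id", sort=True):
        row = {"subject_id": sid}
        row.update(_covariate_row(grp))
        flags = temporal_flags(grp["minute"])
        row["pct_weekday"] = float(flags["weekday"].mean())
        row["n_days"] = int(grp["minute"].dt.normalize().nunique())
        rows.append(row)
    table = pd.DataFrame(rows)
    if questionnaire is not None and len(table):
        first = (
            questionnaire.sort_values("session")
            .groupby("subject_id", as_index=False)
            .first()[["subject_id"] + SESSION_CATEGORICALS]
        )
        table = table.merge(first, on="subject_id", how="left")
    return table


def build_subject_activity_table(minutes: pd.DataFrame, min_total: int = 60) -> pd.DataFrame:
    """One row per (subject, category) with >= ``min_total`` minutes.

    Records shorter than ``min_total`` minutes across all sessions are
    excluded a priori so that each retained category average is
    representative. ``sqrt_speed`` is the sqrt of the category-mean GPS
    speed; ``indoor_indicator`` is 1 for the indoor category.
    """
    rows = []
    for (sid, cat), grp in minutes.groupby(["subject_id", "category"], sort=True):
        if len(grp) < min_total:
            continue
        flags = temporal_flags(grp["minute"])
        rows.append(
            {
                "subject_id": sid,
                "category": cat,
                "sqrt_pah": float(np.sqrt(grp["pah_ng_m3"].mean())),
                "sqrt_speed": float(np.sqrt(grp["mean_speed_kmh"].mean())),
                "pct_daytime": float(flags["daytime"].mean()),
                "indoor_indicator": int(cat == "indoor"),
                "total_minutes": len(grp),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExposureSummary:
    mean: float
    sd: float
    gm: float
    gsd: float
    skewness: float
    n: int
    n_floored: int  # values raised to the 1 ng/m^3 detection limit for log stats


def summarize_exposure(values) -> ExposureSummary:
    """Arithmetic and geometric summary of a concentration sample.

    GM = exp(mean(ln x)), GSD = exp(sd(ln x)); values below the 1 ng/m³
    detection limit are floored at the limit for the log statistics (count
    reported). Skewness is the adjusted Fisher-Pearson coefficient.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty concentration sample")
    floored = np.maximum(x, DETECTION_LIMIT)
    logs = np.log(floored)
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return ExposureSummary(
        mean=float(x.mean()),
        sd=sd,
        gm=float(np.exp(logs.mean())),
        gsd=float(np.exp(logs.std(ddof=1))) if x.size > 1 else 1.0,
        # skewness is 0 by convention for degenerate samples; scipy's
        # estimator returns nan on zero-variance input
        skewness=float(stats.skew(x, bias=False)) if (x.size > 2 and sd > 0) else 0.0,
        n=int(x.size),
        n_floored=int((x < DETECTION_LIMIT).sum()),
    )
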