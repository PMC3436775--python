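"""From raw 15-s GPS fixes to 1-min activity/exposure records.

The pipeline stage implemented here mirrors a personal-monitoring field
protocol: project raw fixes to planar metres, label every fix with one of
three time-activity categories (indoor, in-vehicle travel, other), fuse
the 15-s labels into calendar-minute records by majority vote, and join
the minute records with the 1-min particle-bound PAH concentrations from
the co-carried photoelectric aerosol sensor.

The classifier is a transparent rule-based one (rolling-median speed plus
a dwell radius around home/work anchors); it replaces the externally
trained travel-mode model used in the original field work, whose training
data is not available, and is scored with the same sensitivity /
specificity / precision formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .projection import UTM_ZONE_11N, UtmZone, geodetic_to_projected

__all__ = [
    "ClassifierParams",
    "CATEGORIES",
    "project_coordinates",
    "classify_fixes",
    "aggregate_to_minutes",
    "link_exposure",
    "classification_metrics",
]

CATEGORIES = ("indoor", "in_vehicle", "other")

#: tie-break priority for minute aggregation (first wins)
DEFAULT_PRIORITY = ("in_vehicle", "indoor", "other")

FIX_COLUMNS = ["subject_id", "timestamp", "latitude", "longitude", "speed_kmh", "altitude_m"]


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the rule-based time-activity classifier.

    speed_vehicle: rolling-median speed above which a fix is in-vehicle (km/h).
    speed_still: rolling-median speed below which a fix can be indoor (km/h).
    dwell_radius_m: max distance from a home/work anchor for the indoor rule.
    window: rolling-median window length in fixes (centred; 5 fixes = 75 s).
    """

    speed_vehicle: float = 8.0
    speed_still: float = 2.0
    dwell_radius_m: float = 50.0
    window: int = 5


def project_coordinates(fixes: pd.DataFrame, zone: UtmZone = UTM_ZONE_11N) -> pd.DataFrame:
    """Add planar ``x``/``y`` metre columns from latitude/longitude.

    Empty input returns an empty frame with the x/y columns added.
    """
    out = fixes.copy()
    if len(out) == 0:
        out["x"] = pd.Series(dtype=float)
        out["y"] = pd.Series(dtype=float)
        return out
    x, y = geodetic_to_projected(
        out["latitude"].to_numpy(), out["longitude"].to_numpy(), zone
    )
    out["x"] = x
    out["y"] = y
    return out


def _check_sorted(fixes: pd.DataFrame) -> None:
    for sid, grp in fixes.groupby("subject_id", sort=False):
        ts = grp["timestamp"].to_numpy()
        if len(ts) > 1 and not (ts[1:] > ts[:-1]).all():
            raise ValueError(f"fixes for subject {sid!r} are not strictly time-sorted")


def classify_fixes(
    fixes: pd.DataFrame,
    anchors: list[tuple[float, float]],
    params: ClassifierParams = ClassifierParams(),
) -> np.ndarray:
    """Label each fix indoor / in_vehicle / other.

    Rules, applied to the centred rolling-median speed v (km/h):
      v > speed_vehicle                          -> in_vehicle
      v < speed_still and near an anchor         -> indoor
      otherwise                                  -> other

    ``anchors`` are projected (x, y) dwell locations (home, work).
    Fixes must be strictly time-sorted per subject.
    """
    _check_sorted(fixes)
    labels = np.empty(len(fixes), dtype=object)
    pos = 0
    for _, grp in fixes.groupby("subject_id", sort=False):
        v = (
            grp["speed_kmh"]
            .rolling(params.window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        if anchors:
            ax = np.array([a[0] for a in anchors])
            ay = np.array([a[1] for a in anchors])
            dx = grp["x"].to_numpy()[:, None] - ax[None, :]
            dy = grp["y"].to_numpy()[:, None] - ay[None, :]
            near = (np.hypot(dx, dy).min(axis=1)) <= params.dwell_radius_m
        else:
            near = np.zeros(len(grp), dtype=bool)
        lab = np.where(
            v > params.speed_vehicle,
            "in_vehicle",
            np.where((v < params.speed_still) & near, "indoor", "other"),
        )
        labels[pos : pos + len(grp)] = lab
        pos += len(grp)
    return labels


def mode_with_priority(labels, priority=DEFAULT_PRIORITY) -> str:
    """Most frequent label; ties broken by fixed priority order."""
    counts = {c: 0 for c in priority}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    for cat in priority:
        if counts.get(cat, 0) == best:
            return cat
    raise ValueError("empty label set")


def aggregate_to_minutes(
    fixes: pd.DataFrame,
    labels,
    priority=DEFAULT_PRIORITY,
) -> pd.DataFrame:
    """Fuse 15-s fixes into calendar-minute records.

    Per (subject, minute): category = mode of the 15-s labels with fixed
    tie-break priority; coordinates, speed and altitude are arithmetic
    means. Minutes are half-open calendar minutes (hh:mm:00-hh:mm:59);
    partial minutes are emitted as long as they contain >= 1 fix.
    """
    df = fixes.copy()
    df["label"] = np.asarray(labels, dtype=object)
    df["minute"] = df["timestamp"].dt.floor("min")
    rows = []
    for (sid, minute), grp in df.groupby(["subject_id", "minute"], sort=True):
        rows.append(
            {
                "subject_id": sid,
                "minute": minute,
                "category": mode_with_priority(grp["label"], priority),
                "mean_x": grp["x"].mean(),
                "mean_y": grp["y"].mean(),
                "mean_speed_kmh": grp["speed_kmh"].mean(),
                "mean_altitude_m": grp["altitude_m"].mean() if "altitude_m" in grp else np.nan,
                "n_fixes": len(grp),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "minute",
            "category",
            "mean_x",
            "mean_y",
            "mean_speed_kmh",
            "mean_altitude_m",
            "n_fixes",
        ],
    )


@dataclass
class JoinReport:
    n_linked: int = 0
    gps_only: int = 0
    pah_only: int = 0


def link_exposure(minutes: pd.DataFrame, pah: pd.DataFrame) -> tuple[pd.DataFrame, JoinReport]:
    """Inner-join minute records with 1-min PAH concentrations.

    Both tables are keyed by (subject_id, minute); ``pah`` must carry a
    ``pah_ng_m3`` column. Unmatched minutes on either side are dropped and
    counted in the report, never imputed. Duplicate keys raise, naming the
    offending keys.
    """
    for name, df in (("minutes", minutes), ("pah", pah)):
        if len(df):
            dup = df.duplicated(subset=["subject_id", "minute"])
            if dup.any():
                keys = df.loc[dup, ["subject_id", "minute"]].head(5).to_records(index=False)
                raise ValueError(f"duplicate (subject, minute) keys in {name}: {list(keys)}")
    merged = minutes.merge(
        pah[["subject_id", "minute", "pah_ng_m3"]],
        on=["subject_id", "minute"],
        how="inner",
    )
    report = JoinReport(
        n_linked=len(merged),
        gps_only=len(minutes) - len(merged),
        pah_only=len(pah) - len(merged),
    )
    return merged, report


@dataclass(frozen=True)
class ClassificationMetrics:
    """Sensitivity, specificity and precision for one target category.

    A ratio with zero denominator is reported as None (absent), not zero.
    """

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0


def classification_metrics(predicted, truth, target: str) -> ClassificationMetrics:
    """Score predicted labels against truth for one category (one-vs-rest).

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); precision = TP/(TP+FP).
    """
    pred = np.asarray(predicted, dtype=object)
    true = np.asarray(truth, dtype=object)
    if len(pred) != len(true):
        raise ValueError(f"length mismatch: {len(pred)} predicted vs {len(true)} truth")
    p = pred == target
    t = true == target
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))

    def ratio(num, den):
        return num / den if den > 0 else None

    return ClassificationMetrics(
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        precision=ratio(tp, tp + fp),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )
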