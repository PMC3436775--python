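"""Data-quality filters for linked minute-level exposure records.

Three filters, applied in a fixed order:

1. in-vehicle cluster flagging — a run of consecutive in-vehicle minutes
   whose positions sit inside a small bounding circle at low mean speed is
   almost certainly misclassified dwelling (GPS scatter), not travel;
2. indoor outlier removal — 1-min indoor concentrations above 1000 ng/m³
   are attributed to indoor sources (cooking, smoke) or instrument noise,
   outside the traffic-exposure scope;
3. person-day completeness — days with fewer than 6 h (360 1-min records)
   of valid linked data are dropped entirely.

Filters only remove rows; retained rows are never altered. Re-running the
pipeline on its own output is a no-op.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint

__all__ = [
    "ClusterParams",
    "QaReport",
    "flag_vehicle_clusters",
    "remove_indoor_outliers",
    "filter_incomplete_days",
    "apply_qa",
]


@dataclass(frozen=True)
class ClusterParams:
    """Conjunctive thresholds for the in-vehicle cluster heuristic.

    A run is flagged only when BOTH its bounding-circle radius is below
    ``max_radius_m`` AND its mean speed is below ``min_speed_kmh``.
    """

    max_radius_m: float = 100.0
    min_speed_kmh: float = 10.0


@dataclass
class QaReport:
    n_input_minutes: int = 0
    n_vehicle_cluster_removed: int = 0
    n_indoor_outliers_removed: int = 0
    n_incomplete_day_minutes_removed: int = 0
    per_day_counts: dict = field(default_factory=dict)

    @property
    def n_output_minutes(self) -> int:
        return (
            self.n_input_minutes
            - self.n_vehicle_cluster_removed
            - self.n_indoor_outliers_removed
            - self.n_incomplete_day_minutes_removed
        )

    @property
    def removed_fraction(self) -> float:
        if self.n_input_minutes == 0:
            return 0.0
        return 1.0 - self.n_output_minutes / self.n_input_minutes

    def to_json(self, path) -> None:
        d = asdict(self)
        d["n_output_minutes"] = self.n_output_minutes
        d["removed_fraction"] = self.removed_fraction
        d["per_day_counts"] = {str(k): v for k, v in self.per_day_counts.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    stops = np.r_[idx[breaks] + 1, idx[-1] + 1]
    yield from zip(starts, stops)


def flag_vehicle_clusters(
    minutes: pd.DataFrame, params: ClusterParams = ClusterParams()
) -> pd.Series:
    """Boolean flag per row: suspect stationary 'in-vehicle' cluster.

    Operates on maximal runs of consecutive in-vehicle minutes per subject
    (minutes must be time-sorted per subject). Single-minute runs have
    bounding radius 0 and are flagged when their speed is below threshold.
    """
    flag = np.zeros(len(minutes), dtype=bool)
    offset = 0
    for _, grp in minutes.groupby("subject_id", sort=False):
        iv = (grp["category"] == "in_vehicle").to_numpy()
        xs = grp["mean_x"].to_numpy()
        ys = grp["mean_y"].to_numpy()
        sp = grp["mean_speed_kmh"].to_numpy()
        for start, stop in _runs(iv):
            pts = MultiPoint(list(zip(xs[start:stop], ys[start:stop])))
            radius = shapely.minimum_bounding_radius(pts)
            if radius < params.max_radius_m and sp[start:stop].mean() < params.min_speed_kmh:
                flag[offset + start : offset + stop] = True
        offset += len(grp)
    return pd.Series(flag, index=minutes.index, name="vehicle_cluster_suspect")


def remove_indoor_outliers(
    minutes: pd.DataFrame, threshold: float = 1000.0
) -> tuple[pd.DataFrame, int]:
    """Drop indoor minutes with PAH strictly above ``threshold`` ng/m³.

    Non-indoor categories are untouched regardless of concentration; a
    value exactly at the threshold is retained.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    drop = (minutes["category"] == "indoor") & (minutes["pah_ng_m3"] > threshold)
    return minutes.loc[~drop].copy(), int(drop.sum())


def filter_incomplete_days(
    minutes: pd.DataFrame, min_minutes: int = 360
) -> tuple[pd.DataFrame, pd.Series]:
    """Drop person-days with fewer than ``min_minutes`` valid 1-min records.

    6 h completeness is counted as >= 360 records in the calendar day, not
    as elapsed span. Returns the filtered frame and the per-day counts.
    """
    if len(minutes) == 0:
        return minutes.copy(), pd.Series(dtype=int)
    day = minutes["minute"].dt.normalize()
    counts = minutes.groupby([minutes["subject_id"], day]).size()
    keep_keys = set(counts[counts >= min_minutes].index)
    keep = pd.Series(
        [(s, d) in keep_keys for s, d in zip(minutes["subject_id"], day)],
        index=minutes.index,
    )
    return minutes.loc[keep].copy(), counts


def apply_qa(
    minutes: pd.DataFrame,
    cluster_params: ClusterParams = ClusterParams(),
    indoor_threshold: float = 1000.0,
    min_minutes: int = 360,
    keep_flagged: bool = False,
) -> tuple[pd.DataFrame, QaReport]:
    """Run the three filters in order and account for every removed minute.

    ``keep_flagged`` retains cluster-suspect minutes (flag only) — an
    escape hatch for inspecting the heuristic.
    """
    report = QaReport(n_input_minutes=len(minutes))
    df = minutes.copy()

    flag = flag_vehicle_clusters(df, cluster_params)
    df["vehicle_cluster_suspect"] = flag
    if not keep_flagged:
        report.n_vehicle_cluster_removed = int(flag.sum())
        df = df.loc[~flag].copy()

    df, n_outliers = remove_indoor_outliers(df, indoor_threshold)
    report.n_indoor_outliers_removed = n_outliers

    n_before = len(df)
    df, counts = filter_incomplete_days(df, min_minutes)
    report.n_incomplete_day_minutes_removed = n_before - len(df)
    report.per_day_counts = {f"{s}|{d.date()}": int(c) for (s, d), c in counts.items()}
    return df, report
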