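"""Readers and writers for the pipeline's interchange formats.

Trajectories travel as GPX 1.1 or CSV; minute concentrations, weather and
questionnaires as CSV with ISO-8601 timestamps; road networks as GeoJSON
(see :meth:`pbpah.spatial_traffic.RoadNetwork.to_geojson`).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import pandas as pd

from .projection import UTM_ZONE_11N, projected_to_geodetic

GPX_NS = "http://www.topografix.com/GPX/1/1"

#: single study timezone applied when reading timestamp columns
STUDY_TZ = "America/Los_Angeles"


def _utc_col(df: pd.DataFrame, col: str) -> pd.DataFrame:
    """Copy with a tz-aware timestamp column converted to UTC for writing.

    Mixed local UTC offsets (DST transitions) round-trip poorly through
    CSV, so timestamps are serialized in UTC and restored to the study
    timezone on read.
    """
    out = df.copy()
    if col in out and getattr(out[col].dtype, "tz", None) is not None:
        out[col] = out[col].dt.tz_convert("UTC")
    return out


def _read_ts(df: pd.DataFrame, col: str, tz: str) -> pd.DataFrame:
    df[col] = pd.to_datetime(df[col], utc=True, format="ISO8601").dt.tz_convert(tz)
    return df

FIX_CSV_COLUMNS = ["subject_id", "timestamp", "latitude", "longitude", "speed_kmh", "altitude_m"]
MINUTE_CSV_COLUMNS = [
    "subject_id",
    "minute",
    "category",
    "mean_x",
    "mean_y",
    "mean_speed_kmh",
    "mean_altitude_m",
    "pah_ng_m3",
]


def add_geodetic(fixes: pd.DataFrame, zone=UTM_ZONE_11N) -> pd.DataFrame:
    """Add latitude/longitude columns from projected x/y (inverse UTM)."""
    out = fixes.copy()
    lat, lon = projected_to_geodetic(out["x"].to_numpy(), out["y"].to_numpy(), zone)
    out["latitude"] = lat
    out["longitude"] = lon
    return out


def write_gpx(fixes: pd.DataFrame, path) -> None:
    """Write one GPX 1.1 file with a track per subject.

    Expects latitude/longitude columns (see :func:`add_geodetic`); speed
    goes into an extension element, altitude into <ele>.
    """
    ET.register_namespace("", GPX_NS)
    gpx = ET.Element(f"{{{GPX_NS}}}gpx", version="1.1", creator="pbpah")
    for sid, grp in fixes.groupby("subject_id", sort=True):
        trk = ET.SubElement(gpx, f"{{{GPX_NS}}}trk")
        ET.SubElement(trk, f"{{{GPX_NS}}}name").text = str(sid)
        seg = ET.SubElement(trk, f"{{{GPX_NS}}}trkseg")
        for row in grp.itertuples():
            pt = ET.SubElement(
                seg, f"{{{GPX_NS}}}trkpt", lat=f"{row.latitude:.8f}", lon=f"{row.longitude:.8f}"
            )
            ET.SubElement(pt, f"{{{GPX_NS}}}ele").text = f"{row.altitude_m:.2f}"
            ET.SubElement(pt, f"{{{GPX_NS}}}time").text = (
                pd.Timestamp(row.timestamp).tz_convert("UTC").strftime("%Y-%m-%dT%H:%M:%SZ")
            )
            ext = ET.SubElement(pt, f"{{{GPX_NS}}}extensions")
            ET.SubElement(ext, f"{{{GPX_NS}}}speed_kmh").text = f"{row.speed_kmh:.3f}"
    ET.ElementTree(gpx).write(path, xml_declaration=True, encoding="unicode")


def read_gpx(path) -> pd.DataFrame:
    """Read a GPX 1.1 file written by :func:`write_gpx` (or compatible)."""
    root = ET.parse(path).getroot()
    rows = []
    for trk in root.findall(f"{{{GPX_NS}}}trk"):
        name_el = trk.find(f"{{{GPX_NS}}}name")
        sid = name_el.text if name_el is not None else "unknown"
        for pt in trk.iter(f"{{{GPX_NS}}}trkpt"):
            ele = pt.find(f"{{{GPX_NS}}}ele")
            time = pt.find(f"{{{GPX_NS}}}time")
            speed_el = pt.find(f"{{{GPX_NS}}}extensions/{{{GPX_NS}}}speed_kmh")
            rows.append(
                {
                    "subject_id": sid,
                    "timestamp": pd.Timestamp(time.text) if time is not None else pd.NaT,
                    "latitude": float(pt.get("lat")),
                    "longitude": float(pt.get("lon")),
                    "speed_kmh": float(speed_el.text) if speed_el is not None else 0.0,
                    "altitude_m": float(ele.text) if ele is not None else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=FIX_CSV_COLUMNS)


def write_fixes_csv(fixes: pd.DataFrame, path) -> None:
    fixes = _utc_col(fixes, "timestamp")
    cols = [c for c in FIX_CSV_COLUMNS if c in fixes.columns]
    extra = [c for c in fixes.columns if c not in cols]
    fixes[cols + extra].to_csv(path, index=False)


def read_fixes_csv(path, tz: str = STUDY_TZ) -> pd.DataFrame:
    return _read_ts(pd.read_csv(path), "timestamp", tz)


def write_minutes_csv(minutes: pd.DataFrame, path) -> None:
    minutes = _utc_col(minutes, "minute")
    cols = [c for c in MINUTE_CSV_COLUMNS if c in minutes.columns]
    extra = [c for c in minutes.columns if c not in cols]
    minutes[cols + extra].to_csv(path, index=False)


def read_minutes_csv(path, tz: str = STUDY_TZ) -> pd.DataFrame:
    return _read_ts(pd.read_csv(path), "minute", tz)


def write_pah_csv(pah: pd.DataFrame, path) -> None:
    _utc_col(pah, "minute")[["subject_id", "minute", "pah_ng_m3"]].to_csv(path, index=False)


def read_pah_csv(path, tz: str = STUDY_TZ) -> pd.DataFrame:
    return _read_ts(pd.read_csv(path), "minute", tz)
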