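"""Reading and writing satellite-tag fix tables and derived products.

Input is a plain CSV of GPS fixes (one row per transmitted location) with
configurable column names, because vendor exports differ. Output formats are
a labelled-fix CSV that round-trips exactly, and an RFC 7946 GeoJSON
FeatureCollection of home-range polygons and labelled fix points for map
display.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry.polygon import orient

from .geometry import laea_inverse

#: Default column-name mapping: logical name -> column in the file.
DEFAULT_DIALECT = {"bird_id": "bird_id", "timestamp": "timestamp", "lat": "lat", "lon": "lon"}

_TZ_RE = re.compile(r"(Z|[+-]\d{2}:?\d{2})\s*$")


@dataclass
class Trajectory:
    """All fixes for one bird, time-sorted, with the nest at the first fix."""

    bird_id: str
    times: pd.DatetimeIndex
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self):
        if len(self.times) == 0:
            raise ValueError("trajectory must be non-empty")
        if len(self.times) != len(self.lat) or len(self.times) != len(self.lon):
            raise ValueError("times, lat and lon must have equal length")
        if len(self.times) > 1 and not (np.diff(self.times.view("int64")) > 0).all():
            raise ValueError("timestamps must be strictly increasing within a bird")
        if np.any(np.abs(self.lat) > 90.0) or np.any(np.abs(self.lon) > 180.0):
            raise ValueError("coordinates out of bounds")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def nest_lat(self) -> float:
        return float(self.lat[0])

    @property
    def nest_lon(self) -> float:
        return float(self.lon[0])


@dataclass
class ParseReport:
    """Accounting of what a read did: rows kept, dropped, and why."""

    rows_read: int = 0
    rows_kept: int = 0
    duplicate_rows_dropped: int = 0
    duplicate_timestamps_dropped: int = 0
    bad_rows: int = 0
    reasons: Counter = field(default_factory=Counter)
    naive_timestamps_assumed_utc: bool = False


def read_fixes(path, dialect=None):
    """Read a fix CSV into one :class:`Trajectory` per bird.

    Rows with unparseable timestamps or out-of-bounds coordinates are
    rejected and counted in the report, never silently coerced. Exact
    duplicate rows are dropped; duplicate timestamps within a bird keep the
    first occurrence (the velocity features divide by dt and must never see
    dt = 0). Timestamps without a timezone are assumed UTC and flagged.

    Returns
    -------
    (list of Trajectory, ParseReport)
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for logical, col in dialect.items():
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r} (for {logical})")
    df = df[[dialect["bird_id"], dialect["timestamp"], dialect["lat"], dialect["lon"]]]
    df.columns = ["bird_id", "timestamp", "lat", "lon"]

    report = ParseReport(rows_read=len(df))

    dup = df.duplicated()
    report.duplicate_rows_dropped = int(dup.sum())
    df = df[~dup]

    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="mixed")
    if df["timestamp"].map(lambda s: bool(s) and not _TZ_RE.search(s)).any():
        report.naive_timestamps_assumed_utc = True
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")

    bad_ts = ts.isna()
    bad_coord = lat.isna() | lon.isna() | (lat.abs() > 90.0) | (lon.abs() > 180.0)
    report.reasons["unparseable_timestamp"] = int(bad_ts.sum())
    report.reasons["bad_coordinate"] = int((bad_coord & ~bad_ts).sum())
    bad = bad_ts | bad_coord
    report.bad_rows = int(bad.sum())

    kept = pd.DataFrame(
        {"bird_id": df["bird_id"][~bad], "t": ts[~bad], "lat": lat[~bad], "lon": lon[~bad]}
    )
    trajectories = []
    for bird_id, grp in kept.groupby("bird_id", sort=True):
        grp = grp.sort_values("t", kind="stable")
        dup_t = grp["t"].duplicated()
        report.duplicate_timestamps_dropped += int(dup_t.sum())
        grp = grp[~dup_t]
        if len(grp) == 0:
            continue
        trajectories.append(
            Trajectory(
                bird_id=str(bird_id),
                times=pd.DatetimeIndex(grp["t"]),
                lat=grp["lat"].to_numpy(),
                lon=grp["lon"].to_numpy(),
            )
        )
        report.rows_kept += len(grp)
    return trajectories, report


def write_labeled_fixes(traj: Trajectory, labels, rules, path) -> None:
    """Write one bird's fixes with labels and rule provenance to CSV.

    The file round-trips: :func:`read_labeled_fixes` reproduces ids,
    ISO 8601 timestamps, full-precision coordinates, labels and rules.
    """
    labels = np.asarray(labels)
    rules = np.asarray(rules)
    if len(labels) != len(traj) or len(rules) != len(traj):
        raise ValueError(
            f"one label per fix required: {len(traj)} fixes, {len(labels)} labels"
        )
    df = pd.DataFrame(
        {
            "bird_id": traj.bird_id,
            "timestamp": [t.isoformat() for t in traj.times],
            "lat": [repr(float(v)) for v in traj.lat],
            "lon": [repr(float(v)) for v in traj.lon],
            "label": labels,
            "rule": rules,
        }
    )
    df.to_csv(path, index=False)


def read_labeled_fixes(path):
    """Read a labelled-fix CSV back into per-bird (Trajectory, labels, rules)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("bird_id", "timestamp", "lat", "lon", "label", "rule"):
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r}")
    out = []
    for bird_id, grp in df.groupby("bird_id", sort=True):
        traj = Trajectory(
            bird_id=str(bird_id),
            times=pd.DatetimeIndex(pd.to_datetime(grp["timestamp"], utc=True, format="ISO8601")),
            lat=grp["lat"].astype(float).to_numpy(),
            lon=grp["lon"].astype(float).to_numpy(),
        )
        out.append((traj, grp["label"].to_numpy(), grp["rule"].to_numpy()))
    return out


def _polygon_to_wgs84(poly, nest_lat: float, nest_lon: float):
    """Map a shapely polygon from the km frame to lon/lat, RFC 7946 oriented."""

    def ring_to_lonlat(coords):
        arr = np.asarray(coords)
        lat, lon = laea_inverse(arr[:, 0], arr[:, 1], nest_lat, nest_lon)
        return list(zip(lon.tolist(), lat.tolist()))

    poly = orient(poly, sign=1.0)  # exterior CCW, holes CW
    shell = ring_to_lonlat(poly.exterior.coords)
    holes = [ring_to_lonlat(r.coords) for r in poly.interiors]
    return [shell, *holes]


def export_geojson(ranges, labeled, path) -> None:
    """Export home ranges and labelled fixes as a GeoJSON FeatureCollection.

    Parameters
    ----------
    ranges : list of (bird_id, HomeRange, excursions_excluded, nest_lat, nest_lon)
        Home-range polygons in the nest-centred km frame; each is
        inverse-projected to WGS84 with its own nest as tangent point.
    labeled : list of (Trajectory, labels, rules)
        Fixes to emit as Point features with a ``label`` property.
    path : file path for the output GeoJSON.
    """
    features = []
    for bird_id, hr, excluded, nest_lat, nest_lon in ranges:
        polys = [_polygon_to_wgs84(p, nest_lat, nest_lon) for p in hr.polygon_list]
        if len(polys) == 1:
            geometry = {"type": "Polygon", "coordinates": polys[0]}
        else:
            geometry = {"type": "MultiPolygon", "coordinates": polys}
        features.append(
            {
                "type": "Feature",
                "geometry": geometry,
                "properties": {
                    "bird_id": bird_id,
                    "isopleth_level": hr.isopleth_level,
                    "area_km2": hr.area_km2,
                    "excursions_excluded": bool(excluded),
                },
            }
        )
    for traj, labels, rules in labeled:
        for i in range(len(traj)):
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [float(traj.lon[i]), float(traj.lat[i])],
                    },
                    "properties": {
                        "bird_id": traj.bird_id,
                        "timestamp": traj.times[i].isoformat(),
                        "label": str(labels[i]),
                        "rule": str(rules[i]),
                    },
                }
            )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Convenience view of a trajectory as a DataFrame."""
    return pd.DataFrame(
        {
            "bird_id": traj.bird_id,
            "timestamp": traj.times,
            "lat": traj.lat,
            "lon": traj.lon,
        }
    )


def trajectory_from_frame(df: pd.DataFrame, bird_id=None) -> Trajectory:
    """Build a Trajectory from a DataFrame with bird_id/timestamp/lat/lon."""
    if bird_id is not None:
        df = df[df["bird_id"].astype(str) == str(bird_id)]
    ids = df["bird_id"].astype(str).unique()
    if len(ids) != 1:
        raise ValueError("frame must contain exactly one bird_id (or pass bird_id=)")
    t = pd.DatetimeIndex(pd.to_datetime(df["timestamp"], utc=True))
    order = np.argsort(t.view("int64"), kind="stable")
    return Trajectory(
        bird_id=ids[0],
        times=t[order],
        lat=df["lat"].to_numpy(float)[order],
        lon=df["lon"].to_numpy(float)[order],
    )


__all__ = [
    "DEFAULT_DIALECT",
    "Trajectory",
    "ParseReport",
    "read_fixes",
    "write_labeled_fixes",
    "read_labeled_fixes",
    "export_geojson",
    "trajectory_to_frame",
    "trajectory_from_frame",
]
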