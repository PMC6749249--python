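"""Readers and writers for sensor exports, bio-geotables and result layers.

Two input dialects are supported:

* the canonical per-sample CSV with header ``t,gsr,st,lat,lon`` (time as
  UTC epoch seconds or ISO-8601, auto-detected; lat/lon optional and
  sparse), and
* the wristband export layout: a directory with ``EDA.csv`` and
  ``TEMP.csv``, each a single column of values headed by the UTC epoch
  start time on the first line and the sample rate (Hz) on the second.

Malformed numeric cells and GSR readings outside the physical sensor range
(0.01-100 μS) become entries in the missing mask — field recordings do
contain dropouts and rail values, and masking keeps them recoverable by
imputation rather than aborting the run.

Outputs are plain CSV (bio-geotable, ground truth) and RFC 7946 GeoJSON in
lon-lat order (MOS points, hotspot polygons, tracks).
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from .detection import MOSEvent
from .errors import FormatError
from .hotspots import HotspotCell
from .synth import GroundTruth, SCREventParams
from .traces import GSR_RANGE_US, GeoTrack, SignalTrace

REQUIRED_COLUMNS = ("t", "gsr", "st")


def _parse_time_column(col: pd.Series) -> np.ndarray:
    """Epoch seconds from a numeric or ISO-8601 time column."""
    t = pd.to_numeric(col, errors="coerce")
    if t.notna().all():
        return t.to_numpy(dtype=float)
    parsed = pd.to_datetime(col, utc=True, format="ISO8601", errors="coerce")
    if parsed.isna().any():
        raise FormatError("time column is neither numeric epoch seconds nor ISO-8601")
    return parsed.astype("int64").to_numpy() / 1e9


def _mask_gsr_range(values: np.ndarray) -> np.ndarray:
    """Missing mask for non-finite or physically impossible GSR readings."""
    lo, hi = GSR_RANGE_US
    finite = np.isfinite(values)
    out_of_range = finite & ((values < lo) | (values > hi))
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} GSR values outside [{lo}, {hi}] uS masked as missing",
            stacklevel=3,
        )
    return ~finite | out_of_range


def read_ediary_csv(path: str | Path) -> tuple[SignalTrace, SignalTrace, GeoTrack]:
    """Read a per-sample session CSV into (GSR trace, ST trace, GPS track)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required columns {missing_cols}")
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    t = _parse_time_column(df["t"])
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: timestamps must be strictly increasing")
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 4.0
    rate = round(rate, 6)
    gsr_vals = pd.to_numeric(df["gsr"], errors="coerce").to_numpy(dtype=float)
    st_vals = pd.to_numeric(df["st"], errors="coerce").to_numpy(dtype=float)
    gsr = SignalTrace(start_time=float(t[0]), rate=rate, values=gsr_vals,
                      kind="gsr", missing=_mask_gsr_range(gsr_vals))
    st = SignalTrace(start_time=float(t[0]), rate=rate, values=st_vals, kind="st")
    if "lat" in df.columns and "lon" in df.columns:
        lat = pd.to_numeric(df["lat"], errors="coerce").to_numpy(dtype=float)
        lon = pd.to_numeric(df["lon"], errors="coerce").to_numpy(dtype=float)
        located = np.isfinite(lat) & np.isfinite(lon)
        geo = GeoTrack(t=t[located], lat=lat[located], lon=lon[located])
    else:
        geo = GeoTrack(t=np.empty(0), lat=np.empty(0), lon=np.empty(0))
    return gsr, st, geo


def write_ediary_csv(gsr: SignalTrace, st: SignalTrace, geo: GeoTrack | None,
                     path: str | Path) -> None:
    """Write a session as the per-sample CSV dialect (round-trips with the reader)."""
    if gsr.n != st.n or gsr.rate != st.rate or gsr.start_time != st.start_time:
        raise FormatError("GSR and ST traces must share start, rate and length")
    t = gsr.times()
    lat = np.full(gsr.n, np.nan)
    lon = np.full(gsr.n, np.nan)
    if geo is not None and len(geo):
        idx = np.round((geo.t - gsr.start_time) * gsr.rate).astype(int)
        ok = (idx >= 0) & (idx < gsr.n)
        lat[idx[ok]] = geo.lat[ok]
        lon[idx[ok]] = geo.lon[ok]
    df = pd.DataFrame({"t": t, "gsr": gsr.values, "st": st.values, "lat": lat, "lon": lon})
    df.to_csv(path, index=False, float_format="%.6f")


def _read_e4_file(path: Path) -> SignalTrace:
    lines = path.read_text().strip().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: expected start line, rate line and at least one value")
    try:
        start = float(lines[0].split(",")[0])
        rate = float(lines[1].split(",")[0])
        values = np.array([float(x) for x in lines[2:]], dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed header or value line") from exc
    if rate <= 0:
        raise FormatError(f"{path}: non-positive sample rate {rate}")
    kind = "st" if path.stem.upper().startswith("TEMP") else "gsr"
    missing = _mask_gsr_range(values) if kind == "gsr" else None
    return SignalTrace(start_time=start, rate=rate, values=values, kind=kind, missing=missing)


def read_e4_export(directory: str | Path) -> tuple[SignalTrace, SignalTrace]:
    """Read a wristband export directory: EDA.csv and TEMP.csv."""
    directory = Path(directory)
    eda_path = directory / "EDA.csv"
    temp_path = directory / "TEMP.csv"
    for p in (eda_path, temp_path):
        if not p.exists():
            raise FormatError(f"required export file not found: {p}")
    return _read_e4_file(eda_path), _read_e4_file(temp_path)


def write_biogeo_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.9f")


def read_biogeo_csv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    for col in ("t", "gsr", "st", "phasic", "tonic"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing bio-geotable column {col!r}")
    return df


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_mos_geojson(events: list[MOSEvent], path: str | Path) -> None:
    """MOS detections as GeoJSON Points (lon-lat) with time and score properties."""
    features = []
    for ev in events:
        geom = None
        if not (math.isnan(ev.lat) or math.isnan(ev.lon)):
            geom = {"type": "Point", "coordinates": [ev.lon, ev.lat]}
        features.append({
            "type": "Feature",
            "geometry": geom,
            "properties": {
                "t": ev.t,
                "total_score": ev.total_score,
                "scores": list(ev.scores),
            },
        })
    Path(path).write_text(json.dumps(_feature_collection(features), indent=1))


def read_mos_geojson(path: str | Path) -> list[MOSEvent]:
    try:
        fc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: not a readable GeoJSON file") from exc
    events = []
    for feat in fc.get("features", []):
        props = feat.get("properties", {})
        geom = feat.get("geometry")
        lon, lat = (geom["coordinates"] if geom else (math.nan, math.nan))
        events.append(MOSEvent(
            t=float(props["t"]),
            total_score=float(props["total_score"]),
            scores=tuple(props.get("scores", (0, 0, 0, 0, 0))),
            lat=float(lat), lon=float(lon),
        ))
    return events


def write_hotspots_geojson(cells: list[HotspotCell], path: str | Path) -> None:
    """Hotspot cells as GeoJSON Polygons with ratio, z-score and class."""
    features = []
    for c in cells:
        features.append({
            "type": "Feature",
            "geometry": mapping(c.polygon) if c.polygon is not None else None,
            "properties": {
                "cell_id": list(c.cell_id),
                "n_seconds": c.n_seconds,
                "n_mos": c.n_mos,
                "x_j": c.x_j,
                "gi_z": None if math.isnan(c.gi_z) else c.gi_z,
                "class": c.cls,
            },
        })
    Path(path).write_text(json.dumps(_feature_collection(features), indent=1))


def write_track_geojson(track: GeoTrack, path: str | Path) -> None:
    """A GPS track as a LineString plus per-second Point features."""
    line = {
        "type": "Feature",
        "geometry": {"type": "LineString",
                     "coordinates": [[lo, la] for lo, la in zip(track.lon, track.lat)]},
        "properties": {"kind": "track"},
    }
    points = [{
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [lo, la]},
        "properties": {"t": t},
    } for t, la, lo in zip(track.t, track.lat, track.lon)]
    Path(path).write_text(json.dumps(_feature_collection([line] + points), indent=1))


TRUTH_COLUMNS = ("stimulus_time", "latency", "rise_time", "half_recovery",
                 "amplitude", "st_onset_delay", "st_drop", "st_drop_duration",
                 "expected_mos_time")


def write_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    rows = []
    for ev, tm in zip(truth.events, truth.expected_mos_times):
        rows.append({
            "stimulus_time": ev.stimulus_time, "latency": ev.latency,
            "rise_time": ev.rise_time, "half_recovery": ev.half_recovery,
            "amplitude": ev.amplitude, "st_onset_delay": ev.st_onset_delay,
            "st_drop": ev.st_drop, "st_drop_duration": ev.st_drop_duration,
            "expected_mos_time": tm,
        })
    pd.DataFrame(rows, columns=list(TRUTH_COLUMNS)).to_csv(path, index=False)


def read_truth_csv(path: str | Path) -> GroundTruth:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    for col in TRUTH_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing ground-truth column {col!r}")
    events = [SCREventParams(
        stimulus_time=row.stimulus_time, latency=row.latency, rise_time=row.rise_time,
        half_recovery=row.half_recovery, amplitude=row.amplitude,
        st_onset_delay=row.st_onset_delay, st_drop=row.st_drop,
        st_drop_duration=row.st_drop_duration,
    ) for row in df.itertuples()]
    return GroundTruth(events=events,
                       expected_mos_times=df["expected_mos_time"].tolist())
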