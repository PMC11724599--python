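"""Reading, validating and writing the three telemetry tables.

Detections, tag deployments, and receiver (station) deployments arrive as
delimited text with configurable column names; everything downstream sees a
fixed in-memory schema.  Timestamps are parsed as UTC instants — a
"detection day" anywhere in the package is the UTC calendar date.
Coordinates must already be planar metres (a single local projection is
assumed; no CRS handling is done here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import MultiPolygon, Polygon

from .config import REGIONS, SPECIES
from .errors import ParseError, SchemaError, ValidationError

DETECTION_COLUMNS = ["tag_id", "station_id", "timestamp"]
DEPLOYMENT_COLUMNS = [
    "fish_id", "tag_id", "species", "release_time", "release_x_m",
    "release_y_m", "min_delay_s", "max_delay_s", "length_cm",
]
STATION_COLUMNS = [
    "station_id", "array_name", "region", "x_m", "y_m",
    "active_start", "active_end", "damaged",
]

_TIME_FORMAT = "%Y-%m-%dT%H:%M:%SZ"


@dataclass
class ReadReport:
    """Per-file parse accounting: rows kept, rows rejected, and why."""

    path: str
    n_parsed: int = 0
    n_rejected: int = 0
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


def _apply_schema_map(df: pd.DataFrame, schema_map: dict | None,
                      required: list[str], path) -> pd.DataFrame:
    if schema_map:
        df = df.rename(columns={v: k for k, v in schema_map.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} "
                          f"(schema_map={schema_map})")
    return df


def _parse_times(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series, utc=True, format="ISO8601", errors="coerce")


def read_detections(path, schema_map: dict | None = None, *,
                    delimiter: str = ",",
                    max_bad_fraction: float = 0.01,
                    ) -> tuple[pd.DataFrame, ReadReport]:
    """Read a detection table; returns (records, report).

    Rows with unparseable timestamps are collected in the report; the read
    aborts if their fraction exceeds ``max_bad_fraction``.  Output is sorted
    by (tag_id, timestamp, station_id).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    raw = _apply_schema_map(raw, schema_map, DETECTION_COLUMNS, path)
    report = ReadReport(path=str(path))

    ts = _parse_times(raw["timestamp"])
    bad = ts.isna() | raw["tag_id"].isna() | raw["station_id"].isna()
    if bad.any():
        for i in raw.index[bad]:
            report.rejected_rows.append(
                (int(i), f"unparseable row: {raw.loc[i].to_dict()}"))
    report.n_rejected = int(bad.sum())
    if len(raw) and report.n_rejected / len(raw) > max_bad_fraction:
        raise ParseError(
            f"{path}: {report.n_rejected}/{len(raw)} rows unparseable "
            f"(> {max_bad_fraction:.1%} allowed)")

    df = pd.DataFrame({
        "tag_id": raw.loc[~bad, "tag_id"].astype(str),
        "station_id": raw.loc[~bad, "station_id"].astype(str),
        "timestamp": ts[~bad].dt.floor("s"),
    })
    df = df.sort_values(["tag_id", "timestamp", "station_id"],
                        kind="mergesort").reset_index(drop=True)
    report.n_parsed = len(df)
    return df, report


def read_deployments(path, schema_map: dict | None = None, *,
                     delimiter: str = ",",
                     length_band_cm: tuple[float, float] = (10.0, 100.0),
                     ) -> tuple[pd.DataFrame, ReadReport]:
    """Read tag-deployment metadata (one row per tagged fish)."""
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter)
    raw = _apply_schema_map(raw, schema_map, DEPLOYMENT_COLUMNS, path)
    report = ReadReport(path=str(path))

    df = raw[DEPLOYMENT_COLUMNS].copy()
    df["fish_id"] = df["fish_id"].astype(str)
    df["tag_id"] = df["tag_id"].astype(str)
    df["species"] = df["species"].astype(str)
    df["release_time"] = _parse_times(df["release_time"])
    for c in ("release_x_m", "release_y_m", "length_cm"):
        df[c] = pd.to_numeric(df[c])
    for c in ("min_delay_s", "max_delay_s"):
        df[c] = pd.to_numeric(df[c]).astype("int64")

    if df["release_time"].isna().any():
        raise ValidationError(f"{path}: unparseable release_time")
    unknown = sorted(set(df["species"]) - set(SPECIES))
    if unknown:
        raise ValidationError(f"{path}: unknown species labels {unknown}")
    dup = df["tag_id"][df["tag_id"].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(
            f"{path}: tag_id deployed more than once concurrently: {dup}")
    bad_delay = df["min_delay_s"] > df["max_delay_s"]
    if bad_delay.any():
        raise ValidationError(
            f"{path}: min_delay_s > max_delay_s for tags "
            f"{df.loc[bad_delay, 'tag_id'].tolist()}")
    if (df["min_delay_s"] <= 0).any():
        raise ValidationError(f"{path}: min_delay_s must be > 0")
    lo, hi = length_band_cm
    bad_len = (df["length_cm"] < lo) | (df["length_cm"] > hi)
    if bad_len.any():
        raise ValidationError(
            f"{path}: length_cm outside plausibility band [{lo}, {hi}] for "
            f"fish {df.loc[bad_len, 'fish_id'].tolist()}")

    df = df.sort_values("fish_id", kind="mergesort").reset_index(drop=True)
    report.n_parsed = len(df)
    return df, report


def read_stations(path, schema_map: dict | None = None, *,
                  delimiter: str = ",") -> tuple[pd.DataFrame, ReadReport]:
    """Read receiver-deployment metadata.

    A station_id may appear on several rows (separate deployment intervals);
    each row must satisfy active_start < active_end and carry one of the
    three closed region labels.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter)
    raw = _apply_schema_map(raw, schema_map, STATION_COLUMNS, path)
    report = ReadReport(path=str(path))

    df = raw[STATION_COLUMNS].copy()
    df["station_id"] = df["station_id"].astype(str)
    df["array_name"] = df["array_name"].astype(str)
    df["region"] = df["region"].astype(str)
    for c in ("x_m", "y_m"):
        df[c] = pd.to_numeric(df[c])
    df["active_start"] = _parse_times(df["active_start"])
    df["active_end"] = _parse_times(df["active_end"])
    if df["damaged"].dtype != bool:
        df["damaged"] = df["damaged"].astype(str).str.lower().map(
            {"true": True, "false": False, "1": True, "0": False})
        if df["damaged"].isna().any():
            raise ValidationError(f"{path}: unparseable damaged flag")
    df["damaged"] = df["damaged"].astype(bool)

    bad_region = ~df["region"].isin(REGIONS)
    if bad_region.any():
        rows = df.index[bad_region].tolist()
        labels = df.loc[bad_region, "region"].unique().tolist()
        raise ValidationError(
            f"{path}: unknown region labels {labels} at rows {rows}; "
            f"allowed: {list(REGIONS)}")
    if df["active_start"].isna().any() or df["active_end"].isna().any():
        raise ValidationError(f"{path}: unparseable deployment window")
    bad_win = df["active_start"] >= df["active_end"]
    if bad_win.any():
        raise ValidationError(
            f"{path}: active_start >= active_end at rows "
            f"{df.index[bad_win].tolist()}")
    if not (df["x_m"].map(lambda v: v == v and abs(v) != float('inf')).all()
            and df["y_m"].map(lambda v: v == v and abs(v) != float('inf')).all()):
        raise ValidationError(f"{path}: non-finite coordinates")

    df = df.sort_values(["station_id", "active_start"],
                        kind="mergesort").reset_index(drop=True)
    report.n_parsed = len(df)
    report.extra["stations_per_array"] = (
        df.groupby("array_name")["station_id"].nunique().to_dict())
    return df, report


def read_landmask(path) -> list[Polygon]:
    """Read a land mask: one well-known-text POLYGON/MULTIPOLYGON geometry."""
    geom = shapely_wkt.loads(Path(path).read_text().strip())
    if isinstance(geom, Polygon):
        polys = [geom]
    elif isinstance(geom, MultiPolygon):
        polys = list(geom.geoms)
    else:
        raise ValidationError(f"{path}: expected POLYGON/MULTIPOLYGON, "
                              f"got {geom.geom_type}")
    for p in polys:
        if not p.is_valid:
            raise ValidationError(f"{path}: land-mask polygon is not simple")
    return polys


def write_landmask(polygons, path) -> None:
    geom = MultiPolygon([Polygon(p.exterior, p.interiors) for p in polygons])
    Path(path).write_text(geom.wkt + "\n")


def write_dataset(df: pd.DataFrame, path, *, delimiter: str = ",") -> None:
    """Write a table deterministically (fixed column order, ISO timestamps,
    canonical row order) so that diffs between runs are stable."""
    df = df.copy()
    known_orders = [DETECTION_COLUMNS, DEPLOYMENT_COLUMNS, STATION_COLUMNS]
    for order in known_orders:
        if set(order) <= set(df.columns):
            cols = order + [c for c in df.columns if c not in order]
            df = df[cols]
            df = df.sort_values(order, kind="mergesort")
            break
    for c in df.columns:
        if pd.api.types.is_datetime64_any_dtype(df[c]):
            df[c] = df[c].dt.strftime(_TIME_FORMAT)
    df.to_csv(path, sep=delimiter, index=False, lineterminator="\n")
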