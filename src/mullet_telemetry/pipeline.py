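"""One-command orchestration: simulate -> filter -> residency -> space use ->
connectivity -> stats -> report, with a manifest that makes every run
regenerable (config hash, seed, per-stage record counts)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import connectivity as conn
from . import filters, io, residency, space_use, stats
from .config import PipelineConfig
from .simulate import SimulatedDataset, simulate_dataset

ARTEFACTS = [
    "filtered_detections.csv", "filter_report.json", "residence.csv",
    "station_medians.csv", "mcp.csv", "movements.csv",
    "presence_week.csv", "presence_month.csv", "stats_report.json",
]


@dataclass
class Bundle:
    """In-memory results of one pipeline run plus where they were written."""

    config: PipelineConfig
    dataset: SimulatedDataset
    filtered: pd.DataFrame
    filter_report: filters.FilterReport
    residence: pd.DataFrame
    usages: pd.DataFrame
    station_medians: pd.DataFrame
    mcp: pd.DataFrame
    movements: pd.DataFrame
    presence_week: pd.DataFrame
    presence_month: pd.DataFrame
    stats_report: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)
    output_dir: Path | None = None


def _config_hash(config: PipelineConfig) -> str:
    d = config.to_dict()
    d.pop("output_dir", None)  # where a run lands does not change what it is
    blob = yaml.safe_dump(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stats_entry(result: dict) -> dict:
    out = {k: result[k] for k in ("metric", "grouping", "groups", "H", "df",
                                  "p_value", "group_sizes")}
    out["group_sizes"] = list(out["group_sizes"])
    if result.get("dunn"):
        out["dunn"] = [{"pair": [d.group_i, d.group_j], "z": d.z,
                        "p_raw": d.p_raw, "p_adjusted": d.p_adjusted}
                       for d in result["dunn"]]
    return out


def run(config: PipelineConfig, *, write: bool = True) -> Bundle:
    """Execute every stage on a freshly simulated dataset.

    Identical config (including seed) yields byte-identical artefacts.
    """
    config.validate()
    sim_cfg = config.simulation
    ds = simulate_dataset(sim_cfg)

    filtered, report = filters.apply_all(
        ds.detections, ds.deployments, ds.stations, ds.mortality,
        station_min_deployment_days=config.station_min_deployment_days,
        exclude_years_from_stats=config.exclude_years_from_stats)

    res = residency.residence_records(
        filtered, ds.deployments, ds.stations, region=config.focal_region,
        min_duration_days=config.min_residence_days)
    usages = residency.local_residency_index(
        filtered, ds.deployments, ds.stations, region=config.focal_region)
    reliable, _ = filters.exclude_stations(
        ds.stations, min_deployment_days=config.station_min_deployment_days)
    med = residency.station_medians(
        usages, res, eligible_stations=set(reliable["station_id"]))
    mcp = space_use.mcp_table(filtered, ds.deployments, ds.stations, res,
                              region=config.focal_region,
                              min_stations=config.min_stations_mcp)
    movements = conn.extract_movements(filtered, ds.stations, ds.deployments,
                                       focal_region=config.focal_region)
    week = conn.presence_summary(filtered, ds.stations, ds.deployments,
                                 granularity="week")
    month = conn.presence_summary(filtered, ds.stations, ds.deployments,
                                  granularity="month")

    stats_report = []
    excl = config.exclude_years_from_stats
    timing = res[res["is_return_year"] & res["included"]].copy()
    timing["arrival_doy"] = timing["arrival"].map(residency.doy)
    timing["departure_doy"] = timing["departure"].map(residency.doy)
    for metric, table in [("arrival_doy", timing), ("departure_doy", timing),
                          ("duration_days", timing), ("ri", timing)]:
        if table["species"].nunique() >= 2 and len(table) >= 3:
            stats_report.append(_stats_entry(stats.compare_species(
                table, metric, alpha=config.significance,
                exclude_years=excl)))
    space_table = res[res["included"]]
    if space_table["species"].nunique() >= 2 and len(space_table) >= 3:
        stats_report.append(_stats_entry(stats.compare_species(
            space_table, "n_stations", alpha=config.significance,
            exclude_years=excl)))
    mcp_ok = mcp[~mcp["degenerate"]]
    if len(mcp_ok) >= 3 and mcp_ok["species"].nunique() >= 2:
        stats_report.append(_stats_entry(stats.compare_species(
            mcp_ok, "clipped_area_km2", alpha=config.significance,
            exclude_years=excl)))

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "counts": {
            "stations": int(len(ds.stations)),
            "fish": int(len(ds.deployments)),
            "detections_in": int(report.input_count),
            "detections_removed": {r.name: r.removed for r in report.rules},
            "detections_out": int(report.output_count),
            "residence_records": int(len(res)),
            "movement_events": int(len(movements)),
            "mcp_fish_years": int(len(mcp)),
        },
    }

    bundle = Bundle(config=config, dataset=ds, filtered=filtered,
                    filter_report=report, residence=res, usages=usages,
                    station_medians=med, mcp=mcp, movements=movements,
                    presence_week=week, presence_month=month,
                    stats_report=stats_report, manifest=manifest)
    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.output_dir = out
        io.write_dataset(filtered.drop(columns=["det_id"], errors="ignore"),
                         out / "filtered_detections.csv")
        (out / "filter_report.json").write_text(report.to_json() + "\n")
        _write_csv(res, out / "residence.csv")
        _write_csv(med, out / "station_medians.csv")
        _write_csv(mcp, out / "mcp.csv")
        _write_csv(movements, out / "movements.csv")
        _write_csv(week, out / "presence_week.csv")
        _write_csv(month, out / "presence_month.csv")
        (out / "stats_report.json").write_text(
            json.dumps(stats_report, indent=2) + "\n")
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return bundle


def _write_csv(df: pd.DataFrame, path) -> None:
    df = df.copy()
    for c in df.columns:
        if pd.api.types.is_datetime64_any_dtype(df[c]):
            df[c] = df[c].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    df.to_csv(path, index=False, lineterminator="\n")


def report(bundle: Bundle) -> str:
    """Human-readable summary: a per-array detection block and a per-species
    median (IQR) block for the timing, duration and RI metrics."""
    ds = bundle.dataset
    filtered = bundle.filtered
    lines = ["=== detections per array/region (filtered) ==="]
    meta = ds.stations.drop_duplicates("station_id").set_index("station_id")
    df = filtered.copy()
    df["array_name"] = df["station_id"].map(meta["array_name"])
    df["region"] = df["station_id"].map(meta["region"])
    df["fish_id"] = df["tag_id"].map(
        ds.deployments.set_index("tag_id")["fish_id"])
    summary = (df.groupby(["array_name", "region"])
               .agg(n_fish=("fish_id", "nunique"),
                    n_stations=("station_id", "nunique"),
                    n_detections=("fish_id", "size")))
    for region in sorted(ds.stations["region"].unique()):
        arrays = sorted(ds.stations.loc[ds.stations["region"] == region,
                                        "array_name"].unique())
        for a in arrays:
            if (a, region) in summary.index:
                row = summary.loc[(a, region)]
                lines.append(f"  {a:<18s} {region:<11s} "
                             f"{row['n_fish']:>4d} fish  "
                             f"{row['n_stations']:>4d} stations  "
                             f"{row['n_detections']:>8d} detections")
            else:
                lines.append(f"  {a:<18s} {region:<11s}    0 fish     "
                             f"0 stations         0 detections")

    lines.append("")
    lines.append("=== return-year residence (duration > threshold) ===")
    timing = bundle.residence[
        bundle.residence["is_return_year"] & bundle.residence["included"]].copy()
    if timing.empty:
        lines.append("  (no eligible return-year records)")
    else:
        timing["arrival_doy"] = timing["arrival"].map(residency.doy)
        timing["departure_doy"] = timing["departure"].map(residency.doy)
        for species, g in timing.groupby("species"):
            lines.append(f"  {species} (n = {len(g)} fish-years)")
            for label, col, fmt in [("arrival DOY", "arrival_doy", ".0f"),
                                    ("departure DOY", "departure_doy", ".0f"),
                                    ("duration (d)", "duration_days", ".0f"),
                                    ("RI", "ri", ".3f")]:
                q1, q2, q3 = g[col].quantile([0.25, 0.5, 0.75])
                lines.append(f"    {label:<14s} median {q2:{fmt}}  "
                             f"IQR {q1:{fmt}}-{q3:{fmt}}")
    return "\n".join(lines)
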