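#!/usr/bin/env python
"""Space use: station counts, MCP areas, and per-station median RI_stat.

For each fish-year detected > 5 days at >= 3 reliable stations, computes
the minimum convex polygon over the stations used and its area in km²; for
each station the median share of fish-years' detection days (RI_stat).
Stations damaged or deployed < 90 days are excluded from the per-station
summaries.
"""

import argparse
from pathlib import Path

import mullet_telemetry as mt
from mullet_telemetry.io import (read_deployments, read_detections,
                                 read_stations)
from mullet_telemetry.pipeline import _write_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--filtered", type=Path,
                    default=Path("results/filtered/filtered_detections.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results/space_use"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    det, _ = read_detections(args.filtered)
    dep, _ = read_deployments(args.indir / "deployments.csv")
    stations, _ = read_stations(args.indir / "stations.csv")

    res = mt.residence_records(det, dep, stations)
    mcp = mt.mcp_table(det, dep, stations, res)
    _write_csv(mcp, args.outdir / "mcp.csv")

    use = mt.local_residency_index(det, dep, stations)
    reliable, excluded = mt.exclude_stations(stations)
    med = mt.station_medians(use, res,
                             eligible_stations=set(reliable["station_id"]))
    _write_csv(med, args.outdir / "station_medians.csv")

    ok = mcp[~mcp["degenerate"]]
    print(f"{len(mcp)} eligible fish-years (> 5 days, >= 3 stations); "
          f"{len(mcp) - len(ok)} degenerate (collinear) hulls excluded")
    for species, g in ok.groupby("species"):
        print(f"  {species:<9s} median MCP {g['clipped_area_km2'].median():7.1f} km² "
              f"(IQR {g['clipped_area_km2'].quantile(0.25):.1f}-"
              f"{g['clipped_area_km2'].quantile(0.75):.1f}, n={len(g)})")
    for species, g in res[res['included']].groupby("species"):
        print(f"  {species:<9s} median stations/fish-year: "
              f"{g['n_stations'].median():.1f}")
    print(f"{len(excluded)} station deployments excluded "
          f"(damaged or < 90 d); per-station medians for "
          f"{med['station_id'].nunique() if len(med) else 0} stations "
          f"written to {args.outdir}/")


if __name__ == "__main__":
    main()
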