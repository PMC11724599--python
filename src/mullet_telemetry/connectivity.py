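"""Regional connectivity: cross-region movement events and presence summaries.

A movement event is an adjacent pair of detections of one fish whose
stations lie in different regions; its direction is classified relative to
the focal region (outbound when the origin is focal, inbound when the
destination is focal, external otherwise).  No minimum displacement, speed
or elapsed-time bound is applied — consecutive cross-region detections
define the movement.  Presence summaries count distinct fish per region and
ISO week / calendar month; a fish detected in two regions within one period
is counted once in each.
"""

from __future__ import annotations

from typing import Optional

import networkx as nx
import pandas as pd

from .config import REGIONS
from .errors import ValidationError

MOVEMENT_COLUMNS = [
    "fish_id", "species", "origin_station", "destination_station",
    "origin_region", "destination_region", "t_origin", "t_destination",
    "direction", "year",
]


def classify_direction(origin_region: str, destination_region: str,
                       focal_region: str = "wadden_sea") -> str:
    """Pure direction classification of one ordered region pair."""
    for r in (origin_region, destination_region, focal_region):
        if r not in REGIONS:
            raise ValidationError(f"unknown region {r!r}")
    if origin_region == destination_region:
        raise ValidationError("a movement must connect two distinct regions")
    if origin_region == focal_region:
        return "outbound_from_focal"
    if destination_region == focal_region:
        return "inbound_to_focal"
    return "external"


def extract_movements(detections: pd.DataFrame, stations: pd.DataFrame,
                      deployments: Optional[pd.DataFrame] = None, *,
                      focal_region: str = "wadden_sea") -> pd.DataFrame:
    """One event per adjacent cross-region detection pair, per fish.

    The origin is the last detection in the previous region, the destination
    the first in the new region; the event year is the year of the origin
    detection.
    """
    region_of = stations.drop_duplicates("station_id").set_index(
        "station_id")["region"]
    unknown = sorted(set(detections["station_id"]) - set(region_of.index))
    if unknown:
        raise ValidationError(f"detections at unregioned stations: {unknown}")
    df = detections.sort_values(["tag_id", "timestamp", "station_id"],
                                kind="mergesort").copy()
    df["region"] = df["station_id"].map(region_of)
    if deployments is not None:
        meta = deployments.set_index("tag_id")
        df["fish_id"] = df["tag_id"].map(meta["fish_id"])
        df["species"] = df["tag_id"].map(meta["species"])
    else:
        df["fish_id"] = df["tag_id"]
        df["species"] = "other"

    rows = []
    for fish, g in df.groupby("fish_id", sort=True):
        region = g["region"].to_numpy()
        change = region[1:] != region[:-1]
        for i in change.nonzero()[0]:
            o, d = g.iloc[i], g.iloc[i + 1]
            rows.append({
                "fish_id": fish, "species": o["species"],
                "origin_station": o["station_id"],
                "destination_station": d["station_id"],
                "origin_region": o["region"],
                "destination_region": d["region"],
                "t_origin": o["timestamp"], "t_destination": d["timestamp"],
                "direction": classify_direction(o["region"], d["region"],
                                                focal_region),
                "year": int(o["timestamp"].year),
            })
    return pd.DataFrame(rows, columns=MOVEMENT_COLUMNS)


def presence_summary(detections: pd.DataFrame, stations: pd.DataFrame,
                     deployments: Optional[pd.DataFrame] = None, *,
                     granularity: str = "week") -> pd.DataFrame:
    """Distinct-fish counts per species, region and ISO week / month."""
    if granularity not in ("week", "month"):
        raise ValidationError("granularity must be 'week' or 'month'")
    region_of = stations.drop_duplicates("station_id").set_index(
        "station_id")["region"]
    df = detections.copy()
    df["region"] = df["station_id"].map(region_of)
    if df["region"].isna().any():
        raise ValidationError("detections at unregioned stations")
    if deployments is not None:
        meta = deployments.set_index("tag_id")
        df["fish_id"] = df["tag_id"].map(meta["fish_id"])
        df["species"] = df["tag_id"].map(meta["species"])
    else:
        df["fish_id"] = df["tag_id"]
        df["species"] = "other"
    if granularity == "week":
        iso = df["timestamp"].dt.isocalendar()
        df["period"] = (iso["year"].astype(str) + "-W"
                        + iso["week"].astype(str).str.zfill(2))
    else:
        df["period"] = df["timestamp"].dt.strftime("%Y-%m")
    out = (df.groupby(["species", "region", "period"], sort=True)["fish_id"]
           .nunique().rename("n_unique_fish").reset_index())
    return out


def relative_monthly_presence(monthly: pd.DataFrame) -> pd.DataFrame:
    """Normalise monthly counts per species across regions within a month."""
    out = monthly.copy()
    total = out.groupby(["species", "period"])["n_unique_fish"].transform("sum")
    out["relative_presence"] = out["n_unique_fish"] / total
    return out


def connectivity_graph(events: pd.DataFrame, *,
                       level: str = "station_to_station") -> nx.DiGraph:
    """Aggregate movement events into a weighted directed graph.

    ``level`` chooses the destination aggregation: exact station
    ("station_to_station") or destination region ("station_to_region",
    mirroring origin-station nodes with region sinks).  Edge weights sum to
    the number of events.
    """
    if level not in ("station_to_station", "station_to_region"):
        raise ValidationError(f"unknown aggregation level {level!r}")
    dest = ("destination_station" if level == "station_to_station"
            else "destination_region")
    g = nx.DiGraph()
    if events.empty:
        return g
    weights = events.groupby(["origin_station", dest]).size()
    for (o, d), w in weights.items():
        g.add_edge(o, d, weight=int(w))
    return g


def write_edge_list(graph: nx.DiGraph, path) -> None:
    """Write the aggregated graph as a delimited origin,destination,weight list."""
    rows = [{"origin": o, "destination": d, "weight": data["weight"]}
            for o, d, data in sorted(graph.edges(data=True))]
    pd.DataFrame(rows, columns=["origin", "destination", "weight"]).to_csv(
        path, index=False, lineterminator="\n")
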