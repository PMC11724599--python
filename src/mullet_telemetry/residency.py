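"""Per fish-year residency metrics.

Arrival and departure are the first and last detection of a fish in the
focal region in a calendar year; residence duration is the inclusive day
count between them, so the residency index

    RI = (number of distinct UTC detection dates) / (residence duration)

is bounded in (0, 1].  The per-station local residency index

    RI_stat = (days detected at one station) / (days detected in the array)

measures a station's share of a fish-year's detection days; its per
fish-year sum is >= 1 because a fish can be detected at several stations on
one date.  Timing, duration and RI statistics use only "return years" —
calendar years after the year of tagging — so that arrival is not
confounded by capture date, and only fish-years with residence duration
strictly greater than a threshold (default 5 days), which screens out
partial residence periods seen only while entering or leaving the array.
"""

from __future__ import annotations

import datetime
from typing import Optional

import pandas as pd

from .errors import ValidationError

RESIDENCE_COLUMNS = [
    "fish_id", "species", "year", "region", "arrival", "departure",
    "duration_days", "n_detection_days", "ri", "n_stations",
    "is_return_year", "included",
]
USAGE_COLUMNS = ["fish_id", "species", "year", "station_id",
                 "n_days_at_station", "ri_stat"]


def doy(date) -> int:
    """1-based day of year (Jan 1 -> 1; Dec 31 -> 365/366)."""
    if isinstance(date, (pd.Timestamp, datetime.datetime)):
        date = date.date()
    return date.timetuple().tm_yday


def _regional(detections: pd.DataFrame, deployments: pd.DataFrame,
              stations: pd.DataFrame, region: str) -> pd.DataFrame:
    region_of = stations.drop_duplicates("station_id").set_index(
        "station_id")["region"]
    unknown = sorted(set(detections["station_id"]) - set(region_of.index))
    if unknown:
        raise ValidationError(f"detections at unregioned stations: {unknown}")
    df = detections.copy()
    df["region"] = df["station_id"].map(region_of)
    df = df[df["region"] == region]
    meta = deployments.set_index("tag_id")
    df["fish_id"] = df["tag_id"].map(meta["fish_id"])
    df["species"] = df["tag_id"].map(meta["species"])
    df["release_year"] = df["tag_id"].map(meta["release_time"].dt.year)
    df["year"] = df["timestamp"].dt.year
    df["date"] = df["timestamp"].dt.floor("D")
    return df


def residence_records(detections: pd.DataFrame,
                      deployments: pd.DataFrame,
                      stations: pd.DataFrame, *,
                      region: str = "wadden_sea",
                      min_duration_days: int = 5) -> pd.DataFrame:
    """One record per (fish, calendar year) with >= 1 detection in region.

    ``included`` marks fish-years whose inclusive duration exceeds
    ``min_duration_days`` (strict >); the return-year restriction is left to
    the caller, via the ``is_return_year`` flag, so occurrence summaries can
    keep all years.
    """
    df = _regional(detections, deployments, stations, region)
    if df.empty:
        return pd.DataFrame(columns=RESIDENCE_COLUMNS)
    g = df.groupby(["fish_id", "year"], sort=True)
    rec = g.agg(
        species=("species", "first"),
        arrival=("timestamp", "min"),
        departure=("timestamp", "max"),
        n_detection_days=("date", "nunique"),
        n_stations=("station_id", "nunique"),
        release_year=("release_year", "first"),
    ).reset_index()
    rec["region"] = region
    rec["duration_days"] = (
        (rec["departure"].dt.floor("D") - rec["arrival"].dt.floor("D"))
        .dt.days + 1)
    rec["ri"] = rec["n_detection_days"] / rec["duration_days"]
    rec["is_return_year"] = rec["year"] > rec["release_year"]
    rec["included"] = rec["duration_days"] > min_duration_days
    return rec[RESIDENCE_COLUMNS]


def residency_index(record) -> float:
    """RI of one residence record (row or mapping)."""
    duration = record["duration_days"]
    if duration < 1:
        raise ValidationError("duration_days must be >= 1")
    return record["n_detection_days"] / duration


def local_residency_index(detections: pd.DataFrame,
                          deployments: pd.DataFrame,
                          stations: pd.DataFrame, *,
                          region: str = "wadden_sea") -> pd.DataFrame:
    """Station usage per fish-year: detection days per station and RI_stat."""
    df = _regional(detections, deployments, stations, region)
    if df.empty:
        return pd.DataFrame(columns=USAGE_COLUMNS)
    per_station = (df.groupby(["fish_id", "year", "station_id"], sort=True)
                   .agg(species=("species", "first"),
                        n_days_at_station=("date", "nunique"))
                   .reset_index())
    total_days = (df.groupby(["fish_id", "year"])["date"].nunique()
                  .rename("n_detection_days").reset_index())
    out = per_station.merge(total_days, on=["fish_id", "year"])
    out["ri_stat"] = out["n_days_at_station"] / out["n_detection_days"]
    return out[USAGE_COLUMNS]


def station_medians(usages: pd.DataFrame,
                    residence: pd.DataFrame, *,
                    eligible_stations: Optional[set] = None,
                    ) -> pd.DataFrame:
    """Median RI_stat per station over eligible fish-years.

    Eligibility: fish-years flagged ``included`` in the residence table
    (duration > threshold); stations restricted to ``eligible_stations``
    when given (reliable deployments only).  Stations visited by no eligible
    fish are absent from the output, not zero.
    """
    elig = residence.loc[residence["included"], ["fish_id", "year"]]
    use = usages.merge(elig, on=["fish_id", "year"])
    if eligible_stations is not None:
        use = use[use["station_id"].isin(eligible_stations)]
    if use.empty:
        return pd.DataFrame(columns=["station_id", "species",
                                     "median_ri_stat", "n_fish_years"])
    out = (use.groupby(["station_id", "species"], sort=True)["ri_stat"]
           .agg(median_ri_stat="median", n_fish_years="size").reset_index())
    return out


def station_count(detections: pd.DataFrame, deployments: pd.DataFrame,
                  stations: pd.DataFrame, fish_id: str, year: int, *,
                  region: str = "wadden_sea") -> int:
    """Distinct stations with >= 1 retained detection for one fish-year."""
    df = _regional(detections, deployments, stations, region)
    sel = df[(df["fish_id"] == fish_id) & (df["year"] == year)]
    return int(sel["station_id"].nunique())
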