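"""False-detection filter cascade and exclusion rules.

The cascade removes, in this fixed order: (1) detections logged before the
tag was deployed, (2) exact duplicates — the same transmitter at the same
station at precisely the same second, (3) records closer to the previously
retained record at the same (tag, station) than the tag's minimum
transmission delay, (4) single detections with no companion at the same
(tag, station) within +/- 24 h, and finally (5) all records of fish known to
have died.  Simultaneous receptions of one transmission by two overlapping
stations are physically valid and are retained but counted.

Every rule reports examined/removed counts; the counts reconcile exactly
with input minus output, and applying the cascade twice equals applying it
once.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

_KEY = ["tag_id", "station_id", "timestamp"]
_DAY_S = 24 * 3600


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["tag_id", "timestamp", "station_id"],
                          kind="mergesort").reset_index(drop=True)


@dataclass
class RuleStats:
    name: str
    examined: int
    removed: int


@dataclass
class FilterReport:
    """Auditable record of one cascade run."""

    input_count: int = 0
    output_count: int = 0
    rules: list[RuleStats] = field(default_factory=list)
    cross_station_simultaneities: int = 0
    mortality_fish: list[str] = field(default_factory=list)
    station_exclusions: list[dict] = field(default_factory=list)
    excluded_years_from_stats: list[int] = field(default_factory=list)

    @property
    def total_removed(self) -> int:
        return sum(r.removed for r in self.rules)

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "output_count": self.output_count,
            "rules": [{"name": r.name, "examined": r.examined,
                       "removed": r.removed} for r in self.rules],
            "cross_station_simultaneities": self.cross_station_simultaneities,
            "mortality_fish": self.mortality_fish,
            "station_exclusions": self.station_exclusions,
            "excluded_years_from_stats": self.excluded_years_from_stats,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        lines = [f"filter cascade: {self.input_count} -> {self.output_count} "
                 f"records ({self.total_removed} removed)"]
        for r in self.rules:
            lines.append(f"  {r.name:<20s} examined {r.examined:>9d}  "
                         f"removed {r.removed:>7d}")
        lines.append(f"  cross-station simultaneities retained: "
                     f"{self.cross_station_simultaneities}")
        return "\n".join(lines)


def filter_predeployment(detections: pd.DataFrame,
                         deployments: pd.DataFrame,
                         ) -> tuple[pd.DataFrame, int]:
    """Drop detections strictly before the matching tag's release time.

    A record timestamped exactly at release is retained ("prior to" is
    strict).  Unknown tag ids are an error.
    """
    unknown = sorted(set(detections["tag_id"]) - set(deployments["tag_id"]))
    if unknown:
        raise ValidationError(
            f"detections carry tags without a deployment record: {unknown}")
    release = deployments.set_index("tag_id")["release_time"]
    rel = detections["tag_id"].map(release)
    keep = detections["timestamp"] >= rel
    out = _canonical(detections[keep])
    return out, int((~keep).sum())


def filter_duplicates(detections: pd.DataFrame,
                      ) -> tuple[pd.DataFrame, int, int]:
    """Keep exactly one of identical (tag, station, timestamp) records.

    Returns (records, n_removed, n_cross_station_simultaneities) where a
    simultaneity is one (tag, timestamp) heard at more than one station —
    retained, because overlapping receivers can both hear one transmission.
    """
    df = _canonical(detections)
    dup = df.duplicated(_KEY, keep="first")
    out = df[~dup].reset_index(drop=True)
    simul = (out.groupby(["tag_id", "timestamp"], sort=False)["station_id"]
             .nunique() > 1).sum()
    return out, int(dup.sum()), int(simul)


def _min_delay_scan(times_s: np.ndarray, min_delay: int) -> np.ndarray:
    """Sequential scan of one (tag, station) group; True = keep.

    A record is dropped when its gap to the previously *retained* record is
    > 0 and < min_delay, so a run of ghosts cannot shield each other.
    """
    keep = np.ones(times_s.shape, dtype=bool)
    last = times_s[0]
    for i in range(1, len(times_s)):
        gap = times_s[i] - last
        if 0 < gap < min_delay:
            keep[i] = False
        else:
            last = times_s[i]
    return keep


def filter_min_delay(detections: pd.DataFrame,
                     deployments: pd.DataFrame,
                     ) -> tuple[pd.DataFrame, int]:
    """Drop records violating the tag's minimum transmission delay.

    Scanned chronologically per (tag, station) against the last retained
    record; the later record of a violating pair is removed.
    """
    missing = sorted(set(detections["tag_id"]) - set(deployments["tag_id"]))
    if missing:
        raise ValidationError(f"no min_delay_s known for tags: {missing}")
    if detections.empty:
        return detections.reset_index(drop=True), 0
    df = detections.sort_values(["tag_id", "station_id", "timestamp"],
                                kind="mergesort").reset_index(drop=True)
    min_delay = df["tag_id"].map(
        deployments.set_index("tag_id")["min_delay_s"]).to_numpy()
    t = df["timestamp"].astype("int64").to_numpy() // 10**9
    group = (df["tag_id"].astype("category").cat.codes.to_numpy().astype(np.int64)
             * (df["station_id"].nunique() + 1)
             + df["station_id"].astype("category").cat.codes.to_numpy())
    new_group = np.empty(len(df), dtype=bool)
    new_group[0] = True
    new_group[1:] = group[1:] != group[:-1]
    gap = np.empty(len(df), dtype=np.int64)
    gap[0] = np.iinfo(np.int64).max
    gap[1:] = t[1:] - t[:-1]
    gap[new_group] = np.iinfo(np.int64).max

    candidate = (gap > 0) & (gap < min_delay)
    keep = np.ones(len(df), dtype=bool)
    if candidate.any():
        # only groups containing a violation need the sequential scan
        starts = np.flatnonzero(new_group)
        ends = np.append(starts[1:], len(df))
        for s, e in zip(starts, ends):
            if candidate[s:e].any():
                keep[s:e] = _min_delay_scan(t[s:e], int(min_delay[s]))
    out = _canonical(df[keep])
    return out, int((~keep).sum())


def filter_singletons_24h(detections: pd.DataFrame,
                          ) -> tuple[pd.DataFrame, int]:
    """Drop records with no companion at the same (tag, station) within 24 h.

    Evaluation is simultaneous on the rule's input: two records 25 h apart
    with nothing else are *both* removed, each being alone in its window.
    A companion at exactly 24 h rescues a record.
    """
    if detections.empty:
        return detections.reset_index(drop=True), 0
    df = detections.sort_values(["tag_id", "station_id", "timestamp"],
                                kind="mergesort").reset_index(drop=True)
    t = df["timestamp"].astype("int64").to_numpy() // 10**9
    codes = (df["tag_id"].astype("category").cat.codes.to_numpy().astype(np.int64)
             * (df["station_id"].nunique() + 1)
             + df["station_id"].astype("category").cat.codes.to_numpy())
    n = len(df)
    same_prev = np.zeros(n, dtype=bool)
    same_next = np.zeros(n, dtype=bool)
    same_prev[1:] = codes[1:] == codes[:-1]
    same_next[:-1] = codes[1:] == codes[:-1]
    gap_prev = np.full(n, np.iinfo(np.int64).max)
    gap_next = np.full(n, np.iinfo(np.int64).max)
    gap_prev[1:] = t[1:] - t[:-1]
    gap_next[:-1] = t[1:] - t[:-1]
    keep = (same_prev & (gap_prev <= _DAY_S)) | (same_next & (gap_next <= _DAY_S))
    out = _canonical(df[keep])
    return out, int((~keep).sum())


def remove_mortality(detections: pd.DataFrame,
                     mortality: Optional[pd.DataFrame],
                     deployments: pd.DataFrame, *,
                     mode: str = "all") -> tuple[pd.DataFrame, int, list[str]]:
    """Drop records of fish listed as dead.

    ``mortality`` has columns fish_id and (optionally) death_time.  Default
    mode "all" removes every record of a listed fish (the study excluded
    dead individuals outright); mode "after_death" removes only records
    after the death time where one is given.
    """
    if mortality is None or len(mortality) == 0:
        return _canonical(detections), 0, []
    if mode not in ("all", "after_death"):
        raise ValidationError(f"unknown mortality mode {mode!r}")
    known = set(deployments["fish_id"])
    unknown = sorted(set(mortality["fish_id"].astype(str)) - known)
    if unknown:
        warnings.warn(f"mortality table lists unknown fish: {unknown}",
                      stacklevel=2)
    fish_to_tag = deployments.set_index("fish_id")["tag_id"]
    listed = mortality[mortality["fish_id"].astype(str).isin(known)].copy()
    listed["tag_id"] = listed["fish_id"].astype(str).map(fish_to_tag)

    drop = pd.Series(False, index=detections.index)
    if mode == "all" or "death_time" not in listed.columns:
        drop = detections["tag_id"].isin(set(listed["tag_id"]))
    else:
        death = listed.set_index("tag_id")["death_time"]
        dt = detections["tag_id"].map(death)
        in_table = detections["tag_id"].isin(set(listed["tag_id"]))
        drop = in_table & (dt.isna() | (detections["timestamp"] > dt))
    out = _canonical(detections[~drop])
    return out, int(drop.sum()), sorted(listed["fish_id"].astype(str))


def exclude_stations(stations: pd.DataFrame, *,
                     min_deployment_days: int = 90,
                     ) -> tuple[pd.DataFrame, list[dict]]:
    """Partition station deployments into reliable and excluded.

    A deployment row is excluded when the receiver was damaged or its active
    span is strictly shorter than ``min_deployment_days`` (90 d = half a
    standard 6-month deployment).  The exclusion applies to occurrence and
    per-station space-use summaries, not to arrival/departure timing.
    """
    span_days = ((stations["active_end"] - stations["active_start"])
                 / pd.Timedelta(days=1))
    damaged = stations["damaged"].astype(bool)
    short = span_days < min_deployment_days
    excluded = []
    for i in stations.index[damaged | short]:
        reason = "damaged" if damaged.loc[i] else "short_deployment"
        excluded.append({"station_id": stations.loc[i, "station_id"],
                         "reason": reason})
    kept = stations[~(damaged | short)].reset_index(drop=True)
    return kept, excluded


def restrict_to_stations(detections: pd.DataFrame,
                         stations: pd.DataFrame) -> pd.DataFrame:
    """Subset detections to the given station deployments."""
    return _canonical(
        detections[detections["station_id"].isin(set(stations["station_id"]))])


def apply_all(detections: pd.DataFrame,
              deployments: pd.DataFrame,
              stations: Optional[pd.DataFrame] = None,
              mortality: Optional[pd.DataFrame] = None, *,
              mortality_mode: str = "all",
              station_min_deployment_days: int = 90,
              exclude_years_from_stats: Optional[list[int]] = None,
              ) -> tuple[pd.DataFrame, FilterReport]:
    """Run the full cascade in the documented order and report every rule.

    Station exclusions are *recorded* in the report (they scope occurrence
    and per-station analyses) but do not remove detections here; excluded
    statistical years are likewise recorded, not dropped, so that data
    summaries retain them.
    """
    report = FilterReport(input_count=len(detections))
    df = _canonical(detections)

    df, n = filter_predeployment(df, deployments)
    report.rules.append(RuleStats("predeployment", report.input_count, n))

    before = len(df)
    df, n, simul = filter_duplicates(df)
    report.rules.append(RuleStats("duplicates", before, n))
    report.cross_station_simultaneities = simul

    before = len(df)
    df, n = filter_min_delay(df, deployments)
    report.rules.append(RuleStats("min_delay", before, n))

    before = len(df)
    df, n = filter_singletons_24h(df)
    report.rules.append(RuleStats("singletons_24h", before, n))

    before = len(df)
    df, n, fish = remove_mortality(df, mortality, deployments,
                                   mode=mortality_mode)
    report.rules.append(RuleStats("mortality", before, n))
    report.mortality_fish = fish

    if stations is not None:
        _, excl = exclude_stations(
            stations, min_deployment_days=station_min_deployment_days)
        report.station_exclusions = excl
    report.excluded_years_from_stats = list(exclude_years_from_stats or [])
    report.output_count = len(df)
    assert report.input_count - report.output_count == report.total_removed
    return df, report


def flag_mortality_candidates(detections: pd.DataFrame,
                              deployments: pd.DataFrame, *,
                              min_continuous_days: int = 14) -> pd.DataFrame:
    """Convenience heuristic: flag fish whose detection profile looks dead.

    A fish is flagged when it is detected at a single station on every one
    of >= ``min_continuous_days`` consecutive UTC dates with no detection
    anywhere else in that span — the signature of a tag transmitting from a
    fixed position.  Input to a human decision, not a filter rule.
    """
    df = detections.merge(deployments[["tag_id", "fish_id"]], on="tag_id")
    df["date"] = df["timestamp"].dt.floor("D")
    days = (df.groupby(["fish_id", "date"])["station_id"]
            .agg(["nunique", "first"]).reset_index())
    out = []
    for fish, g in days.groupby("fish_id"):
        g = g.sort_values("date")
        run_len, run_station, run_start = 0, None, None
        prev_date = None
        for _, row in g.iterrows():
            contiguous = (prev_date is not None
                          and row["date"] - prev_date == pd.Timedelta(days=1))
            if (row["nunique"] == 1 and contiguous
                    and row["first"] == run_station):
                run_len += 1
            elif row["nunique"] == 1:
                run_len, run_station, run_start = 1, row["first"], row["date"]
            else:
                run_len, run_station = 0, None
            prev_date = row["date"]
            if run_len >= min_continuous_days:
                out.append({"fish_id": fish, "station_id": run_station,
                            "run_start": run_start, "run_days": run_len})
                break
    return pd.DataFrame(out, columns=["fish_id", "station_id",
                                      "run_start", "run_days"])
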