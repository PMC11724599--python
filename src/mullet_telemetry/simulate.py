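"""Ground-truthed synthetic acoustic-telemetry generator.

The generator emulates the statistical structure of a seasonal coastal
residency study: a dense receiver grid in a shallow focal sea, sparse
offshore receiver blocks far to the south, one freshwater receiver behind a
sluice barrier, and two species of tagged fish that differ in arrival
timing, mobility, site fidelity, and affinity for fresh water.

Movement is a daily centre-of-activity model.  During the residence season
a fish either sits near its current anchor station (probability
``station_fidelity``; within ``anchor_radius_m``, i.e. inside detection
range) or roams with a Gaussian step of scale ``mobility_step_m``,
re-anchoring whenever the roam lands within maximum detection range of a
station.  Outside the season the fish is offshore, passing an offshore
receiver on a given day with probability ``offshore_detection_prob``.  Tags
transmit with gaps uniform in [min_delay, max_delay]; each transmission is
heard independently by every in-range active receiver with a two-point
logistic range model, during a daily accessibility window (a crude stand-in
for tidal constraints) of ``in_range_hours_per_day``.

Every emitted detection carries a ground-truth label (true, false_positive,
duplicate, subdelay_ghost); per-fish truth records arrival/departure per
year, the station-visit log, and death times.  Identical configurations
(including the seed) produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import SimulationConfig
from .errors import ValidationError

_DAY_S = 86400


# ----------------------------------------------------------------------
# detection-range model
# ----------------------------------------------------------------------
def detection_probability(distance_m, d50_m: float = 149.0,
                          d_max_m: float = 610.0,
                          p_at_dmax: float = 0.05):
    """Per-transmission detection probability at a given distance.

    A two-parameter logistic fixed by the midpoint range (p = 0.5 at
    ``d50_m``) and the maximum range (p = ``p_at_dmax`` at ``d_max_m``);
    beyond the maximum range the probability is 0 (the maximum range is read
    as the distance at which detections cease).  Monotone non-increasing.
    """
    if not d50_m < d_max_m:
        raise ValidationError("d50_m must be < d_max_m")
    if not 0.0 < p_at_dmax < 0.5:
        raise ValidationError("p_at_dmax must be in (0, 0.5)")
    d = np.asarray(distance_m, dtype=float)
    if (d < 0).any():
        raise ValidationError("distance must be >= 0")
    k = np.log((1.0 - p_at_dmax) / p_at_dmax) / (d_max_m - d50_m)
    p = 1.0 / (1.0 + np.exp(k * (d - d50_m)))
    p = np.where(d > d_max_m, 0.0, p)
    return p if p.ndim else float(p)


# ----------------------------------------------------------------------
# receiver array
# ----------------------------------------------------------------------
def simulate_array(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate station deployments for the three regions.

    The focal (wadden_sea) block is a jittered grid over ~55 x 25 km with a
    few sub-kilometre "harbour pairs" whose ranges overlap; offshore
    (north_sea) stations sit in three distant blocks; fresh_water is exactly
    one station.  A configured fraction of focal stations is marked damaged
    or given a short (< 90 d) deployment to exercise station exclusion.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    start = pd.Timestamp(config.start_year, 1, 1, tz="UTC")
    end = pd.Timestamp(config.start_year + config.n_years, 1, 1, tz="UTC")

    n_w = config.n_wadden_stations
    nx = int(np.ceil(np.sqrt(n_w * 55 / 25)))
    ny = int(np.ceil(n_w / nx))
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny))
    cells = np.column_stack([gx.ravel(), gy.ravel()])[:n_w]
    x = (cells[:, 0] + 0.5) * (55000 / nx) + rng.uniform(-900, 900, n_w)
    y = (cells[:, 1] + 0.5) * (25000 / ny) + rng.uniform(-900, 900, n_w)
    # harbour pairs: overlapping ranges so one transmission can be heard twice
    for a, b in ((0, 1), (2, 3), (4, 5)):
        if b < n_w:
            theta = rng.uniform(0, 2 * np.pi)
            x[b] = x[a] + 450 * np.cos(theta)
            y[b] = y[a] + 450 * np.sin(theta)

    rows = []
    for i in range(n_w):
        rows.append({"station_id": f"WS{i:03d}",
                     "array_name": "focal_grid" if i >= 5 else "sluice_line",
                     "region": "wadden_sea", "x_m": x[i], "y_m": y[i],
                     "active_start": start, "active_end": end,
                     "damaged": False})

    n_ns = config.n_north_sea_stations
    block_centres = [(-10000.0, -150000.0), (30000.0, -250000.0),
                     (0.0, -90000.0)]
    for i in range(n_ns):
        cx, cy = block_centres[i % len(block_centres)]
        rows.append({"station_id": f"NS{i:03d}",
                     "array_name": f"offshore_block_{i % len(block_centres)}",
                     "region": "north_sea",
                     "x_m": cx + rng.uniform(-3000, 3000),
                     "y_m": cy + rng.uniform(-3000, 3000),
                     "active_start": start, "active_end": end,
                     "damaged": False})

    rows.append({"station_id": "FW000", "array_name": "lake_harbour",
                 "region": "fresh_water", "x_m": 27000.0, "y_m": -9000.0,
                 "active_start": start, "active_end": end, "damaged": False})

    df = pd.DataFrame(rows)

    wadden_idx = df.index[df["region"] == "wadden_sea"].to_numpy()
    n_damaged = int(round(config.damaged_fraction * n_w))
    n_short = int(round(config.short_deployment_fraction * n_w))
    special = rng.choice(wadden_idx, size=min(n_damaged + n_short, n_w),
                         replace=False)
    for i in special[:n_damaged]:
        df.loc[i, "damaged"] = True
    for i in special[n_damaged:]:
        s0 = start + pd.Timedelta(days=int(rng.integers(0, 200)))
        df.loc[i, "active_start"] = s0
        df.loc[i, "active_end"] = s0 + pd.Timedelta(days=60)
    return df


# ----------------------------------------------------------------------
# fish trajectories
# ----------------------------------------------------------------------
@dataclass
class TruthTable:
    """Ground truth accompanying a synthetic dataset."""

    labels: pd.DataFrame = field(default_factory=pd.DataFrame)       # det_id, label
    fish_years: pd.DataFrame = field(default_factory=pd.DataFrame)   # true windows
    deaths: pd.DataFrame = field(default_factory=pd.DataFrame)       # fish_id, death_time
    visits: pd.DataFrame = field(default_factory=pd.DataFrame)       # in-range log


def _draw_window(rng, sp) -> tuple[int, int]:
    for _ in range(200):
        arr = int(round(rng.normal(sp.arrival_doy_median, sp.arrival_doy_spread)))
        dep = int(round(rng.normal(sp.departure_doy_median,
                                   sp.departure_doy_spread)))
        if 1 <= arr < dep <= 364:
            return arr, dep
    arr = int(np.clip(sp.arrival_doy_median, 1, 363))
    return arr, min(arr + 1 + int(abs(sp.departure_doy_median - arr)), 364)


def simulate_fish(config: SimulationConfig, stations: pd.DataFrame,
                  rng: np.random.Generator | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate tag deployments and daily centre-of-activity trajectories.

    Returns (deployments, trajectories, truth skeleton).  Trajectory rows
    exist only for days on which the fish could be detected somewhere:
    residence-season days, freshwater forays, offshore passes, and
    post-death emissions from a fixed position.
    """
    config.validate()
    if stations.empty:
        raise ValidationError("station array must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    wadden = stations[stations["region"] == "wadden_sea"]
    north = stations[stations["region"] == "north_sea"]
    fresh = stations[stations["region"] == "fresh_water"]
    wxy = wadden[["x_m", "y_m"]].to_numpy(dtype=float)
    tree = cKDTree(wxy)
    xmin, ymin = wxy.min(axis=0) - 2000
    xmax, ymax = wxy.max(axis=0) + 2000

    year0 = config.start_year
    last_year = config.start_year + config.n_years - 1
    study_start_day = pd.Timestamp(year0, 1, 1).toordinal() - 719163
    study_end_day = (pd.Timestamp(last_year, 12, 31).toordinal() - 719163)

    fish_rows, traj_f, traj_d, traj_x, traj_y, traj_anchor = [], [], [], [], [], []
    fy_rows, death_rows = [], []

    prefix = {"thicklip": "TKM", "thinlip": "TNM", "other": "OTH"}
    fish_specs = []
    for species in sorted(config.n_fish_per_species):
        for i in range(config.n_fish_per_species[species]):
            fish_specs.append((species, i))
    n_fish = len(fish_specs)
    n_dead = int(round(config.mortality_fraction * n_fish))
    dead_idx = set(rng.choice(n_fish, size=n_dead, replace=False).tolist()
                   if n_dead else [])

    for f_idx, (species, i) in enumerate(fish_specs):
        sp = config.species_params[species]
        fish_id = f"{prefix.get(species, 'F')}{i:03d}"
        tag_id = f"TAG{f_idx:04d}"
        cohort = (year0 if (config.n_years == 1
                            or rng.random() < config.first_year_cohort_fraction)
                  else year0 + 1)

        present_years = [cohort]
        yy = cohort
        while yy + 1 <= last_year and rng.random() < sp.annual_return_prob:
            present_years.append(yy + 1)
            yy += 1

        is_dead = f_idx in dead_idx
        death_day = None  # epoch day

        windows = {}
        for year in present_years:
            arr_doy, dep_doy = _draw_window(rng, sp)
            y_start = pd.Timestamp(year, 1, 1).toordinal() - 719163
            windows[year] = (y_start + arr_doy - 1, y_start + dep_doy - 1)
        if is_dead:
            a0, d0 = windows[cohort]
            death_day = int(rng.integers(a0, d0 + 1))
            present_years = [cohort]
            windows = {cohort: windows[cohort]}

        arr0, dep0 = windows[cohort]
        # the tag exists only from release: the walk (and hence any true
        # detection) starts at the release day in the tagging year
        release_day = min(arr0 + int(rng.uniform(3, 30)), dep0)
        if is_dead:
            release_day = min(release_day, death_day)
        release_time = pd.Timestamp(release_day * _DAY_S, unit="s", tz="UTC")
        length = float(np.clip(rng.normal(sp.median_length_cm, 5.0), 40.0, 70.0))

        tag_end_day = release_day + config.tag_lifespan_days
        anchor = int(rng.integers(0, len(wadden)))
        rel_xy = wxy[anchor]

        fish_rows.append({
            "fish_id": fish_id, "tag_id": tag_id, "species": species,
            "release_time": release_time,
            "release_x_m": float(rel_xy[0]), "release_y_m": float(rel_xy[1]),
            "min_delay_s": config.min_delay_s,
            "max_delay_s": config.max_delay_s, "length_cm": round(length, 1),
        })

        # --- residence-season walk, year by year -----------------------
        frozen_xy = None
        for year in present_years:
            a_day, d_day = windows[year]
            true_dep_day = d_day
            pos = wxy[anchor].copy()
            day = max(a_day, release_day) if year == cohort else a_day
            while day <= d_day:
                if is_dead and day > death_day:
                    break
                if (sp.freshwater_day_prob > 0 and len(fresh)
                        and rng.random() < sp.freshwater_day_prob):
                    fx = fresh.iloc[0]
                    pos = np.array([fx["x_m"], fx["y_m"]])
                    st = None
                elif rng.random() < sp.station_fidelity:
                    r = rng.uniform(0, config.anchor_radius_m)
                    th = rng.uniform(0, 2 * np.pi)
                    pos = wxy[anchor] + np.array([r * np.cos(th),
                                                  r * np.sin(th)])
                    st = anchor
                else:
                    step = rng.normal(0, sp.mobility_step_m, size=2)
                    pos = np.clip(pos + step, [xmin, ymin], [xmax, ymax])
                    dist, near = tree.query(pos)
                    if dist <= config.d_max_m:
                        anchor = int(near)
                        st = anchor
                    else:
                        st = None
                traj_f.append(f_idx); traj_d.append(day)
                traj_x.append(pos[0]); traj_y.append(pos[1])
                traj_anchor.append(st if st is not None else -1)
                day += 1
            if is_dead and death_day <= d_day:
                true_dep_day = min(death_day, d_day)
                frozen_xy = pos.copy()
                stop = min(death_day + config.post_death_emission_days,
                           tag_end_day, study_end_day)
                for dd in range(death_day + 1, stop + 1):
                    traj_f.append(f_idx); traj_d.append(dd)
                    traj_x.append(frozen_xy[0]); traj_y.append(frozen_xy[1])
                    traj_anchor.append(-1)
                death_rows.append({
                    "fish_id": fish_id,
                    "death_time": pd.Timestamp(death_day * _DAY_S, unit="s",
                                               tz="UTC")})
            fy_rows.append({
                "fish_id": fish_id, "species": species, "year": year,
                "true_arrival": pd.Timestamp(a_day * _DAY_S, unit="s", tz="UTC"),
                "true_departure": pd.Timestamp(true_dep_day * _DAY_S, unit="s",
                                               tz="UTC"),
                "is_return_year": year > cohort,
            })

        # --- off-season offshore passes --------------------------------
        if len(north) and sp.offshore_detection_prob > 0 and not is_dead:
            in_res = np.zeros(study_end_day - study_start_day + 1, dtype=bool)
            for a_day, d_day in windows.values():
                in_res[a_day - study_start_day:d_day - study_start_day + 1] = True
            days = np.arange(study_start_day, study_end_day + 1)
            ok = ((days >= release_day) & (days <= tag_end_day)
                  & ~in_res[days - study_start_day])
            passes = days[ok][rng.random(ok.sum()) < sp.offshore_detection_prob]
            for dd in passes:
                ns = north.iloc[int(rng.integers(0, len(north)))]
                traj_f.append(f_idx); traj_d.append(int(dd))
                traj_x.append(ns["x_m"] + rng.uniform(-50, 50))
                traj_y.append(ns["y_m"] + rng.uniform(-50, 50))
                traj_anchor.append(-1)

    deployments = pd.DataFrame(fish_rows).sort_values(
        "fish_id", kind="mergesort").reset_index(drop=True)
    trajectories = pd.DataFrame({
        "fish_idx": np.asarray(traj_f, dtype=np.int64),
        "epoch_day": np.asarray(traj_d, dtype=np.int64),
        "x_m": np.asarray(traj_x, dtype=float),
        "y_m": np.asarray(traj_y, dtype=float),
    })
    fish_index = pd.DataFrame(fish_rows)[["fish_id", "tag_id"]]
    trajectories["fish_id"] = fish_index["fish_id"].to_numpy()[
        trajectories["fish_idx"].to_numpy()]
    truth = TruthTable(
        fish_years=pd.DataFrame(fy_rows),
        deaths=pd.DataFrame(death_rows, columns=["fish_id", "death_time"]),
    )
    return deployments, trajectories, truth


# ----------------------------------------------------------------------
# detections
# ----------------------------------------------------------------------
def simulate_detections(config: SimulationConfig, stations: pd.DataFrame,
                        trajectories: pd.DataFrame,
                        deployments: pd.DataFrame,
                        rng: np.random.Generator | None = None,
                        truth: TruthTable | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Schedule transmissions and roll per-station detection trials.

    Returns (detections, labels): detections carry an integer ``det_id``
    besides the three record columns; labels map det_id -> "true".  The
    in-range station-visit log is written into ``truth.visits`` when a truth
    table is passed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)

    sxy = stations[["x_m", "y_m"]].to_numpy(dtype=float)
    s_start = (stations["active_start"].astype("int64").to_numpy() // 10**9
               // _DAY_S)
    s_end = (stations["active_end"].astype("int64").to_numpy() // 10**9
             // _DAY_S)
    tree = cKDTree(sxy)
    tag_by_fish = deployments.set_index("fish_id")["tag_id"]

    if trajectories.empty:
        empty = pd.DataFrame(columns=["tag_id", "station_id", "timestamp",
                                      "det_id"])
        return empty, pd.DataFrame(columns=["det_id", "label"])

    pos = trajectories[["x_m", "y_m"]].to_numpy(dtype=float)
    days = trajectories["epoch_day"].to_numpy()
    neighbours = tree.query_ball_point(pos, r=config.d_max_m)

    # flatten (trajectory row, station) pairs for active in-range stations
    row_ids, st_ids = [], []
    for i, hits in enumerate(neighbours):
        d = days[i]
        for s in hits:
            if s_start[s] <= d < s_end[s]:
                row_ids.append(i)
                st_ids.append(s)
    row_ids = np.asarray(row_ids, dtype=np.int64)
    st_ids = np.asarray(st_ids, dtype=np.int64)

    if truth is not None:
        vis = trajectories.iloc[row_ids][["fish_id", "epoch_day"]].copy()
        vis["station_id"] = stations["station_id"].to_numpy()[st_ids]
        vis["date"] = pd.to_datetime(vis.pop("epoch_day") * _DAY_S, unit="s",
                                     utc=True)
        truth.visits = vis.reset_index(drop=True)

    if len(row_ids) == 0:
        empty = pd.DataFrame(columns=["tag_id", "station_id", "timestamp",
                                      "det_id"])
        return empty, pd.DataFrame(columns=["det_id", "label"])

    dists = np.hypot(pos[row_ids, 0] - sxy[st_ids, 0],
                     pos[row_ids, 1] - sxy[st_ids, 1])
    p_det = detection_probability(dists, config.d50_m, config.d_max_m,
                                  config.p_at_dmax)

    active_rows = np.unique(row_ids)
    w_s = config.in_range_hours_per_day * 3600.0
    window_start = rng.uniform(0, _DAY_S - w_s, size=len(active_rows))
    ws_of_row = np.full(len(trajectories), np.nan)
    ws_of_row[active_rows] = window_start

    n_slots = int(np.ceil(_DAY_S / config.min_delay_s)) + 1
    order = np.argsort(row_ids, kind="stable")
    row_sorted, st_sorted, p_sorted = row_ids[order], st_ids[order], p_det[order]

    out_tag, out_station, out_t = [], [], []
    chunk = 2000
    starts = np.searchsorted(row_sorted, active_rows)
    ends = np.append(starts[1:], len(row_sorted))
    fish_of_row = trajectories["fish_id"].to_numpy()

    for c0 in range(0, len(active_rows), chunk):
        rows_c = active_rows[c0:c0 + chunk]
        m = len(rows_c)
        gaps = rng.uniform(config.min_delay_s, config.max_delay_s,
                           size=(m, n_slots))
        times = np.cumsum(gaps, axis=1)
        ws = ws_of_row[rows_c][:, None]
        in_win = (times >= ws) & (times < ws + w_s) & (times < _DAY_S)
        for j, r in enumerate(rows_c):
            tvalid = times[j][in_win[j]]
            if tvalid.size == 0:
                continue
            base = days[r] * _DAY_S
            for k in range(starts[c0 + j], ends[c0 + j]):
                heard = rng.random(tvalid.size) < p_sorted[k]
                if heard.any():
                    tt = (base + np.floor(tvalid[heard])).astype(np.int64)
                    out_tag.append(np.full(tt.size, r))
                    out_station.append(np.full(tt.size, st_sorted[k]))
                    out_t.append(tt)

    if not out_t:
        empty = pd.DataFrame(columns=["tag_id", "station_id", "timestamp",
                                      "det_id"])
        return empty, pd.DataFrame(columns=["det_id", "label"])

    rrow = np.concatenate(out_tag)
    sid = np.concatenate(out_station)
    tsec = np.concatenate(out_t)
    det = pd.DataFrame({
        "tag_id": pd.Series(fish_of_row[rrow]).map(tag_by_fish).to_numpy(),
        "station_id": stations["station_id"].to_numpy()[sid],
        "timestamp": pd.to_datetime(tsec, unit="s", utc=True),
    })
    det = det.sort_values(["tag_id", "timestamp", "station_id"],
                          kind="mergesort").reset_index(drop=True)
    det["det_id"] = np.arange(len(det), dtype=np.int64)
    labels = pd.DataFrame({"det_id": det["det_id"], "label": "true"})
    return det, labels


# ----------------------------------------------------------------------
# noise injection
# ----------------------------------------------------------------------
def inject_noise(detections: pd.DataFrame, labels: pd.DataFrame,
                 deployments: pd.DataFrame, stations: pd.DataFrame,
                 config: SimulationConfig,
                 rng: np.random.Generator | None = None,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add labelled false records: exact echoes, sub-delay ghosts, and
    isolated false positives (no companion within 24 h at their station).

    Raises when the requested noise cannot be placed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    n_fp = config.n_false_positives
    n_echo = config.n_echo_duplicates
    n_ghost = config.n_subdelay_ghosts
    if n_fp == n_echo == n_ghost == 0:
        return detections, labels

    det = detections.copy()
    lab = labels.copy()
    true_ids = lab.loc[lab["label"] == "true", "det_id"].to_numpy()
    if (n_echo and len(true_ids) < n_echo) or (n_ghost and len(true_ids) < n_ghost):
        raise ValidationError("requested noise exceeds feasible placements: "
                              "not enough true detections to copy/shadow")
    det_by_id = det.set_index("det_id")
    next_id = int(det["det_id"].max()) + 1 if len(det) else 0
    min_delay = deployments.set_index("tag_id")["min_delay_s"]

    existing = {}
    tsec_all = det["timestamp"].astype("int64").to_numpy() // 10**9
    for (tag, st), idx in det.groupby(["tag_id", "station_id"]).groups.items():
        existing[(tag, st)] = set(tsec_all[det.index.get_indexer(idx)])

    new_rows = []

    if n_echo:
        picks = rng.choice(true_ids, size=n_echo, replace=False)
        for d_id in picks:
            r = det_by_id.loc[d_id]
            new_rows.append({"tag_id": r["tag_id"],
                             "station_id": r["station_id"],
                             "timestamp": r["timestamp"],
                             "det_id": next_id, "label": "duplicate"})
            next_id += 1

    if n_ghost:
        picks = rng.choice(true_ids, size=n_ghost, replace=False)
        for d_id in picks:
            r = det_by_id.loc[d_id]
            base = int(r["timestamp"].value // 10**9)
            md = int(min_delay[r["tag_id"]])
            if md < 2:
                raise ValidationError("min_delay too small to place ghosts")
            placed = False
            for _ in range(50):
                t = base + int(rng.integers(1, md))
                key = (r["tag_id"], r["station_id"])
                if t not in existing.setdefault(key, set()):
                    existing[key].add(t)
                    new_rows.append({
                        "tag_id": r["tag_id"], "station_id": r["station_id"],
                        "timestamp": pd.Timestamp(t, unit="s", tz="UTC"),
                        "det_id": next_id, "label": "subdelay_ghost"})
                    next_id += 1
                    placed = True
                    break
            if not placed:
                raise ValidationError(
                    "requested noise exceeds feasible placements (ghosts)")

    if n_fp:
        tags = deployments["tag_id"].to_numpy()
        st_all = stations["station_id"].to_numpy()
        lo = int(stations["active_start"].min().value // 10**9)
        hi = int(stations["active_end"].max().value // 10**9)
        margin = 25 * 3600  # strictly outside the 24 h companion window
        placed_total = 0
        attempts = 0
        while placed_total < n_fp:
            attempts += 1
            if attempts > 2000 * n_fp:
                raise ValidationError(
                    "requested noise exceeds feasible placements "
                    "(false positives)")
            tag = tags[int(rng.integers(0, len(tags)))]
            st = st_all[int(rng.integers(0, len(st_all)))]
            t = int(rng.integers(lo, hi))
            key = (tag, st)
            times = existing.get(key)
            if times:
                arr = np.fromiter(times, dtype=np.int64)
                if np.abs(arr - t).min() <= margin:
                    continue
            existing.setdefault(key, set()).add(t)
            new_rows.append({"tag_id": tag, "station_id": st,
                             "timestamp": pd.Timestamp(t, unit="s", tz="UTC"),
                             "det_id": next_id, "label": "false_positive"})
            next_id += 1
            placed_total += 1

    add = pd.DataFrame(new_rows)
    det = pd.concat([det, add[["tag_id", "station_id", "timestamp", "det_id"]]],
                    ignore_index=True)
    lab = pd.concat([lab, add[["det_id", "label"]]], ignore_index=True)
    det = det.sort_values(["tag_id", "timestamp", "station_id"],
                          kind="mergesort").reset_index(drop=True)
    lab = lab.sort_values("det_id", kind="mergesort").reset_index(drop=True)
    return det, lab


# ----------------------------------------------------------------------
# one-call dataset
# ----------------------------------------------------------------------
@dataclass
class SimulatedDataset:
    config: SimulationConfig
    stations: pd.DataFrame
    deployments: pd.DataFrame
    detections: pd.DataFrame        # includes det_id
    truth: TruthTable
    mortality: pd.DataFrame         # input table for the mortality filter


def simulate_dataset(config: SimulationConfig, *,
                     with_noise: bool = True) -> SimulatedDataset:
    """Run the full generator: array, fish, detections, noise, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    stations = simulate_array(config, rng)
    deployments, trajectories, truth = simulate_fish(config, stations, rng)
    detections, labels = simulate_detections(config, stations, trajectories,
                                             deployments, rng, truth=truth)
    if with_noise:
        detections, labels = inject_noise(detections, labels, deployments,
                                          stations, config, rng)
    truth.labels = labels
    mortality = truth.deaths.copy()
    return SimulatedDataset(config=config, stations=stations,
                            deployments=deployments, detections=detections,
                            truth=truth, mortality=mortality)
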