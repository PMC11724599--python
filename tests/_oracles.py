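"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an operation's expected output from first principles
(per-row scans, O(n^2) pairwise checks, monotone-chain hull + shoelace,
ray-casting Monte Carlo) without touching the implementation under test.
"""

import numpy as np
from matplotlib.path import Path


def _secs(df):
    return (df["timestamp"].astype("int64") // 10**9).to_numpy()


def brute_predeployment(det, deployments):
    """Row-by-row comparison against the tag's release time."""
    release = {r["tag_id"]: r["release_time"].value // 10**9
               for _, r in deployments.iterrows()}
    t = _secs(det)
    keep = [t[i] >= release[det["tag_id"].iloc[i]] for i in range(len(det))]
    return det[np.array(keep, dtype=bool)]


def brute_duplicates(det):
    """Keep the first of each identical (tag, station, timestamp) triple."""
    seen = set()
    keep = []
    t = _secs(det)
    for i in range(len(det)):
        key = (det["tag_id"].iloc[i], det["station_id"].iloc[i], t[i])
        keep.append(key not in seen)
        seen.add(key)
    return det[np.array(keep, dtype=bool)]


def brute_min_delay(det, deployments):
    """Chronological per-(tag, station) retention scan in pure python."""
    min_delay = {r["tag_id"]: int(r["min_delay_s"])
                 for _, r in deployments.iterrows()}
    t = _secs(det)
    order = sorted(range(len(det)),
                   key=lambda i: (det["tag_id"].iloc[i],
                                  det["station_id"].iloc[i], t[i]))
    keep = np.zeros(len(det), dtype=bool)
    last = {}
    for i in order:
        key = (det["tag_id"].iloc[i], det["station_id"].iloc[i])
        md = min_delay[det["tag_id"].iloc[i]]
        if key not in last:
            keep[i] = True
            last[key] = t[i]
        else:
            gap = t[i] - last[key]
            if 0 < gap < md:
                keep[i] = False
            else:
                keep[i] = True
                last[key] = t[i]
    return det[keep]


def brute_singletons_24h(det):
    """O(n^2) pairwise companion search within +/- 24 h, same tag+station."""
    t = _secs(det)
    tags = det["tag_id"].to_numpy()
    sts = det["station_id"].to_numpy()
    keep = np.zeros(len(det), dtype=bool)
    for i in range(len(det)):
        same = (tags == tags[i]) & (sts == sts[i])
        same[i] = False
        keep[i] = bool((np.abs(t[same] - t[i]) <= 86400).any())
    return det[keep]


def singleton_ids_adjacent_gaps(det):
    """Singleton det_ids via sorted adjacent gaps (a record's nearest
    same-(tag, station) neighbour in time is adjacent in sorted order).
    Scales to large datasets, unlike the O(n^2) pairwise oracle."""
    singles = set()
    t_all = _secs(det)
    for _, idx in det.groupby(["tag_id", "station_id"]).indices.items():
        t = np.sort(t_all[idx])
        order = np.argsort(t_all[idx], kind="stable")
        ids = det["det_id"].to_numpy()[idx][order]
        prev = np.diff(t, prepend=t[0] - 10**9)
        nxt = np.diff(t, append=t[-1] + 10**9)
        singles.update(ids[(prev > 86400) & (nxt > 86400)])
    return singles


# ----------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------
def convex_hull_area(points):
    """Monotone-chain hull + shoelace area (m^2), implemented from scratch."""
    pts = sorted(set(map(tuple, np.asarray(points, dtype=float))))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:
        return 0.0
    area = 0.0
    for i in range(len(hull)):
        x0, y0 = hull[i]
        x1, y1 = hull[(i + 1) % len(hull)]
        area += x0 * y1 - x1 * y0
    return abs(area) / 2.0


def monte_carlo_clipped_area_km2(hull_vertices, mask_polygons, n_samples, rng):
    """Ray-casting Monte-Carlo estimate of (hull minus land) area in km^2.

    Samples uniformly over the hull's bounding box and counts points inside
    the hull but in no mask polygon (matplotlib.path ray casting, not
    shapely).
    """
    verts = np.asarray(hull_vertices, dtype=float)
    hull_path = Path(verts)
    mask_paths = [Path(np.asarray(p.exterior.coords)) for p in mask_polygons]
    xmin, ymin = verts.min(axis=0)
    xmax, ymax = verts.max(axis=0)
    pts = np.column_stack([rng.uniform(xmin, xmax, n_samples),
                           rng.uniform(ymin, ymax, n_samples)])
    inside = hull_path.contains_points(pts)
    for mp in mask_paths:
        inside &= ~mp.contains_points(pts)
    box_km2 = (xmax - xmin) * (ymax - ymin) / 1e6
    return inside.mean() * box_km2
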