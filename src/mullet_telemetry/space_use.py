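"""Minimum convex polygon space-use estimation.

Per fish-year, the MCP is the convex hull of the receiver stations at which
the fish was detected (>= 3 stations and residence duration > 5 days are
required), with its planar area optionally reduced by the overlap with a
land mask.  Areas are reported in km² from projected metre coordinates.
MCPs over receiver positions are a coarse, array-design-dependent proxy for
the extent of movements — they assume full use of the hull interior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from .errors import ValidationError

M2_PER_KM2 = 1e6


@dataclass
class MCPResult:
    fish_id: str
    year: int
    station_set: frozenset
    hull_vertices: np.ndarray          # (k, 2) CCW exterior ring, no repeat
    raw_area_km2: float
    clipped_area_km2: float
    degenerate: bool


def eligible_fish_years(residence: pd.DataFrame, *,
                        min_stations: int = 3) -> set[tuple[str, int]]:
    """Fish-years with residence duration above threshold (the ``included``
    flag) detected at >= ``min_stations`` stations."""
    ok = residence["included"] & (residence["n_stations"] >= min_stations)
    return set(map(tuple, residence.loc[ok, ["fish_id", "year"]].values))


def mcp(points) -> tuple[np.ndarray, float, bool]:
    """Convex hull of station coordinates (metres).

    Returns (vertices, area_km2, degenerate).  Collinear point sets yield
    area 0 with the degenerate flag set.  Fewer than 3 points is an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array of metres")
    if len(pts) < 3:
        raise ValidationError(f"MCP needs >= 3 points, got {len(pts)}")
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon":
        # all points coincident or collinear
        verts = np.unique(pts, axis=0)
        return verts, 0.0, True
    ring = np.asarray(hull.exterior.coords)[:-1]
    return ring, hull.area / M2_PER_KM2, False


def clip_to_water(hull_vertices, landmask: Optional[Iterable[Polygon]],
                  ) -> tuple[object, float]:
    """Subtract the land polygons from the hull; returns (geometry, km²).

    An empty or missing mask leaves the hull untouched; the result may be
    several disjoint pieces.  Self-intersecting mask polygons are an error.
    """
    verts = np.asarray(hull_vertices, dtype=float)
    if len(verts) < 3:
        return Polygon(), 0.0
    hull = Polygon(verts)
    if landmask is None:
        return hull, hull.area / M2_PER_KM2
    polys = list(landmask)
    if not polys:
        return hull, hull.area / M2_PER_KM2
    for p in polys:
        if not p.is_valid:
            raise ValidationError("land-mask polygon is invalid "
                                  "(self-intersecting?)")
    clipped = hull.difference(unary_union(polys))
    return clipped, clipped.area / M2_PER_KM2


def mcp_table(detections: pd.DataFrame, deployments: pd.DataFrame,
              stations: pd.DataFrame, residence: pd.DataFrame, *,
              region: str = "wadden_sea", min_stations: int = 3,
              landmask: Optional[Iterable[Polygon]] = None) -> pd.DataFrame:
    """Raw and land-clipped MCP area per eligible fish-year.

    Degenerate (collinear) hulls are reported with area 0 and flagged; they
    are excluded from species comparisons downstream.
    """
    from .residency import _regional

    coords = stations.drop_duplicates("station_id").set_index("station_id")
    df = _regional(detections, deployments, stations, region)
    eligible = eligible_fish_years(residence, min_stations=min_stations)
    rows = []
    for (fish, year), g in df.groupby(["fish_id", "year"], sort=True):
        if (fish, year) not in eligible:
            continue
        used = sorted(g["station_id"].unique())
        pts = coords.loc[used, ["x_m", "y_m"]].to_numpy(dtype=float)
        verts, raw_km2, degenerate = mcp(pts)
        if degenerate:
            clipped_km2 = 0.0
        else:
            _, clipped_km2 = clip_to_water(verts, landmask)
        rows.append({"fish_id": fish, "species": g["species"].iloc[0],
                     "year": year, "n_stations": len(used),
                     "raw_area_km2": raw_km2,
                     "clipped_area_km2": clipped_km2,
                     "degenerate": degenerate})
    return pd.DataFrame(rows, columns=["fish_id", "species", "year",
                                       "n_stations", "raw_area_km2",
                                       "clipped_area_km2", "degenerate"])
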