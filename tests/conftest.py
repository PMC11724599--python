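import numpy as np
import pandas as pd
import pytest

import mullet_telemetry as mt


def make_detections(rows):
    """Build a detection table from (tag, station, iso_time) tuples."""
    df = pd.DataFrame(rows, columns=["tag_id", "station_id", "timestamp"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df.sort_values(["tag_id", "timestamp", "station_id"],
                          kind="mergesort").reset_index(drop=True)


def make_deployments(rows):
    """Build a deployment table from (fish, tag, species, release_iso) tuples,
    with default delays 60-120 s and length 50 cm."""
    recs = []
    for fish, tag, species, release in rows:
        recs.append({"fish_id": fish, "tag_id": tag, "species": species,
                     "release_time": pd.Timestamp(release, tz="UTC"),
                     "release_x_m": 0.0, "release_y_m": 0.0,
                     "min_delay_s": 60, "max_delay_s": 120,
                     "length_cm": 50.0})
    return pd.DataFrame(recs)


def make_stations(rows):
    """Build a station table from (station, region, x, y) tuples with a
    full two-year deployment window."""
    recs = []
    for st, region, x, y in rows:
        recs.append({"station_id": st, "array_name": "test", "region": region,
                     "x_m": float(x), "y_m": float(y),
                     "active_start": pd.Timestamp("2021-01-01", tz="UTC"),
                     "active_end": pd.Timestamp("2023-01-01", tz="UTC"),
                     "damaged": False})
    return pd.DataFrame(recs)


def small_config(seed=7, **kw):
    defaults = dict(
        seed=seed,
        n_fish_per_species={"thicklip": 6, "thinlip": 4},
        n_years=2,
        n_false_positives=10, n_echo_duplicates=10, n_subdelay_ghosts=10,
    )
    defaults.update(kw)
    return mt.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """One small noisy synthetic dataset shared across read-only tests."""
    return mt.simulate_dataset(small_config())


@pytest.fixture(scope="session")
def small_filtered(small_dataset):
    ds = small_dataset
    filtered, report = mt.apply_all(ds.detections, ds.deployments,
                                    ds.stations, ds.mortality)
    return filtered, report


def random_detection_table(rng, n, n_tags=8, n_stations=5, span_days=30):
    """Random detection table with heavy key collisions, for filter oracles."""
    tags = [f"T{i}" for i in range(n_tags)]
    stations = [f"S{i}" for i in range(n_stations)]
    base = pd.Timestamp("2022-06-01", tz="UTC").value // 10**9
    t = base + rng.integers(0, span_days * 86400, size=n)
    df = pd.DataFrame({
        "tag_id": rng.choice(tags, size=n),
        "station_id": rng.choice(stations, size=n),
        "timestamp": pd.to_datetime(t, unit="s", utc=True),
    })
    return df.sort_values(["tag_id", "timestamp", "station_id"],
                          kind="mergesort").reset_index(drop=True)
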