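"""Unit and property tests of the false-detection filter cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mullet_telemetry as mt
from mullet_telemetry.filters import (apply_all, exclude_stations,
                                      filter_duplicates, filter_min_delay,
                                      filter_predeployment,
                                      filter_singletons_24h, remove_mortality)

import _oracles as oracle
from conftest import (make_detections, make_deployments, make_stations,
                      random_detection_table, small_config)

DEP = make_deployments([("F1", "A", "thicklip", "2022-06-01T00:00:00"),
                        ("F2", "B", "thinlip", "2022-06-01T00:00:00")])


class TestPredeployment:
    def test_before_release_removed_at_release_retained(self):
        det = make_detections([
            ("A", "S1", "2022-05-31T23:00:00"),   # 1 h before release
            ("A", "S1", "2022-06-01T00:00:00"),   # exactly at release
            ("A", "S1", "2022-06-02T00:00:00"),
        ])
        out, n = filter_predeployment(det, DEP)
        assert n == 1 and len(out) == 2
        assert out["timestamp"].min() == pd.Timestamp("2022-06-01", tz="UTC")

    def test_unknown_tag_is_error(self):
        det = make_detections([("Z", "S1", "2022-06-02T00:00:00")])
        with pytest.raises(mt.ValidationError, match="Z"):
            filter_predeployment(det, DEP)


class TestDuplicates:
    def test_identical_rows_collapse_to_one(self):
        det = make_detections([("A", "S1", "2022-06-02T00:00:00")] * 2)
        out, n, simul = filter_duplicates(det)
        assert len(out) == 1 and n == 1 and simul == 0

    def test_cross_station_simultaneity_kept_and_counted(self):
        det = make_detections([("A", "S1", "2022-06-02T00:00:00"),
                               ("A", "S2", "2022-06-02T00:00:00")])
        out, n, simul = filter_duplicates(det)
        assert len(out) == 2 and n == 0 and simul == 1


class TestMinDelay:
    def test_hand_worked_gap_sequence(self):
        # gaps 0 s (exact duplicate, removed upstream), 30 s, 70 s; delay 60
        det = make_detections([
            ("A", "S1", "2022-06-02T00:00:00"),
            ("A", "S1", "2022-06-02T00:00:30"),
            ("A", "S1", "2022-06-02T00:01:40"),
        ])
        out, n = filter_min_delay(det, DEP)
        assert n == 1
        assert list(out["timestamp"].dt.second) == [0, 40]

    def test_all_gaps_legal_no_removals(self):
        det = make_detections([
            ("A", "S1", f"2022-06-02T00:{m:02d}:00") for m in range(0, 10, 2)])
        out, n = filter_min_delay(det, DEP)
        assert n == 0 and len(out) == len(det)

    def test_ghost_run_does_not_shield_itself(self):
        # three records 30 s apart: the 2nd and 3rd both violate against the
        # first *retained* record
        det = make_detections([
            ("A", "S1", "2022-06-02T00:00:00"),
            ("A", "S1", "2022-06-02T00:00:30"),
            ("A", "S1", "2022-06-02T00:01:00"),
        ])
        out, n = filter_min_delay(det, DEP)
        assert n == 1  # 30 s removed; 60 s gap to the first is legal
        det2 = make_detections([
            ("A", "S1", "2022-06-02T00:00:00"),
            ("A", "S1", "2022-06-02T00:00:30"),
            ("A", "S1", "2022-06-02T00:00:59"),
        ])
        out2, n2 = filter_min_delay(det2, DEP)
        assert n2 == 2 and len(out2) == 1


class TestSingletons:
    def test_lone_detection_removed(self):
        det = make_detections([("A", "S1", "2022-06-02T00:00:00")])
        out, n = filter_singletons_24h(det)
        assert len(out) == 0 and n == 1

    def test_companions_23h_apart_both_retained(self):
        det = make_detections([("A", "S1", "2022-06-02T00:00:00"),
                               ("A", "S1", "2022-06-02T23:00:00")])
        out, n = filter_singletons_24h(det)
        assert len(out) == 2 and n == 0

    def test_25h_apart_both_removed_simultaneously(self):
        det = make_detections([("A", "S1", "2022-06-02T00:00:00"),
                               ("A", "S1", "2022-06-03T01:00:00")])
        out, n = filter_singletons_24h(det)
        assert len(out) == 0 and n == 2

    def test_other_station_does_not_rescue(self):
        det = make_detections([("A", "S1", "2022-06-02T00:00:00"),
                               ("A", "S2", "2022-06-02T01:00:00")])
        out, n = filter_singletons_24h(det)
        assert len(out) == 0 and n == 2


class TestMortality:
    def test_listed_fish_fully_removed(self):
        det = make_detections(
            [("A", "S1", f"2022-06-02T00:{m:02d}:00") for m in range(50)])
        mortality = pd.DataFrame({"fish_id": ["F1"]})
        out, n, fish = remove_mortality(det, mortality, DEP)
        assert len(out) == 0 and n == 50 and fish == ["F1"]

    def test_empty_table_is_identity(self):
        det = make_detections([("A", "S1", "2022-06-02T00:00:00")])
        out, n, _ = remove_mortality(det, None, DEP)
        assert n == 0 and len(out) == 1

    def test_after_death_mode_keeps_earlier_records(self):
        det = make_detections([("A", "S1", "2022-06-02T00:00:00"),
                               ("A", "S1", "2022-06-04T00:00:00")])
        mortality = pd.DataFrame({
            "fish_id": ["F1"],
            "death_time": [pd.Timestamp("2022-06-03", tz="UTC")]})
        out, n, _ = remove_mortality(det, mortality, DEP, mode="after_death")
        assert n == 1 and len(out) == 1

    def test_unknown_fish_warns_not_errors(self):
        det = make_detections([("A", "S1", "2022-06-02T00:00:00")])
        with pytest.warns(UserWarning, match="GHOSTFISH"):
            remove_mortality(det, pd.DataFrame({"fish_id": ["GHOSTFISH"]}),
                             DEP)


class TestExcludeStations:
    def _stations(self, days, damaged=False):
        df = make_stations([("S1", "wadden_sea", 0, 0)])
        df["active_end"] = df["active_start"] + pd.Timedelta(days=days)
        df["damaged"] = damaged
        return df

    def test_89_days_excluded_90_retained(self):
        kept, excl = exclude_stations(self._stations(89))
        assert len(kept) == 0 and excl[0]["reason"] == "short_deployment"
        kept, excl = exclude_stations(self._stations(90))
        assert len(kept) == 1 and excl == []

    def test_damaged_excluded_with_reason(self):
        kept, excl = exclude_stations(self._stations(200, damaged=True))
        assert len(kept) == 0 and excl[0]["reason"] == "damaged"

    def test_mixed_partition_matches_brute_force(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(40):
            days = int(rng.integers(10, 400))
            rows.append({"station_id": f"S{i}", "array_name": "a",
                         "region": "wadden_sea", "x_m": 0.0, "y_m": 0.0,
                         "active_start": pd.Timestamp("2021-01-01", tz="UTC"),
                         "active_end": (pd.Timestamp("2021-01-01", tz="UTC")
                                        + pd.Timedelta(days=days)),
                         "damaged": bool(rng.random() < 0.3)})
        df = pd.DataFrame(rows)
        kept, excl = exclude_stations(df)
        expected_kept = {r["station_id"] for _, r in df.iterrows()
                         if not r["damaged"]
                         and (r["active_end"] - r["active_start"]).days >= 90}
        assert set(kept["station_id"]) == expected_kept
        assert len(excl) == len(df) - len(kept)


class TestCascade:
    def test_fixed_order_on_crafted_fixture(self):
        # duplicates must run before the min-delay scan: an exact duplicate
        # has gap 0 and must not consume the scan
        det = make_detections([
            ("A", "S1", "2022-06-02T00:00:00"),
            ("A", "S1", "2022-06-02T00:00:00"),   # exact duplicate
            ("A", "S1", "2022-06-02T00:00:30"),   # sub-delay ghost
            ("A", "S1", "2022-06-02T00:01:30"),   # legal (90 s after first)
            ("A", "S1", "2022-06-02T12:00:00"),   # legal companion
            ("A", "S2", "2022-06-05T00:00:00"),   # isolated singleton
        ])
        out, report = apply_all(det, DEP)
        removed = {r.name: r.removed for r in report.rules}
        assert removed == {"predeployment": 0, "duplicates": 1,
                           "min_delay": 1, "singletons_24h": 1,
                           "mortality": 0}
        assert len(out) == 3

    def test_clean_data_passes_unchanged(self):
        ds = mt.simulate_dataset(small_config(seed=11), with_noise=False)
        out, report = apply_all(ds.detections, ds.deployments, ds.stations,
                                None)
        # clean synthetic data contains no pre-release, duplicate or
        # sub-delay records; only true isolated singletons may fall
        for rule in report.rules:
            if rule.name not in ("singletons_24h",):
                assert rule.removed == 0

    def test_report_counts_reconcile(self, small_dataset, small_filtered):
        out, report = small_filtered
        assert report.input_count == len(small_dataset.detections)
        assert report.input_count - report.output_count == report.total_removed
        assert report.output_count == len(out)

    def test_report_json_round_trips(self, small_filtered):
        import json
        d = json.loads(small_filtered[1].to_json())
        assert {r["name"] for r in d["rules"]} == {
            "predeployment", "duplicates", "min_delay", "singletons_24h",
            "mortality"}

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(20, 200))
    def test_idempotent_and_conservative(self, seed, n):
        rng = np.random.default_rng(seed)
        det = random_detection_table(rng, n)
        dep = make_deployments(
            [(f"F{t}", f"T{t}", "thicklip", "2022-05-25T00:00:00")
             for t in range(8)])
        once, rep1 = apply_all(det, dep)
        twice, rep2 = apply_all(once, dep)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True))
        assert rep2.total_removed == 0
        assert rep1.input_count - rep1.output_count == rep1.total_removed
        assert len(once) <= len(det)


class TestMortalityHeuristic:
    def test_flags_simulated_dead_fish(self):
        cfg = small_config(seed=13, mortality_fraction=0.2,
                           n_false_positives=0, n_echo_duplicates=0,
                           n_subdelay_ghosts=0)
        ds = mt.simulate_dataset(cfg, with_noise=False)
        dead_truth = set(ds.truth.deaths["fish_id"])
        assert dead_truth, "fixture must contain dead fish"
        flagged = mt.filters.flag_mortality_candidates(
            ds.detections, ds.deployments, min_continuous_days=14)
        # every flagged fish is truly dead (no false accusations on this
        # fixture); detectability limits mean not every death is flagged
        assert set(flagged["fish_id"]) <= dead_truth
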