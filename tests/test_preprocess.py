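from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from codnet import preprocess as pp
from conftest import det_frame


def _fish(tid="1001", release="2015-08-15 10:00:00", site="I"):
    return pd.DataFrame({
        "transmitter_id": [tid],
        "release_site": [site],
        "weight_g": [200.0],
        "total_length_cm": [28.0],
        "release_datetime": [pd.Timestamp(release, tz="UTC")],
    })


class TestPostReleaseWindow:
    def test_later_detections_unchanged(self):
        det = det_frame([("2015-08-17 10:00:00", "1001", "A")])
        out = pp.remove_postrelease_window(det, _fish())
        pd.testing.assert_frame_equal(out, det)

    def test_only_records_past_24h_survive(self):
        det = det_frame([
            ("2015-08-15 11:00:00", "1001", "A"),  # +1 h
            ("2015-08-16 09:00:00", "1001", "A"),  # +23 h
            ("2015-08-16 11:00:00", "1001", "A"),  # +25 h
        ])
        out = pp.remove_postrelease_window(det, _fish())
        assert len(out) == 1
        assert out["timestamp"].iloc[0] == pd.Timestamp("2015-08-16 11:00:00", tz="UTC")

    def test_fish_entirely_inside_window_becomes_empty(self):
        det = det_frame([("2015-08-15 12:00:00", "1001", "A")])
        assert len(pp.remove_postrelease_window(det, _fish())) == 0

    def test_unknown_transmitter_raises_with_name(self):
        det = det_frame([("2015-08-20 12:00:00", "1099", "A")])
        with pytest.raises(KeyError, match="1099"):
            pp.remove_postrelease_window(det, _fish())


class TestExtractMovements:
    def test_single_receiver_run_yields_no_movements(self):
        det = det_frame([(f"2015-09-01 12:{m:02d}:00", "1001", "A") for m in range(3)])
        assert len(pp.extract_movements(det)) == 0

    def test_transition_between_receivers_is_one_movement(self):
        det = det_frame([
            ("2015-09-01 12:00:00", "1001", "A"),
            ("2015-09-01 12:10:00", "1001", "B"),
        ])
        mov = pp.extract_movements(det)
        assert len(mov) == 1
        m = mov.iloc[0]
        assert (m["from_receiver"], m["to_receiver"], m["transit_s"]) == ("A", "B", 600.0)

    def test_sub_threshold_transit_removed(self):
        det = det_frame([
            ("2015-09-01 12:00:00", "1001", "A"),
            ("2015-09-01 12:02:00", "1001", "B"),
        ])
        assert len(pp.extract_movements(det)) == 0

    def test_removed_movement_does_not_chain_endpoints(self):
        det = det_frame([
            ("2015-09-01 12:00:00", "1001", "A"),
            ("2015-09-01 12:02:00", "1001", "B"),  # A->B removed (<4 min)
            ("2015-09-01 12:20:00", "1001", "C"),  # B->C kept (18 min)
        ])
        mov = pp.extract_movements(det)
        assert list(zip(mov["from_receiver"], mov["to_receiver"])) == [("B", "C")]

    def test_departure_is_last_detection_of_origin_run(self):
        det = det_frame([
            ("2015-09-01 12:00:00", "1001", "A"),
            ("2015-09-01 12:30:00", "1001", "A"),
            ("2015-09-01 13:00:00", "1001", "B"),
        ])
        mov = pp.extract_movements(det)
        assert mov["departure"].iloc[0] == pd.Timestamp("2015-09-01 12:30:00", tz="UTC")
        assert mov["transit_s"].iloc[0] == 1800.0

    def test_unsorted_input_rejected(self):
        det = det_frame([
            ("2015-09-01 13:00:00", "1001", "A"),
            ("2015-09-01 12:00:00", "1001", "B"),
        ]).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            pp.extract_movements(det)

    @given(st.integers(min_value=0, max_value=5), st.integers(min_value=0, max_value=10))
    def test_duplicating_a_detection_inside_a_run_changes_nothing(self, dup_idx, offset_min):
        rows = [
            ("2015-09-01 12:00:00", "1001", "A"),
            ("2015-09-01 12:20:00", "1001", "A"),
            ("2015-09-01 12:40:00", "1001", "B"),
            ("2015-09-01 13:10:00", "1001", "B"),
            ("2015-09-01 13:40:00", "1001", "C"),
            ("2015-09-01 14:00:00", "1001", "C"),
        ]
        base = det_frame(rows)
        ts = pd.Timestamp(rows[dup_idx][0], tz="UTC") + pd.Timedelta(minutes=offset_min)
        run_end = {0: 1, 1: 1, 2: 3, 3: 3, 4: 5, 5: 5}[dup_idx]
        ts = min(ts, pd.Timestamp(rows[run_end][0], tz="UTC"))
        dup = det_frame(rows + [(ts.strftime("%Y-%m-%d %H:%M:%S"), "1001", rows[dup_idx][2])])
        pd.testing.assert_frame_equal(pp.extract_movements(base), pp.extract_movements(dup))

    def test_movement_count_bounded_by_detections(self, bundle8):
        det = bundle8["detections"]
        mov = pp.extract_movements(det, pd.Timedelta(0))
        per_fish_m = mov.groupby("transmitter_id").size()
        per_fish_d = det.groupby("transmitter_id").size()
        for tid, nm in per_fish_m.items():
            assert nm <= per_fish_d[tid] - 1


class TestIndices:
    @pytest.mark.parametrize("dd,dm,expected", [
        (133, 156, 0.85), (148, 149, 0.99), (146, 155, 0.94), (0, 156, 0.0),
    ])
    def test_residency_index_matches_published_rounding(self, dd, dm, expected):
        assert round(pp.compute_residency_index(dd, dm), 2) == expected

    def test_residency_index_domain_errors(self):
        with pytest.raises(ValueError):
            pp.compute_residency_index(1, 0)
        with pytest.raises(ValueError):
            pp.compute_residency_index(10, 5)

    @pytest.mark.parametrize("nm,dd,expected", [(10, 5, 2.0), (50, 3, 16.67), (0, 10, 0.0)])
    def test_movement_index(self, nm, dd, expected):
        assert round(pp.compute_movement_index(nm, dd), 2) == expected

    def test_movement_index_undefined_without_detection_days(self):
        with pytest.raises(ValueError):
            pp.compute_movement_index(3, 0)

    @pytest.mark.parametrize("release,expected", [
        ("2015-08-15", 156), ("2015-08-16", 155), ("2015-08-21", 150),
        ("2015-08-22", 149), ("2015-08-24", 147),
    ])
    def test_days_monitored_reproduces_reference_arithmetic(self, release, expected):
        assert pp.days_monitored(pd.Timestamp(release), pd.Timestamp("2016-01-18")) == expected


class TestExclusions:
    def _cohort(self, n=48):
        return pd.DataFrame({
            "transmitter_id": [str(2000 + i) for i in range(n)],
            "release_site": ["I"] * n,
            "weight_g": 200.0,
            "total_length_cm": 28.0,
            "release_datetime": pd.Timestamp("2015-08-15 10:00:00", tz="UTC"),
        })

    def _records_and_movements(self, cohort, n_gone=3, n_static=6):
        """Detections/movements where the first n_gone fish vanish within 24 h
        and the next n_static fish are detected but never move."""
        rows = []
        ids = list(cohort["transmitter_id"])
        for tid in ids[:n_gone]:
            rows.append(("2015-08-15 12:00:00", tid, "A"))  # inside 24-h window
        for tid in ids[n_gone:]:
            rows.append(("2015-09-01 10:00:00", tid, "A"))
            rows.append(("2015-09-01 11:00:00", tid, "B"))
        det = det_frame(rows)
        det = pp.remove_postrelease_window(det, cohort)
        mov = pp.extract_movements(det)
        movers = ids[n_gone + n_static:]
        mov = mov.loc[mov["transmitter_id"].isin(movers)].reset_index(drop=True)
        return det, mov

    def test_stated_exclusion_pattern_retains_39_of_48(self):
        cohort = self._cohort(48)
        det, mov = self._records_and_movements(cohort)
        retained, report = pp.exclude_fish(cohort, det, mov)
        assert len(retained) == 39
        reasons = report.loc[~report["retained"], "reason"].value_counts()
        assert reasons["no detections after post-release window"] == 3
        assert reasons["no movements"] == 6

    def test_exclusion_is_idempotent(self):
        cohort = self._cohort(12)
        det, mov = self._records_and_movements(cohort, n_gone=2, n_static=3)
        retained, _ = pp.exclude_fish(cohort, det, mov)
        again, _ = pp.exclude_fish(
            cohort.loc[cohort["transmitter_id"].isin(retained)], det, mov
        )
        assert again == retained

    def test_no_exclusions_is_identity_and_all_gone_is_empty(self):
        cohort = self._cohort(5)
        det, mov = self._records_and_movements(cohort, n_gone=0, n_static=0)
        retained, _ = pp.exclude_fish(cohort, det, mov)
        assert retained == list(cohort["transmitter_id"])
        empty = det.iloc[:0]
        retained, _ = pp.exclude_fish(cohort, empty, mov.iloc[:0])
        assert retained == []


class TestSeasons:
    @pytest.mark.parametrize("ts,label", [
        ("2015-09-01", "summer"), ("2015-10-05", "summer"), ("2015-10-06", "autumn"),
        ("2015-12-11", "autumn"), ("2015-12-12", "winter"), ("2016-01-18", "winter"),
    ])
    def test_reference_boundaries(self, ts, label):
        assert pp.assign_season(pd.Timestamp(ts)) == label

    def test_outside_all_windows_raises(self):
        with pytest.raises(ValueError, match="outside"):
            pp.assign_season(pd.Timestamp("2016-06-01"))

    def test_overlapping_windows_rejected(self):
        bad = (
            pp.SeasonWindow("a", date(2015, 8, 15), date(2015, 10, 6)),
            pp.SeasonWindow("b", date(2015, 10, 6), date(2015, 12, 11)),
        )
        with pytest.raises(ValueError, match="overlap"):
            pp.check_season_windows(bad)


class TestRelativeMovements:
    def test_ratio_and_zero_and_missing_cases(self):
        det = det_frame(
            [("2015-09-01 10:00:00", str(1001 + i), "A") for i in range(5)]
            + [("2015-09-02 10:00:00", "1001", "A"), ("2015-09-02 11:00:00", "1002", "A"),
               ("2015-09-02 12:00:00", "1003", "A")]
        )
        mov = pd.DataFrame({
            "transmitter_id": ["1001"] * 10,
            "from_receiver": "A", "to_receiver": "B",
            "departure": pd.Timestamp("2015-09-01 12:00:00", tz="UTC"),
            "arrival": pd.Timestamp("2015-09-01 12:10:00", tz="UTC"),
            "transit_s": 600.0,
        })
        out = pp.relative_movements_per_day(mov, det).set_index("date")
        d1, d2 = date(2015, 9, 1), date(2015, 9, 2)
        assert out.loc[d1, "relative_movements"] == 2.0
        assert out.loc[d2, "relative_movements"] == 0.0

    def test_movements_without_detections_flagged_missing(self):
        mov = pd.DataFrame({
            "transmitter_id": ["1001"] * 4,
            "from_receiver": "A", "to_receiver": "B",
            "departure": pd.Timestamp("2015-09-03 12:00:00", tz="UTC"),
            "arrival": pd.Timestamp("2015-09-03 12:10:00", tz="UTC"),
            "transit_s": 600.0,
        })
        out = pp.relative_movements_per_day(mov, det_frame([]).iloc[:0])
        assert np.isnan(out["relative_movements"]).all()
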