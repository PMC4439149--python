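"""Ingest filters: allometric weight, transit/mismatch removal, effort split."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from reefcpue.ingest import (apportion_effort, estimate_weight,
                             flag_reef_mismatch, flag_transit_outliers, ingest)
from reefcpue.raster import Raster


def _records(rows):
    return pd.DataFrame(rows, columns=["diver_id", "timestamp", "x_m", "y_m",
                                       "shell_length_mm"])


class TestWeight:
    def test_reference_length_maps_to_coefficient(self):
        assert estimate_weight(10.0) == pytest.approx(0.000412, abs=1e-15)

    def test_independently_computed_value_at_100mm(self):
        # 0.000412 * 10^2.76 evaluated with 30-digit arithmetic
        assert estimate_weight(100.0) == pytest.approx(0.23708125418290866,
                                                       abs=1e-12)

    def test_strictly_monotone(self):
        sl = np.linspace(0.5, 250.0, 500)
        w = estimate_weight(sl)
        assert np.all(np.diff(w) > 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            estimate_weight(0.0)
        with pytest.raises(ValueError):
            estimate_weight(np.array([50.0, -1.0]))


class TestTransitFilter:
    def test_fast_gap_removed(self):
        recs = _records([
            ("D1", "2008-03-01T08:00:00", 0.0, 0.0, 130.0),
            ("D1", "2008-03-01T08:01:00", 1000.0, 0.0, 130.0),
        ])
        kept, rep = flag_transit_outliers(recs, 2.0)
        assert len(kept) == 1 and rep.n_transit_removed == 1
        assert rep.removal_reasons == {1: "transit"}

    def test_slow_gaps_identity(self):
        recs = _records([
            ("D1", "2008-03-01T08:00:00", 0.0, 0.0, 130.0),
            ("D1", "2008-03-01T08:01:00", 30.0, 0.0, 130.0),
            ("D1", "2008-03-01T08:02:00", 60.0, 40.0, 130.0),
        ])
        kept, rep = flag_transit_outliers(recs, 2.0)
        assert len(kept) == 3 and rep.n_transit_removed == 0

    def test_streaming_removal_does_not_cascade(self):
        # transit excursion then a return near the original track: only the
        # excursion is removed because speed is taken vs the last retained
        recs = _records([
            ("D1", "2008-03-01T08:00:00", 0.0, 0.0, 130.0),
            ("D1", "2008-03-01T08:02:00", 2000.0, 0.0, 130.0),   # 16.7 m/s
            ("D1", "2008-03-01T08:04:00", 20.0, 0.0, 130.0),     # slow vs #0
        ])
        kept, rep = flag_transit_outliers(recs, 2.0)
        assert list(kept.index) == [0, 2]

    def test_duplicate_timestamp_different_position_rejected(self):
        recs = _records([
            ("D1", "2008-03-01T08:00:00", 0.0, 0.0, 130.0),
            ("D1", "2008-03-01T08:00:00", 50.0, 0.0, 130.0),
        ])
        with pytest.raises(ValueError, match="malformed"):
            flag_transit_outliers(recs, 2.0)

    def test_planted_outlier_recovery(self, small_seafloor, small_fishery):
        out, cfg = small_fishery
        kept, rep = flag_transit_outliers(out.swipes, 2.0)
        planted = set(out.truth.transit_indices)
        assert planted
        removed = set(rep.removal_reasons)
        sens = len(planted & removed) / len(planted)
        assert sens >= 0.95
        # false removals stay rare
        fp = len(removed - planted) / (len(out.swipes) - len(planted))
        assert fp <= 0.02


class TestReefMismatch:
    def _halfplane_mask(self):
        # reef occupies x < 500 of a 1000 x 200 m area at 10 m pixels
        data = np.zeros((20, 100), dtype=bool)
        data[:, :50] = True
        return Raster(data, 0.0, 0.0, 10.0)

    def test_on_reef_retained_far_removed(self):
        mask = self._halfplane_mask()
        recs = _records([
            ("D1", "2008-03-01T08:00:00", 250.0, 100.0, 130.0),   # on reef
            ("D1", "2008-03-01T08:01:00", 995.0, 100.0, 130.0),   # ~500 m off
        ])
        kept, rep = flag_reef_mismatch(recs, mask, buffer_m=100.0)
        assert list(kept.index) == [0]
        assert rep.removal_reasons == {1: "reef_mismatch"}

    def test_matches_buffered_polygon_oracle(self, rng):
        mask = self._halfplane_mask()
        # geometric oracle: points within 100 m of the buffered reef pixels
        reef_poly = box(0.0, 0.0, 500.0, 200.0).buffer(0.0)
        n = 400
        pts = np.column_stack([rng.uniform(0, 1000, n), rng.uniform(0, 200, n)])
        recs = _records([("D1", f"2008-03-01T08:{i // 60:02d}:{i % 60:02d}",
                          x, y, 130.0) for i, (x, y) in enumerate(pts)])
        recs["timestamp"] = pd.to_datetime(recs["timestamp"])
        kept, _ = flag_reef_mismatch(recs, mask, buffer_m=100.0)
        # oracle distance: to nearest reef pixel centre (pixel centres span
        # x in [5, 495], y in [5, 195])
        for i, (x, y) in enumerate(pts):
            px = min(max(x, 5.0), 495.0)
            py = min(max(y, 5.0), 195.0)
            d = Point(x, y).distance(Point(px, py))
            assert (i in kept.index) == (d <= 100.0)

    def test_empty_mask_removes_all_with_warning(self):
        mask = Raster(np.zeros((5, 5), dtype=bool), 0.0, 0.0, 10.0)
        recs = _records([("D1", "2008-03-01T08:00:00", 10.0, 10.0, 130.0)])
        kept, rep = flag_reef_mismatch(recs, mask)
        assert kept.empty and rep.n_reef_mismatch_removed == 1
        assert any("empty" in w for w in rep.warnings)


class TestApportionment:
    def _effort(self, rows):
        return pd.DataFrame(rows, columns=["diver_id", "date", "hours"])

    def test_even_split(self):
        recs = _records([("D1", f"2008-03-01T08:0{i}:00", 0, 0, 130.0)
                         for i in range(4)])
        eff = self._effort([("D1", "2008-03-01", 2.0)])
        out, unmatched = apportion_effort(recs, eff)
        assert np.allclose(out["apportioned_hours"], 0.5)
        assert unmatched == []

    def test_single_swipe_gets_all_hours(self):
        recs = _records([("D1", "2008-03-01T08:00:00", 0, 0, 130.0)])
        eff = self._effort([("D1", "2008-03-01", 3.0)])
        out, _ = apportion_effort(recs, eff)
        assert out["apportioned_hours"].iloc[0] == 3.0

    def test_sums_match_logbook_on_random_structure(self, rng):
        rows, eff_rows = [], []
        for d in range(3):
            for day in range(4):
                n = int(rng.integers(1, 9))
                date = f"2008-03-{day + 1:02d}"
                hours = float(rng.uniform(1, 8))
                eff_rows.append((f"D{d}", date, hours))
                for k in range(n):
                    rows.append((f"D{d}", f"{date}T08:{k:02d}:00", 0, 0, 130.0))
        out, _ = apportion_effort(_records(rows), self._effort(eff_rows))
        total_eff = sum(r[2] for r in eff_rows)
        assert out["apportioned_hours"].sum() == pytest.approx(total_eff,
                                                               abs=1e-9)

    def test_missing_logbook_day_is_error(self):
        recs = _records([("D1", "2008-03-01T08:00:00", 0, 0, 130.0)])
        eff = self._effort([("D1", "2008-03-02", 2.0)])
        with pytest.raises(ValueError, match="logbook"):
            apportion_effort(recs, eff)

    def test_logbook_day_without_swipes_reported(self):
        recs = _records([("D1", "2008-03-01T08:00:00", 0, 0, 130.0)])
        eff = self._effort([("D1", "2008-03-01", 2.0), ("D1", "2008-03-02", 1.0)])
        out, unmatched = apportion_effort(recs, eff)
        assert unmatched == [("D1", "2008-03-02")]


class TestCombinedIngest:
    def test_filter_order_insensitive_on_nonoverlapping_faults(self):
        # transit outlier is on reef; mismatch point is slow: the two filters
        # touch disjoint records, so their order cannot matter
        mask = Raster(np.ones((20, 20), dtype=bool), 0.0, 0.0, 10.0)
        mask.data[:, 10:] = False  # reef is x < 100
        recs = _records([
            ("D1", "2008-03-01T08:00:00", 10.0, 50.0, 130.0),
            ("D1", "2008-03-01T08:00:30", 95.0, 140.0, 130.0),   # fast, on reef
            ("D1", "2008-03-01T09:00:00", 20.0, 60.0, 130.0),
            ("D1", "2008-03-01T09:30:00", 190.9, 190.0, 131.0),  # slow, off reef (>100 m)
        ])
        a1, _ = flag_transit_outliers(recs, 2.0)
        a2, _ = flag_reef_mismatch(a1, mask, 80.0)
        b1, _ = flag_reef_mismatch(recs, mask, 80.0)
        b2, _ = flag_transit_outliers(b1, 2.0)
        assert sorted(a2.index) == sorted(b2.index) == [0, 2]

    def test_counts_reconcile_and_weight_conserved(self, small_seafloor,
                                                   small_fishery):
        sea = small_seafloor
        out, _ = small_fishery
        retained, rep = ingest(out.swipes, out.effort, sea.reef_mask)
        assert rep.n_input == rep.n_retained + rep.n_transit_removed \
            + rep.n_reef_mismatch_removed
        total = estimate_weight(retained["shell_length_mm"].to_numpy()).sum()
        assert retained["weight_kg"].sum() == pytest.approx(total, rel=1e-12)
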