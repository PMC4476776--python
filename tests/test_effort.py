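import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import aisfish as af
from aisfish.effort import (allocate_trip_days, compare_efforts,
                            grid_to_rectangles)


def _labeled(n_fishing, n_other=0, vessel="V1", lat=57.5, lon=11.0):
    n = n_fishing + n_other
    return pd.DataFrame(dict(
        ais_vessel_id=vessel, lat=lat + 0.001 * np.arange(n), lon=lon,
        label=["fishing"] * n_fishing + ["non-fishing"] * n_other))


class TestAisEffort:
    def test_twelve_messages_100kw_one_hour(self):
        grid = af.ais_effort(_labeled(12), {"V1": 100.0})
        assert grid.total == pytest.approx(100 * 3600 / 86400, abs=1e-12)

    def test_full_day_equals_power(self):
        grid = af.ais_effort(_labeled(288), {"V1": 100.0})
        assert grid.total == pytest.approx(100.0, abs=1e-9)

    def test_non_fishing_contributes_nothing(self):
        grid = af.ais_effort(_labeled(0, 50), {"V1": 100.0})
        assert grid.total == 0.0

    def test_conservation_under_random_labeling(self, small_fleet):
        rng = np.random.default_rng(0)
        msgs = small_fleet.messages.copy()
        msgs["label"] = np.where(rng.random(len(msgs)) < 0.5,
                                 "fishing", "non-fishing")
        power = small_fleet.truth.vessels.set_index("ais_vessel_id")["power_kw"]
        grid = af.ais_effort(msgs, power)
        fishing = msgs[msgs.label == "fishing"]
        expected = (fishing.ais_vessel_id.map(power) * 300 / 86400).sum()
        assert grid.total == pytest.approx(expected, rel=1e-9)

    def test_unknown_vessel_skipped_and_counted(self):
        df = pd.concat([_labeled(5, vessel="V1"), _labeled(3, vessel="V2")],
                       ignore_index=True)
        grid = af.ais_effort(df, {"V1": 100.0})
        assert grid.skipped_messages == 3
        assert grid.total == pytest.approx(5 * 100 * 300 / 86400)

    def test_cell_size_is_one_nautical_mile(self):
        grid = af.ais_effort(_labeled(1), {"V1": 100.0})
        assert grid.dlat == pytest.approx(1 / 60)
        # cell width is ~1 NM at grid latitude, adjusted to divide 1 degree
        width_nm = grid.dlon * 60 * np.cos(np.radians(grid.lat0 + 0.25))
        assert width_nm == pytest.approx(1.0, abs=0.02)
        assert round(1 / grid.dlon) == pytest.approx(1 / grid.dlon)


class TestLogbookEffort:
    @staticmethod
    def _trip(rects_catches, days=2.0, vessel="R1", trip="T1"):
        dep = pd.Timestamp("2024-03-01T00:00:00Z")
        return pd.DataFrame([
            dict(vessel_id=vessel, trip_id=trip, departure=dep,
                 arrival=dep + pd.Timedelta(days=days), lat=57.5, lon=11.0,
                 catch_kg=c, gear="OTB", ices_rectangle=r)
            for r, c in rects_catches])

    def test_proportional_split(self):
        lb = self._trip([("44G1", 300.0), ("44G2", 100.0)])
        out = af.logbook_effort(lb, {"R1": 200.0}).set_index("rectangle")
        assert out.loc["44G1", "kw_days"] == pytest.approx(1.5 * 200)
        assert out.loc["44G2", "kw_days"] == pytest.approx(0.5 * 200)

    def test_single_rectangle_gets_everything(self):
        out = af.logbook_effort(self._trip([("44G1", 50.0)], days=3.0),
                                {"R1": 400.0})
        assert out.kw_days.iloc[0] == pytest.approx(3.0 * 400)

    def test_zero_catch_equal_split(self):
        lb = self._trip([("44G1", 0.0), ("44G2", 0.0)])
        out = af.logbook_effort(lb, {"R1": 100.0})
        assert np.allclose(out.kw_days, [100.0, 100.0])

    @given(st.lists(st.floats(0, 1e4, allow_nan=False), min_size=1, max_size=6),
           st.floats(0.1, 30.0))
    def test_allocated_days_conserve_trip_duration(self, catches, duration):
        days, _ = allocate_trip_days(duration, np.array(catches))
        assert days.sum() == pytest.approx(duration, rel=1e-12)
        assert (days >= 0).all()


class TestIcesRectangles:
    def test_known_rectangle(self):
        assert af.ices_encode(57.75, 11.5).code == "44G1"

    def test_known_anchors(self):
        assert af.ices_encode(51.75, 3.5).code == "32F3"
        assert af.ices_encode(54.25, 3.5).code == "37F3"
        assert af.ices_encode(36.0, -44.0).code == "01A0"

    def test_round_trip_contains_point(self):
        rng = np.random.default_rng(7)
        lats = rng.uniform(36.0, 85.5 - 1e-9, 1000)
        lons = rng.uniform(-44.0, 68.5 - 1e-9, 1000)
        for lat, lon in zip(lats, lons):
            r = af.ices_decode(af.ices_encode(lat, lon).code)
            assert r.lat_min <= lat < r.lat_max
            assert r.lon_min <= lon < r.lon_max

    def test_boundary_point_belongs_to_upper_cell(self):
        r = af.ices_encode(57.5, 11.0)
        assert r.lat_min == 57.5 and r.lon_min == 11.0

    def test_out_of_domain_rejected(self):
        for lat, lon in [(30.0, 0.0), (60.0, -50.0), (90.0, 0.0), (60.0, 70.0)]:
            with pytest.raises(ValueError):
                af.ices_encode(lat, lon)

    def test_malformed_codes_rejected(self):
        for code in ["44I1", "44A5", "0044", "44G", "44GX"]:
            with pytest.raises(ValueError):
                af.ices_decode(code)


class TestCompareEfforts:
    def test_grid_refinement_consistency(self, small_fleet, default_pipeline):
        """Aggregating the 1-NM grid to rectangles equals computing effort
        directly at rectangle resolution."""
        rng = np.random.default_rng(1)
        msgs = small_fleet.messages.copy()
        msgs["label"] = np.where(rng.random(len(msgs)) < 0.4,
                                 "fishing", "non-fishing")
        power = small_fleet.truth.vessels.set_index("ais_vessel_id")["power_kw"]
        fine = grid_to_rectangles(af.ais_effort(msgs, power)).set_index("rectangle")
        fishing = msgs[msgs.label == "fishing"].copy()
        fishing["rectangle"] = [af.ices_encode(a, b).code for a, b in
                                zip(fishing.lat, fishing.lon)]
        fishing["kw"] = fishing.ais_vessel_id.map(power)
        direct = (fishing.groupby("rectangle")["kw"].sum() * 300 / 86400)
        assert set(fine.index) == set(direct.index)
        for rect in direct.index:
            assert fine.loc[rect, "kw_days"] == pytest.approx(direct[rect],
                                                              rel=1e-9)

    def test_ais_effort_bounded_by_logbook_when_trips_fully_fished(self):
        """A trip whose whole at-sea time is labeled fishing gives AIS
        effort <= logbook effort in its rectangle (logbooks count whole
        days at sea)."""
        n = 96  # 8 hours of fishing messages
        labeled = _labeled(n, lat=57.75, lon=11.5)
        grid = af.ais_effort(labeled, {"V1": 200.0})
        dep = pd.Timestamp("2024-03-01T00:00:00Z")
        lb = pd.DataFrame([dict(vessel_id="R1", trip_id="T1", departure=dep,
                                arrival=dep + pd.Timedelta(hours=10),
                                lat=57.75, lon=11.5, catch_kg=100.0, gear="OTB",
                                ices_rectangle="44G1")])
        lb_eff = af.logbook_effort(lb, {"R1": 200.0})
        table, _ = compare_efforts(grid, lb_eff)
        assert (table.ais_kw_days <= table.logbook_kw_days + 1e-9).all()

    def test_default_fleet_rank_correlation_positive(self, default_fleet,
                                                     default_pipeline):
        labeled = default_pipeline["labeled"]
        power = default_fleet.truth.vessels.set_index("ais_vessel_id")["power_kw"]
        power_reg = default_fleet.register.set_index("register_id")["power_kw"]
        grid = af.ais_effort(labeled, power)
        lb_eff = af.logbook_effort(default_fleet.logbook, power_reg)
        table, rho = compare_efforts(grid, lb_eff)
        assert rho > 0.5

    def test_single_rectangle_comparison_has_one_row(self):
        labeled = _labeled(10, lat=57.75, lon=11.5)
        grid = af.ais_effort(labeled, {"V1": 100.0})
        lb_eff = pd.DataFrame(dict(rectangle=["44G1"], kw_days=[400.0]))
        table, rho = compare_efforts(grid, lb_eff)
        assert len(table) == 1
        assert np.isnan(rho)  # correlation undefined on one rectangle
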