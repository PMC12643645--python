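"""Heat-index algorithm, grid aggregation, percentile tables, moving averages."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from heatpm.heat import (HeatPercentileTable, aggregate_grid_to_zip,
                         compute_heat_index, compute_percentiles,
                         moving_average, percentile_tables_from_frame,
                         percentile_tables_to_frame, to_percentile)


def f_to_c(f):
    return (f - 32.0) * 5.0 / 9.0


def c_to_f(c):
    return c * 9.0 / 5.0 + 32.0


# Frozen from an independent evaluation of the published NWS formulas
# (Steadman simple formula, Rothfusz regression, both humidity adjustments),
# in degF: (T_f, RH_pct, heat_index_f).
NWS_POINTS = [
    (70, 50, 69.0500),    # simple-formula branch
    (75, 80, 75.9600),    # simple-formula branch
    (60, 90, 59.9300),    # cool and humid, still simple branch
    (79, 10, 77.0700),    # just below the 80 degF threshold
    (85, 60, 89.2513),    # Rothfusz, no adjustment
    (90, 70, 105.9220),   # Rothfusz, no adjustment
    (96, 65, 121.0316),   # Rothfusz, no adjustment
    (100, 10, 94.1225),   # low-humidity adjustment region
    (105, 8, 98.1239),    # low-humidity adjustment region
    (82, 90, 92.7417),    # high-humidity adjustment region
    (86, 95, 108.8268),   # high-humidity adjustment region
    (110, 40, 135.6570),  # hot, unadjusted Rothfusz
]


@pytest.mark.parametrize("t_f,rh,expected_f", NWS_POINTS)
def test_heat_index_matches_nws_reference(t_f, rh, expected_f):
    got_f = c_to_f(compute_heat_index(f_to_c(t_f), rh))
    assert got_f == pytest.approx(expected_f, abs=0.1)


def test_low_humidity_adjustment_is_exactly_the_nws_term():
    # at (100 F, 10%) the output differs from the raw Rothfusz polynomial by
    # ((13-R)/4) * sqrt((17-|T-95|)/17)
    t_f, rh = 100.0, 10.0
    raw = (-42.379 + 2.04901523 * t_f + 10.14333127 * rh
           - 0.22475541 * t_f * rh - 6.83783e-3 * t_f**2
           - 5.481717e-2 * rh**2 + 1.22874e-3 * t_f**2 * rh
           + 8.5282e-4 * t_f * rh**2 - 1.99e-6 * t_f**2 * rh**2)
    adj = ((13 - rh) / 4.0) * np.sqrt((17 - abs(t_f - 95.0)) / 17.0)
    got_f = c_to_f(compute_heat_index(f_to_c(t_f), rh))
    assert got_f == pytest.approx(raw - adj, abs=1e-6)


def test_branch_boundary_seam_is_bounded():
    # The NWS simple/Rothfusz switch is not exactly continuous; the seam
    # stays under 1 degF up to moderate humidity and under 2.5 degF overall
    # (largest near saturation), a documented property of the published
    # algorithm.
    for rh, bound in [(20.0, 1.0), (40.0, 1.0), (50.0, 1.0),
                      (70.0, 2.5), (90.0, 2.5)]:
        t_f = np.linspace(75, 95, 2001)
        hi_f = c_to_f(compute_heat_index(f_to_c(t_f), rh))
        jumps = np.abs(np.diff(hi_f))
        assert jumps.max() < bound


def test_monotone_in_humidity_when_hot():
    t_f = 95.0
    rh = np.linspace(14, 84, 200)  # outside both adjustment corners
    hi = compute_heat_index(np.full_like(rh, f_to_c(t_f)), rh)
    assert np.all(np.diff(hi) > 0)


@pytest.mark.parametrize("bad", [
    {"tmax_c": 30.0, "rhmin_pct": -1.0},
    {"tmax_c": 30.0, "rhmin_pct": 101.0},
    {"tmax_c": np.nan, "rhmin_pct": 50.0},
    {"tmax_c": np.inf, "rhmin_pct": 50.0},
])
def test_heat_index_rejects_invalid_inputs(bad):
    with pytest.raises(ValueError):
        compute_heat_index(bad["tmax_c"], bad["rhmin_pct"])


class TestGridAggregation:
    def test_two_point_mean(self):
        grid = pd.DataFrame({"cell_id": [1, 2], "value": [10.0, 20.0]})
        mapping = pd.DataFrame({"cell_id": [1, 2], "zip": ["A", "A"]})
        out = aggregate_grid_to_zip(grid, mapping)
        assert out.loc[out["zip"] == "A", "value"].item() == 15.0

    def test_one_cell_per_zip_is_identity(self):
        grid = pd.DataFrame({"cell_id": range(5), "value": [1., 2., 3., 4., 5.]})
        mapping = pd.DataFrame({"cell_id": range(5),
                                "zip": [f"Z{i}" for i in range(5)]})
        out = aggregate_grid_to_zip(grid, mapping).sort_values("zip")
        assert np.array_equal(out["value"].to_numpy(), grid["value"].to_numpy())

    def test_matches_brute_force_group_mean(self, rng):
        n = 1000
        grid = pd.DataFrame({"cell_id": np.arange(n), "value": rng.normal(size=n)})
        mapping = pd.DataFrame({"cell_id": np.arange(n),
                                "zip": rng.integers(0, 50, size=n)})
        out = aggregate_grid_to_zip(grid, mapping).set_index("zip")["value"]
        for z in out.index:
            cells = mapping.loc[mapping["zip"] == z, "cell_id"]
            expected = grid.set_index("cell_id").loc[cells, "value"].mean()
            assert out[z] == pytest.approx(expected, abs=1e-12)

    def test_empty_mapping_warns_and_returns_empty(self):
        grid = pd.DataFrame({"cell_id": [1], "value": [1.0]})
        with pytest.warns(UserWarning):
            out = aggregate_grid_to_zip(grid, pd.DataFrame(columns=["cell_id", "zip"]))
        assert out.empty


class TestPercentiles:
    def _records(self, values, dates, zip_="Z0"):
        return pd.DataFrame({"zip": zip_, "date": pd.to_datetime(dates),
                             "heat_index": values})

    def test_constant_series_collapses(self):
        rec = self._records([25.0] * 10, ["2010-07-01"] * 10)
        climate = pd.DataFrame({"zip": ["Z0"], "subtype": ["Cfa"]})
        tables = compute_percentiles(rec, climate)
        t = tables["Cfa"]
        assert t.percentile(25.0) == 100.0
        assert t.quantile(0) == t.quantile(100) == 25.0

    def test_rank_convention_on_1_to_100(self):
        rec = self._records(np.arange(1.0, 101.0), ["2010-06-15"] * 100)
        climate = pd.DataFrame({"zip": ["Z0"], "subtype": ["Dfb"]})
        t = compute_percentiles(rec, climate)["Dfb"]
        # right-continuous proportion-<=: 50 of 100 values are <= 50
        assert t.percentile(50.0) == 50.0
        assert t.percentile(100.0) == 100.0
        assert t.percentile(0.5) == 0.0

    def test_off_season_values_excluded(self):
        rec = self._records([10.0, 40.0], ["2010-01-15", "2010-07-15"])
        climate = pd.DataFrame({"zip": ["Z0"], "subtype": ["Cfa"]})
        t = compute_percentiles(rec, climate)["Cfa"]
        assert t.values.tolist() == [40.0]

    def test_same_degc_maps_differently_across_subtypes(self):
        rec = pd.concat([
            self._records(np.linspace(20, 30, 50), ["2010-07-01"] * 50, "Z0"),
            self._records(np.linspace(25, 35, 50), ["2010-07-01"] * 50, "Z1"),
        ])
        climate = pd.DataFrame({"zip": ["Z0", "Z1"], "subtype": ["Dfb", "Cfa"]})
        tables = compute_percentiles(rec, climate)
        assert to_percentile(28.0, "Dfb", tables) > to_percentile(28.0, "Cfa", tables)

    def test_unknown_subtype_rejected(self):
        with pytest.raises(KeyError):
            to_percentile(20.0, "Xx", {})

    def test_quantile_percentile_identity_on_sample(self, rng):
        vals = rng.normal(28, 4, size=200)
        t = HeatPercentileTable(subtype="Cfa", values=vals)
        for x in np.sort(vals)[[0, 50, 120, 199]]:
            assert t.quantile(t.percentile(x)) == pytest.approx(x)

    def test_roundtrip_serialization(self, rng):
        t = HeatPercentileTable(subtype="BSk", values=rng.normal(30, 5, 50))
        frame = percentile_tables_to_frame({"BSk": t})
        back = percentile_tables_from_frame(frame)["BSk"]
        assert np.array_equal(back.values, t.values)


class TestMovingAverage:
    def _panel(self, values, start="2010-05-01", zip_="Z0"):
        dates = pd.date_range(start, periods=len(values), freq="D")
        return pd.DataFrame({"zip": zip_, "date": dates, "x": values})

    def test_constant_series_unchanged(self):
        out = moving_average(self._panel([7.0] * 6), 3, value_cols=("x",))
        assert np.allclose(out["x"].iloc[2:], 7.0)
        assert out["x"].iloc[:2].isna().all()

    def test_hand_computed_example(self):
        out = moving_average(self._panel([1.0, 2.0, 3.0, 4.0]), 3,
                             value_cols=("x",))
        assert out["x"].iloc[:2].isna().all()
        assert out["x"].iloc[2] == 2.0
        assert out["x"].iloc[3] == 3.0

    def test_april_run_in_feeds_early_may(self):
        # panel starting April 29 gives complete 3-day means on May 1
        out = moving_average(self._panel([10.0, 20.0, 30.0, 40.0],
                                         start="2010-04-29"), 3,
                             value_cols=("x",))
        may1 = out[out["date"] == "2010-05-01"]["x"].item()
        assert may1 == pytest.approx((10 + 20 + 30) / 3)
        may2 = out[out["date"] == "2010-05-02"]["x"].item()
        assert may2 == pytest.approx((20 + 30 + 40) / 3)

    def test_calendar_gap_yields_missing(self):
        panel = self._panel([1.0, 2.0, 3.0])
        panel.loc[2, "date"] = pd.Timestamp("2010-05-10")  # break adjacency
        out = moving_average(panel, 3, value_cols=("x",))
        assert out["x"].iloc[2:].isna().all()

    def test_window_below_one_rejected(self):
        with pytest.raises(ValueError):
            moving_average(self._panel([1.0]), 0, value_cols=("x",))

    @given(shift=st.floats(-50, 50))
    def test_commutes_with_adding_constant(self, shift):
        base = self._panel([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        a = moving_average(base, 3, value_cols=("x",))["x"]
        shifted = base.assign(x=base["x"] + shift)
        b = moving_average(shifted, 3, value_cols=("x",))["x"]
        assert np.allclose(a + shift, b, equal_nan=True)
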