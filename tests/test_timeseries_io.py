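import numpy as np
import pandas as pd
import pytest

from mosqspec import (
    TimeSeries,
    WeatherDialect,
    fill_gaps,
    moving_average,
    read_abundance,
    read_weather,
    write_abundance,
    write_weather,
    generate_weather,
)
from mosqspec.synthetic import WeatherGenParams


class TestTimeSeriesInvariants:
    def test_rejects_unequal_spacing(self):
        dates = pd.DatetimeIndex(["2010-01-01", "2010-01-02", "2010-01-04"])
        with pytest.raises(ValueError, match="equally spaced"):
            TimeSeries(dates, [1.0, 2.0, 3.0])

    def test_rejects_duplicate_dates(self):
        dates = pd.DatetimeIndex(["2010-01-01", "2010-01-01", "2010-01-02"])
        with pytest.raises(ValueError, match="increasing"):
            TimeSeries(dates, [1.0, 2.0, 3.0])

    def test_rejects_length_one(self):
        with pytest.raises(ValueError, match="at least 2"):
            TimeSeries(pd.DatetimeIndex(["2010-01-01"]), [1.0])

    def test_weekly_spacing_accepted(self, ts_factory):
        ts = ts_factory([1, 2, 3], delta_t=7.0)
        assert ts.delta_t == 7.0


class TestMovingAverage:
    def test_window_one_is_identity(self, ts_factory):
        ts = ts_factory([3.0, 1.0, 4.0, 1.0, 5.0])
        out = moving_average(ts, 1)
        np.testing.assert_array_equal(out.values, ts.values)

    def test_constant_series_unchanged(self, ts_factory):
        ts = ts_factory([7.0] * 20)
        out = moving_average(ts, 10)
        np.testing.assert_allclose(out.values, 7.0)

    def test_trailing_mean_of_1_to_10(self, ts_factory):
        ts = ts_factory(list(range(1, 11)))
        out = moving_average(ts, 10)
        assert out.values[-1] == pytest.approx(5.5)  # (1+...+10)/10
        # partial windows at the start use the available days
        assert out.values[0] == pytest.approx(1.0)
        assert out.values[2] == pytest.approx(2.0)

    def test_window_below_one_rejected(self, ts_factory):
        with pytest.raises(ValueError):
            moving_average(ts_factory([1, 2, 3]), 0)


class TestFillGaps:
    def test_single_hole_midpoint(self, ts_factory):
        ts = ts_factory([2.0, np.nan, 6.0])
        out = fill_gaps(ts, max_gap=2)
        assert out.values[1] == pytest.approx(4.0)

    def test_long_gap_rejected_with_span(self, ts_factory):
        ts = ts_factory([1.0] + [np.nan] * 5 + [1.0])
        with pytest.raises(ValueError, match="gap of 5 days"):
            fill_gaps(ts, max_gap=2)

    def test_gapless_series_returned_unchanged(self, ts_factory):
        ts = ts_factory([1.0, 2.0, 3.0])
        assert fill_gaps(ts, max_gap=3) is ts

    def test_observed_values_never_altered(self, ts_factory):
        vals = [5.0, np.nan, 9.0, 4.0, np.nan, np.nan, 8.0]
        ts = ts_factory(vals)
        out = fill_gaps(ts, max_gap=3)
        observed = ~np.isnan(np.asarray(vals))
        np.testing.assert_array_equal(out.values[observed],
                                      np.asarray(vals)[observed])
        assert not out.has_gaps


class TestAbundanceIO:
    def test_round_trip_exact(self, tmp_path, ts_factory):
        ts = ts_factory([0, 12, 800, 3, 0], label="ae_vexans")
        path = tmp_path / "abund.csv"
        write_abundance(path, [ts])
        back = read_abundance(path, "ae_vexans")
        np.testing.assert_array_equal(back.values, ts.values)
        assert (back.dates == ts.dates).all()

    def test_two_row_file(self, tmp_path):
        (tmp_path / "a.csv").write_text("date,sp\n2010-01-01,4\n2010-01-02,5\n")
        ts = read_abundance(tmp_path / "a.csv", "sp")
        assert len(ts) == 2

    def test_unknown_species_lists_available(self, tmp_path):
        (tmp_path / "a.csv").write_text("date,sp1,sp2\n2010-01-01,1,2\n2010-01-02,3,4\n")
        with pytest.raises(ValueError, match="sp1"):
            read_abundance(tmp_path / "a.csv", "nope")

    def test_duplicated_date_rejected(self, tmp_path):
        (tmp_path / "a.csv").write_text("date,sp\n2010-01-01,1\n2010-01-01,2\n")
        with pytest.raises(ValueError, match="duplicated"):
            read_abundance(tmp_path / "a.csv", "sp")

    def test_missing_days_become_gaps_not_values(self, tmp_path):
        (tmp_path / "a.csv").write_text(
            "date,sp\n2010-01-01,1\n2010-01-02,2\n2010-01-06,6\n"
        )
        ts = read_abundance(tmp_path / "a.csv", "sp")
        assert len(ts) == 6
        assert ts.gap_spans() == [(2, 5)]


class TestWeatherIO:
    def test_synthetic_year_round_trip(self, tmp_path):
        w = generate_weather(365, WeatherGenParams(seed=1))
        path = tmp_path / "w.csv"
        write_weather(path, w)
        back = read_weather(path)
        assert len(back) == 365
        np.testing.assert_allclose(back.temperature, w.temperature, atol=1e-9)

    def test_tenths_mm_dialect_divides_by_ten(self, tmp_path):
        (tmp_path / "w.csv").write_text(
            "date,temperature,precipitation\n2010-01-01,5,130\n2010-01-02,6,0\n"
        )
        w = read_weather(tmp_path / "w.csv",
                         WeatherDialect(precipitation_unit="tenths_mm"))
        assert w.precipitation[0] == pytest.approx(13.0)

    def test_missing_mandatory_column_named(self, tmp_path):
        (tmp_path / "w.csv").write_text("date,temperature\n2010-01-01,5\n")
        with pytest.raises(ValueError, match="precipitation"):
            read_weather(tmp_path / "w.csv")

    def test_three_day_gap_interpolated_and_reported(self, tmp_path, caplog):
        (tmp_path / "w.csv").write_text(
            "date,temperature,precipitation\n"
            "2010-01-01,0,0\n2010-01-05,8,0\n2010-01-06,10,2\n"
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="mosqspec"):
            w = read_weather(tmp_path / "w.csv")
        assert len(w) == 6
        np.testing.assert_allclose(w.temperature, [0, 2, 4, 6, 8, 10])
        assert any("3 missing day" in r.message for r in caplog.records)

    def test_humidity_bounds_enforced(self):
        with pytest.raises(ValueError, match="relative_humidity"):
            from mosqspec import WeatherSeries

            WeatherSeries(
                pd.date_range("2010-01-01", periods=2),
                temperature=[1.0, 2.0],
                precipitation=[0.0, 0.0],
                relative_humidity=[50.0, 140.0],
            )
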