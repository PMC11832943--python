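"""Climate departures, regional means, moisture index, season windows."""

import numpy as np
import pandas as pd
import pytest

from dendrotrend.climate import (
    ClimateError,
    SLOT_LABELS,
    moisture_index,
    regional_mean,
    season_window,
    standardize_station,
)
from dendrotrend.ringio import ClimateTable


def _table(values_by_ym, station="S1", variable="temperature"):
    idx = pd.MultiIndex.from_tuples(list(values_by_ym),
                                    names=["year", "month"])
    return ClimateTable(station, variable,
                        pd.Series(list(values_by_ym.values()), index=idx))


def _monthly_table(years, fn, station="S1", variable="temperature"):
    data = {(y, m): fn(y, m) for y in years for m in range(1, 13)}
    return _table(data, station, variable)


class TestStandardize:
    def test_z_score_formula(self):
        """Reference mean 10 and sd 2 turn a value of 12 into z = +1."""
        rng = np.random.default_rng(0)
        years = range(1991, 2021)
        raw = {(y, 1): v for y, v in zip(years, rng.normal(10, 2, 30))}
        raw[(2021, 1)] = 12.0
        tbl = _table(raw)
        dep = standardize_station(tbl, (1991, 2020))
        ref = np.array([raw[(y, 1)] for y in years])
        expect = (12.0 - ref.mean()) / ref.std(ddof=1)
        assert dep.at(2021, 1) == pytest.approx(expect)

    def test_reference_period_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        tbl = _monthly_table(range(1992, 2022),
                             lambda y, m: rng.normal(5 + m, 1 + 0.1 * m))
        dep = standardize_station(tbl, (1992, 2021))
        for m in (1, 6, 12):
            z = np.array([dep.at(y, m) for y in range(1992, 2022)])
            assert z.mean() == pytest.approx(0.0, abs=1e-10)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_gap_outside_reference_tolerated(self):
        rng = np.random.default_rng(2)
        data = {(y, m): rng.normal(10, 2)
                for y in range(1980, 2022) for m in range(1, 13)
                if y != 1985}
        dep = standardize_station(_table(data), (1992, 2021))
        assert np.isfinite(dep.at(1984, 3))
        assert np.isnan(dep.at(1985, 3))

    def test_affine_invariance(self):
        """Celsius-to-Fahrenheit rescaling leaves z-scores unchanged."""
        rng = np.random.default_rng(3)
        vals = {(y, m): rng.normal(8, 3)
                for y in range(1992, 2022) for m in range(1, 13)}
        a = standardize_station(_table(vals), (1992, 2021))
        f = {k: v * 9 / 5 + 32 for k, v in vals.items()}
        b = standardize_station(_table(f), (1992, 2021))
        pd.testing.assert_series_equal(a.values, b.values, atol=1e-10)

    def test_zero_sd_month_rejected(self):
        vals = {(y, m): (7.0 if m == 4 else float(y % 5))
                for y in range(1992, 2022) for m in range(1, 13)}
        with pytest.raises(ClimateError, match="month 4"):
            standardize_station(_table(vals), (1992, 2021))


class TestRegionalMean:
    @staticmethod
    def _dep(values_by_ym, station="S1"):
        tbl = _monthly_table(range(1992, 2022), values_by_ym, station=station)
        return standardize_station(tbl, (1992, 2021))

    def test_opposite_stations_cancel(self):
        from dendrotrend.climate import ClimateDeparture

        idx = pd.MultiIndex.from_tuples([(2000, 1)], names=["year", "month"])
        a = ClimateDeparture("temperature", pd.Series([1.0], index=idx),
                             (1992, 2021))
        b = ClimateDeparture("temperature", pd.Series([-1.0], index=idx),
                             (1992, 2021))
        out = regional_mean([a, b])
        assert out.values.iloc[0] == 0.0

    def test_single_station_identity(self):
        rng = np.random.default_rng(4)
        dep = self._dep(lambda y, m: rng.normal())
        out = regional_mean([dep])
        pd.testing.assert_series_equal(out.values, dep.values)

    def test_missing_month_uses_available_stations(self):
        from dendrotrend.climate import ClimateDeparture

        idx2 = pd.MultiIndex.from_tuples([(2000, 1), (2000, 2)],
                                         names=["year", "month"])
        idx1 = pd.MultiIndex.from_tuples([(2000, 1)],
                                         names=["year", "month"])
        full = ClimateDeparture("temperature",
                                pd.Series([1.0, 2.0], index=idx2),
                                (1992, 2021))
        partial = ClimateDeparture("temperature",
                                   pd.Series([3.0], index=idx1),
                                   (1992, 2021))
        out = regional_mean([full, full, partial])
        assert out.values.loc[(2000, 1)] == pytest.approx(5 / 3)
        assert out.values.loc[(2000, 2)] == pytest.approx(2.0)
        assert out.n_stations.loc[(2000, 2)] == 2


class TestMoistureIndex:
    @staticmethod
    def _dep(z, variable):
        from dendrotrend.climate import ClimateDeparture

        idx = pd.MultiIndex.from_tuples([(2000, 1)], names=["year", "month"])
        return ClimateDeparture(variable, pd.Series([z], index=idx),
                                (1992, 2021))

    @pytest.mark.parametrize("p,t,expect", [(1.0, -1.0, 2.0),
                                            (0.0, 0.0, 0.0),
                                            (-1.0, 1.0, -2.0)])
    def test_forced_values(self, p, t, expect):
        mi = moisture_index(self._dep(t, "temperature"),
                            self._dep(p, "precipitation"))
        assert mi.values.iloc[0] == pytest.approx(expect)

    def test_antisymmetry_under_role_swap(self):
        rng = np.random.default_rng(6)
        idx = pd.MultiIndex.from_product([range(2000, 2010), range(1, 13)],
                                         names=["year", "month"])
        from dendrotrend.climate import ClimateDeparture

        a = ClimateDeparture("temperature",
                             pd.Series(rng.normal(size=120), index=idx),
                             (1992, 2021))
        b = ClimateDeparture("precipitation",
                             pd.Series(rng.normal(size=120), index=idx),
                             (1992, 2021))
        fwd = moisture_index(a, b).values
        swapped = moisture_index(
            ClimateDeparture("temperature", b.values, (1992, 2021)),
            ClimateDeparture("precipitation", a.values, (1992, 2021)),
        ).values
        pd.testing.assert_series_equal(fwd, -swapped)


class TestSeasonWindow:
    def test_enumeration_for_growth_year_2000(self):
        """A ring labeled 2000 integrates Oct 1998 through Apr 2000."""
        win = season_window(2000)
        cal = win.calendar()
        assert len(cal) == 19
        assert cal[0] == (1998, 10)
        assert cal[2] == (1998, 12)
        assert cal[3] == (1999, 1)
        assert cal[14] == (1999, 12)
        assert cal[-1] == (2000, 4)
        assert len(set(cal)) == 19

    def test_consecutive_windows_overlap_seven_months(self):
        a = set(season_window(2000).calendar())
        b = set(season_window(2001).calendar())
        assert len(a & b) == 7

    def test_slot_labels_partition(self):
        assert len(SLOT_LABELS) == 19
        assert sum(1 for s in SLOT_LABELS if s.startswith("prev.")) == 7
        assert sum(1 for s in SLOT_LABELS if s.startswith("win.")) == 5
        assert sum(1 for s in SLOT_LABELS if s.startswith("cur.")) == 7
        assert SLOT_LABELS[0] == "prev.Oct" and SLOT_LABELS[-1] == "cur.Apr"
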