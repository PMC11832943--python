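"""Ring-width and tabular input/output."""

import io

import numpy as np
import pytest

from dendrotrend.ringio import (
    ClimateTable,
    RingIOError,
    RingSeries,
    TreeRecord,
    merge_cores_to_tree,
    read_climate,
    read_rings_csv,
    read_rwl,
    read_tree_metadata,
    write_rings_csv,
    write_rwl,
)


class TestRwl:
    def test_round_trip_two_series(self, tmp_path):
        """Values survive a Tucson write/read cycle exactly (0.01 mm grid)."""
        s1 = RingSeries("AAA1a", "AAA1", 1987, np.array([1.23, 0.5, 2.0, 1.11]))
        s2 = RingSeries("AAA2a", "AAA2", 1765,
                        np.round(np.linspace(0.2, 3.0, 57), 2))
        path = tmp_path / "toy.rwl"
        write_rwl([s1, s2], path)
        back = {s.series_id: s for s in read_rwl(path)}
        for s in (s1, s2):
            got = back[s.series_id]
            assert got.first_year == s.first_year
            np.testing.assert_allclose(got.widths, s.widths)

    def test_decade_line_assigns_years(self):
        """A line stamped 1990 with 10 values covers 1990-1999."""
        text = "TST1    1990   100   110   120   130   140   150   160   170   180   190\nTST1    2000   200   999\n"
        series = read_rwl(io.StringIO(text))
        assert len(series) == 1
        s = series[0]
        assert s.first_year == 1990 and s.last_year == 2000
        np.testing.assert_allclose(s.widths[:3], [1.0, 1.1, 1.2])

    def test_decade_jump_is_error(self):
        text = "TST1    1990   100   110\nTST1    2010   120   999\n"
        with pytest.raises(RingIOError, match="jumps"):
            read_rwl(io.StringIO(text))

    def test_duplicate_series_id_is_error(self):
        text = (
            "TST1    1990   100   999\n"
            "TST1    1990   100   999\n"
        )
        with pytest.raises(RingIOError):
            read_rwl(io.StringIO(text))

    def test_minus9999_terminator_dialect(self):
        text = "TST1    1990   100   110 -9999\n"
        (s,) = read_rwl(io.StringIO(text))
        assert len(s) == 2

    def test_rings_csv_round_trip(self, tmp_path, toy_series):
        path = tmp_path / "rings.csv"
        write_rings_csv([toy_series], path)
        (back,) = read_rings_csv(path)
        assert back.first_year == toy_series.first_year
        np.testing.assert_allclose(back.widths, toy_series.widths)


class TestMergeCores:
    def test_mean_of_mirrored_cores(self):
        a = RingSeries("T1a", "T1", 2000, [1.0, 2.0, 3.0])
        b = RingSeries("T1b", "T1", 2000, [3.0, 2.0, 1.0])
        merged = merge_cores_to_tree([a, b])
        np.testing.assert_allclose(merged.widths, [2.0, 2.0, 2.0])

    def test_single_core_identity(self):
        a = RingSeries("T1a", "T1", 2000, [1.0, 2.0])
        merged = merge_cores_to_tree([a])
        np.testing.assert_allclose(merged.widths, a.widths)

    def test_offset_cores_mean_on_overlap_flanks_single(self):
        """Cores offset by 2 years: union span, means where both exist."""
        a = RingSeries("T1a", "T1", 2000, [1.0, 1.0, 1.0, 1.0])  # 2000-2003
        b = RingSeries("T1b", "T1", 2002, [3.0, 3.0, 3.0, 3.0])  # 2002-2005
        merged = merge_cores_to_tree([a, b])
        assert merged.first_year == 2000 and merged.last_year == 2005
        np.testing.assert_allclose(merged.widths,
                                   [1.0, 1.0, 2.0, 2.0, 3.0, 3.0])

    def test_order_invariance(self):
        a = RingSeries("T1a", "T1", 2000, [1.0, 2.0, 3.0])
        b = RingSeries("T1b", "T1", 2001, [4.0, 5.0, 6.0])
        m1 = merge_cores_to_tree([a, b])
        m2 = merge_cores_to_tree([b, a])
        np.testing.assert_allclose(m1.widths, m2.widths)

    def test_empty_input_error(self):
        with pytest.raises(RingIOError):
            merge_cores_to_tree([])

    def test_mixed_trees_error(self):
        a = RingSeries("T1a", "T1", 2000, [1.0, 2.0])
        b = RingSeries("T2a", "T2", 2000, [1.0, 2.0])
        with pytest.raises(RingIOError, match="different trees"):
            merge_cores_to_tree([a, b])


class TestTables:
    def test_metadata_round_trip(self, tmp_path):
        path = tmp_path / "trees.csv"
        path.write_text(
            "tree_id,dbh_mm,height_m,crown_damage_pct,neighbors\n"
            "T1,300,11.5,35,250/2.5;410/3.1\n"
            "T2,410,12.0,5,\n"
            "T3,520,10.1,95,100/1.0\n"
        )
        recs = read_tree_metadata(path)
        assert len(recs) == 3
        assert recs[0].neighbors == [(250.0, 2.5), (410.0, 3.1)]
        assert recs[1].neighbors == []  # empty field, no error
        assert recs[2].crown_damage == 95.0

    def test_damage_out_of_bounds(self, tmp_path):
        path = tmp_path / "trees.csv"
        path.write_text(
            "tree_id,dbh_mm,height_m,crown_damage_pct,neighbors\n"
            "T1,300,11.5,101,\n"
        )
        with pytest.raises(RingIOError, match="crown_damage"):
            read_tree_metadata(path)

    def test_negative_precipitation_rejected(self, tmp_path):
        path = tmp_path / "climate.csv"
        path.write_text(
            "station_id,variable,year,month,value\n"
            "P1,precipitation,2000,1,-3\n"
        )
        with pytest.raises(RingIOError, match="negative precipitation"):
            read_climate(path)

    def test_climate_reader_types(self, tmp_path):
        path = tmp_path / "climate.csv"
        path.write_text(
            "station_id,variable,year,month,value\n"
            "S1,temperature,2000,1,15.5\n"
            "S1,temperature,2000,2,14.0\n"
            "P1,precipitation,2000,1,80\n"
        )
        tables = read_climate(path)
        assert {t.station_id for t in tables} == {"S1", "P1"}
        t = next(t for t in tables if t.station_id == "S1")
        assert t.values.loc[(2000, 2)] == 14.0

    def test_duplicate_month_rejected(self):
        import pandas as pd

        idx = pd.MultiIndex.from_tuples([(2000, 1), (2000, 1)],
                                        names=["year", "month"])
        with pytest.raises(RingIOError, match="duplicate"):
            ClimateTable("S1", "temperature", pd.Series([1.0, 2.0], index=idx))

    def test_tree_record_validation(self):
        with pytest.raises(RingIOError):
            TreeRecord("T1", dbh=-5, height=10, crown_damage=10)
        with pytest.raises(RingIOError):
            TreeRecord("T1", dbh=300, height=10, crown_damage=10,
                       neighbors=[(200.0, 0.0)])
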