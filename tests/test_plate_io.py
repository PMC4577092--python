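"""Plate I/O: round-trips, validation diagnostics, dilution arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fpscreen.plate_io import (
    AssayMeta,
    ROWS,
    ScreenFormatError,
    ScreenTable,
    ScreenValidationError,
    WellRecord,
    dilute,
    fp_from_channels,
    parse_well,
    read_screen,
    well_name,
    write_screen,
)


def make_plate(plate_id="P01", n_samples=352):
    """A full 384-well plate: controls in columns 1/24, samples elsewhere."""
    recs = []
    for r in ROWS:
        recs.append(WellRecord(plate_id, r, 1, "", "neg_control", 200.0, 1e4, 0.0))
        recs.append(WellRecord(plate_id, r, 24, "", "pos_control", 80.0, 1e4, 0.0))
    k = 0
    for c in range(2, 24):
        for r in ROWS:
            if k >= n_samples:
                break
            recs.append(
                WellRecord(plate_id, r, c, f"C{k:04d}", "sample", 170.0 + k % 7,
                           1e4, 10.0)
            )
            k += 1
    return recs


class TestWellCoordinates:
    def test_serialization_convention(self):
        assert well_name("A", 1) == "A01"
        assert parse_well("a1") == ("A", 1)
        assert parse_well("P24") == ("P", 24)

    @pytest.mark.parametrize("bad", ["Q01", "A00", "A25", "1A", ""])
    def test_out_of_bounds_rejected(self, bad):
        with pytest.raises(ScreenValidationError):
            parse_well(bad)


class TestScreenTable:
    def test_full_plate_identity(self, tmp_path):
        table = ScreenTable.from_records(make_plate())
        assert len(table.df) == 384
        table.check_control_minima()

    def test_duplicate_well_reported(self):
        recs = make_plate()
        recs.append(recs[-1])
        with pytest.raises(ScreenValidationError, match="duplicate"):
            ScreenTable.from_records(recs)

    def test_sample_requires_compound_id(self):
        recs = [WellRecord("P01", "A", 2, "", "sample", 170.0, 1e4, 10.0)]
        with pytest.raises(ScreenValidationError, match="compound_id"):
            ScreenTable.from_records(recs)

    def test_control_must_not_carry_compound(self):
        recs = [WellRecord("P01", "A", 1, "CMP1", "neg_control", 200.0, 1e4, 0.0)]
        with pytest.raises(ScreenValidationError):
            ScreenTable.from_records(recs)

    def test_sample_count_conserved_across_plates(self, tmp_path):
        recs = []
        per_plate = [352, 352, 352, 352, 189]
        k = 0
        for pi, n in enumerate(per_plate, 1):
            plate = make_plate(f"P{pi:02d}", n_samples=0)
            recs += plate
            for c in range(2, 24):
                for r in ROWS:
                    if n == 0:
                        break
                    recs.append(
                        WellRecord(f"P{pi:02d}", r, c, f"CMPD{k:05d}", "sample",
                                   171.0, 1e4, 10.0)
                    )
                    k += 1
                    n -= 1
        table = ScreenTable.from_records(recs)
        path = write_screen(table, tmp_path / "screen.csv")
        back = read_screen(path)
        assert (back.df["role"] == "sample").sum() == 1597


class TestReadWrite:
    def test_round_trip_bitwise(self, tmp_path, small_sim):
        _, screen, _ = small_sim
        p1 = write_screen(screen, tmp_path / "a.csv")
        back = read_screen(p1)
        pd.testing.assert_frame_equal(screen.df, back.df)
        p2 = write_screen(back, tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()

    @given(
        fp=st.lists(
            st.floats(-200, 400, allow_nan=False, allow_infinity=False,
                      width=64),
            min_size=4, max_size=24,
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_round_trip_random_tables(self, tmp_path_factory, fp):
        recs = [
            WellRecord("P01", ROWS[i % 16], 2 + i // 16, f"C{i}", "sample",
                       v, abs(v) + 1.0, 10.0)
            for i, v in enumerate(fp)
        ]
        recs += make_plate(n_samples=0)
        table = ScreenTable.from_records(recs)
        path = tmp_path_factory.mktemp("rt") / "t.csv"
        write_screen(table, path)
        back = read_screen(path)
        pd.testing.assert_frame_equal(table.df, back.df)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("plate_id,well,fp_mP\nP01,A01,170\n")
        with pytest.raises(ScreenFormatError, match="missing"):
            read_screen(p)

    def test_non_numeric_fp_names_the_cell(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "plate_id,well,compound_id,role,fp_mP,total_intensity,compound_conc_uM\n"
            "P01,A02,C1,sample,oops,10000,10\n"
        )
        with pytest.raises(ScreenValidationError, match=r"line 2.*fp_mP"):
            read_screen(p)

    def test_roles_merged_from_plate_map(self, tmp_path):
        data = tmp_path / "data.csv"
        data.write_text(
            "plate_id,well,fp_mP,total_intensity\n"
            "P01,A01,200,10000\nP01,A02,205,10000\n"
            "P01,B01,95,10000\nP01,B02,100,10000\n"
            "P01,C01,170,10000\n"
        )
        layout = tmp_path / "map.csv"
        layout.write_text(
            "plate_id,well,role,compound_id\n"
            "P01,A01,neg_control,\nP01,A02,neg_control,\n"
            "P01,B01,pos_control,\nP01,B02,pos_control,\n"
            "P01,C01,sample,CMP1\n"
        )
        table = read_screen(data, layout=layout)
        assert (table.df["role"] == "sample").sum() == 1
        assert set(table.df["compound_conc_uM"]) == {0.0, 10.0}


class TestDilution:
    def test_screen_dose_arithmetic(self):
        # 5 µL of 50 µM stock into 20 µL assay mixture -> 10 µM final
        assert dilute(50, 5, 20) == pytest.approx(10.0)

    def test_no_diluent_and_hundredfold(self):
        assert dilute(42.0, 3.0, 0.0) == pytest.approx(42.0)
        assert dilute(100, 1, 99) == pytest.approx(1.0)

    @pytest.mark.parametrize("args", [(50, 0, 20), (50, -1, 20), (50, 5, -2)])
    def test_nonpositive_volumes_rejected(self, args):
        with pytest.raises(ValueError):
            dilute(*args)

    @given(
        c=st.floats(0.01, 1e4), v=st.floats(0.01, 1e3), a=st.floats(0, 1e3),
        k=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_homogeneity_and_volume_scale_invariance(self, c, v, a, k):
        assert dilute(k * c, v, a) == pytest.approx(k * dilute(c, v, a), rel=1e-12)
        assert dilute(c, k * v, k * a) == pytest.approx(dilute(c, v, a), rel=1e-12)


class TestChannelPolarization:
    def test_pure_parallel_light(self):
        assert fp_from_channels(100.0, 0.0) == pytest.approx(1000.0)

    def test_depolarized_light_reads_zero(self):
        assert fp_from_channels(50.0, 50.0) == pytest.approx(0.0)

    def test_g_factor_correction(self):
        # with G = 2 the perpendicular channel counts double
        assert fp_from_channels(100.0, 50.0, g_factor=2.0) == pytest.approx(0.0)
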