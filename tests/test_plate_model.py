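import numpy as np
import pandas as pd
import pytest

from calscreen import (
    PlateLayout,
    WellAssignment,
    WellTrace,
    generate_screen,
    pair_plates,
    read_dataset,
    read_layout,
    read_traces,
    write_dataset,
    write_layout,
    write_traces,
)
from calscreen.errors import DataError, FormatError, PairingError, ParseError
from calscreen.plate_model import rowcol_to_well, well_to_rowcol


def _trace_csv(tmp_path, rows, name="traces.csv"):
    path = tmp_path / name
    path.write_text("plate,well,time_s,fluorescence\n" + "\n".join(rows) + "\n")
    return path


def _mk_trace(plate, well, n=12, value=100.0):
    t = np.arange(n) * 2.0
    return WellTrace(plate, well, t, np.full(n, value))


class TestWellIds:
    @pytest.mark.parametrize(
        "well,rowcol",
        [("A1", (0, 0)), ("H12", (7, 11)), ("Z48", (25, 47)), ("AA1", (26, 0)), ("AF48", (31, 47))],
    )
    def test_round_trip(self, well, rowcol):
        assert well_to_rowcol(well) == rowcol
        assert rowcol_to_well(*rowcol) == well

    def test_malformed_id_rejected(self):
        with pytest.raises(FormatError):
            well_to_rowcol("42")


class TestReadTraces:
    def test_long_format_groups_wells(self, tmp_path):
        rows = [
            f"P1,{well},{t},{100 + t}"
            for well in ("A1", "A2", "B1")
            for t in range(0, 20, 2)
        ]
        traces = read_traces(_trace_csv(tmp_path, rows))
        assert len(traces) == 3
        assert all(len(tr) == 10 for tr in traces)

    def test_row_order_irrelevant(self, tmp_path):
        rows = [f"P1,A1,{t},{100 + t}" for t in range(0, 20, 2)]
        rows += [f"P1,A2,{t},{200 + t}" for t in range(0, 20, 2)]
        shuffled = list(reversed(rows))
        a = read_traces(_trace_csv(tmp_path, rows, "a.csv"))
        b = read_traces(_trace_csv(tmp_path, shuffled, "b.csv"))
        assert a == b

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("plate,well,fluorescence\nP1,A1,1\n")
        with pytest.raises(FormatError, match="time_s"):
            read_traces(path)

    def test_non_numeric_cites_line(self, tmp_path):
        rows = [f"P1,A1,{t},{100 + t}" for t in range(0, 20, 2)]
        rows[4] = "P1,A1,NA,108"
        with pytest.raises(ParseError, match="line 6"):
            read_traces(_trace_csv(tmp_path, rows))

    def test_duplicate_sample_rejected(self, tmp_path):
        rows = [f"P1,A1,{t},{100 + t}" for t in range(0, 20, 2)] + ["P1,A1,0,99"]
        with pytest.raises(DataError, match="duplicate"):
            read_traces(_trace_csv(tmp_path, rows))

    def test_wide_dialect(self, tmp_path):
        path = tmp_path / "wide.csv"
        t = np.arange(0, 24, 2)
        df = pd.DataFrame({"time_s": t, "A1": 100 + t, "A2": 200 + t})
        df.to_csv(path, index=False)
        traces = read_traces(path, dialect="wide", plate_id="P9")
        assert {tr.well_id for tr in traces} == {"A1", "A2"}
        assert traces[0].plate_id == "P9"


class TestWellTraceInvariants:
    def test_too_short_rejected(self):
        with pytest.raises(DataError, match=">= 10"):
            WellTrace("P", "A1", np.arange(5.0), np.ones(5))

    def test_non_monotone_time_rejected(self):
        t = np.arange(12.0)
        t[5] = t[4]
        with pytest.raises(DataError, match="increasing"):
            WellTrace("P", "A1", t, np.ones(12))

    def test_non_finite_rejected(self):
        f = np.ones(12)
        f[3] = np.nan
        with pytest.raises(DataError, match="finite"):
            WellTrace("P", "A1", np.arange(12.0), f)


class TestLayout:
    def test_default_1536_role_counts(self, small_screen):
        dataset, _ = small_screen
        layout = dataset.plate_pairs[0].layout_a
        counts = layout.role_counts()
        assert counts["agonist_control"] == 192
        assert counts["buffer_control"] == 64

    def test_unknown_role_rejected(self):
        with pytest.raises(FormatError, match="blank"):
            PlateLayout(
                plate_id="P",
                format="well96",
                agonist="CRP",
                duplicate_tag="A",
                injection_time_s=60.0,
                wells={"A1": WellAssignment(role="blank")},
            )

    def test_compound_without_id_rejected(self):
        with pytest.raises(DataError, match="compound_id"):
            PlateLayout(
                plate_id="P",
                format="well96",
                agonist="CRP",
                duplicate_tag="A",
                injection_time_s=60.0,
                wells={"A1": WellAssignment(role="compound")},
            )

    def test_96_well_duplicate_conditions_valid(self):
        wells = {
            "A1": WellAssignment(role="agonist_control"),
            "A2": WellAssignment(role="agonist_control"),
            "B1": WellAssignment(role="compound", compound_id="X", concentration_um=10.0),
            "B2": WellAssignment(role="compound", compound_id="X", concentration_um=10.0),
        }
        layout = PlateLayout("P", "well96", "thrombin", "A", 30.0, wells)
        assert layout.role_counts()["compound"] == 2

    def test_layout_round_trip(self, tmp_path):
        wells = {
            "A1": WellAssignment(role="agonist_control"),
            "B1": WellAssignment(role="compound", compound_id="X", concentration_um=10.0),
        }
        layout = PlateLayout("P-A", "well96", "CRP", "A", 45.0, wells)
        write_layout(layout, tmp_path / "l.csv")
        back = read_layout(tmp_path / "l.csv")
        assert back.wells == layout.wells
        assert back.agonist == "CRP" and back.injection_time_s == 45.0


class TestPairing:
    def _layout(self, tag, compound="X", well="B1"):
        wells = {
            well: WellAssignment(role="compound", compound_id=compound, concentration_um=10.0),
        }
        return PlateLayout(f"S1-{tag}", "well96", "CRP", tag, 10.0, wells)

    def test_pair_formed(self):
        la, lb = self._layout("A"), self._layout("B")
        ta = {"B1": _mk_trace("S1-A", "B1")}
        tb = {"B1": _mk_trace("S1-B", "B1")}
        ds = pair_plates([(la, ta), (lb, tb)])
        assert len(ds.plate_pairs) == 1
        assert ds.plate_pairs[0].compound_ids() == ["X"]

    def test_orphan_reported(self):
        la = self._layout("A")
        with pytest.raises(PairingError, match="unpaired"):
            pair_plates([(la, {"B1": _mk_trace("S1-A", "B1")})])

    def test_placement_mismatch_names_well(self):
        la, lb = self._layout("A", "X"), self._layout("B", "Y")
        with pytest.raises(DataError, match="B1"):
            pair_plates(
                [
                    (la, {"B1": _mk_trace("S1-A", "B1")}),
                    (lb, {"B1": _mk_trace("S1-B", "B1")}),
                ]
            )

    def test_trace_well_missing_from_layout(self):
        la = self._layout("A")
        with pytest.raises(DataError, match="C1"):
            pair_plates([(la, {"C1": _mk_trace("S1-A", "C1")})])


class TestDatasetRoundTrip:
    def test_round_trip_preserves_values_and_roles(self, tmp_path, small_screen):
        dataset, _ = small_screen
        manifest = write_dataset(dataset, tmp_path / "ds")
        back = read_dataset(manifest)
        assert len(back.plate_pairs) == len(dataset.plate_pairs)
        for orig, rt in zip(dataset.plate_pairs, back.plate_pairs):
            assert orig.layout_a.role_counts() == rt.layout_a.role_counts()
            well = sorted(orig.traces_a)[0]
            np.testing.assert_array_equal(
                orig.traces_a[well].fluorescence_au, rt.traces_a[well].fluorescence_au
            )

    def test_manifest_missing_file_named(self, tmp_path, small_screen):
        dataset, _ = small_screen
        manifest = write_dataset(dataset, tmp_path / "ds")
        victim = next((tmp_path / "ds").glob("*.traces.csv"))
        victim.unlink()
        with pytest.raises(FileNotFoundError, match=victim.name):
            read_dataset(manifest)
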