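import io
import warnings

import numpy as np
import pandas as pd
import pytest

import inktqsar as iq
from inktqsar.dataset import LITERATURE_ASSAY_COUNTS, ResponseTableError

REF = "CPD-001"

CSV_HEADER = ("compound_id,study_id,species,setting,presentation,marker,"
              "dose,dose_unit,time,time_unit,value\n")


def _records(rows):
    """Minimal record frame for normalization tests."""
    return pd.DataFrame(rows, columns=[
        "compound_id", "study_id", "test_system", "marker", "dose", "time",
        "value"])


class TestReadResponseTable:
    def test_well_formed_file(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(CSV_HEADER
                        + "CPD-001,S1,mice,in-vivo,,il4,1,ug/kg,24,h,10\n"
                        + "CPD-002,S1,Mouse,in vivo,,IFN-gamma,1,ug/kg,24,h,20\n"
                        + "CPD-003,S1,human,in-vitro,cell-cell,IL-13,1,ng/mL,24,h,5\n",
                        encoding="utf-8")
        records = iq.read_response_table(path)
        assert len(records) == 3
        assert records.loc[0, "marker"] == "IL-4"
        assert records.loc[1, "marker"] == "IFN-γ"
        assert records.loc[1, "test_system"] == "mice/in-vivo"
        assert records.loc[2, "test_system"] == "human/in-vitro/cell-cell"

    def test_non_numeric_value_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(CSV_HEADER
                        + "CPD-001,S1,mice,in-vivo,,IL-4,1,u,24,h,10\n"
                        + "CPD-002,S1,mice,in-vivo,,IL-4,1,u,24,h,NA\n",
                        encoding="utf-8")
        with pytest.raises(ResponseTableError, match="line 3"):
            iq.read_response_table(path)

    def test_unknown_marker_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(CSV_HEADER
                        + "CPD-001,S1,mice,in-vivo,,TNF,1,u,24,h,10\n",
                        encoding="utf-8")
        with pytest.raises(ResponseTableError, match="line 2.*TNF"):
            iq.read_response_table(path)

    def test_missing_column_rejected(self):
        with pytest.raises(ResponseTableError, match="missing columns"):
            iq.read_response_table(io.StringIO("compound_id,value\nA,1\n"))


class TestReferenceConditionSelection:
    def _study(self, values_by_dose):
        return _records([(REF, "S1", "mice/in-vivo", "IFN-γ", d, 24.0, v)
                         for d, v in values_by_dose.items()])

    def test_single_condition(self):
        rec = self._study({1.0: 10.0})
        assert iq.select_reference_condition(
            rec, ("mice/in-vivo", "IFN-γ"), "S1", REF) == (1.0, 24.0)

    def test_argmax_over_doses(self):
        rec = self._study({0.1: 10.0, 1.0: 50.0, 10.0: 30.0})
        assert iq.select_reference_condition(
            rec, ("mice/in-vivo", "IFN-γ"), "S1", REF)[0] == 1.0

    def test_tie_breaks_to_lowest_dose(self):
        rec = self._study({0.1: 50.0, 1.0: 50.0, 10.0: 20.0})
        assert iq.select_reference_condition(
            rec, ("mice/in-vivo", "IFN-γ"), "S1", REF)[0] == 0.1

    def test_missing_reference_raises(self):
        rec = _records([("CPD-002", "S1", "mice/in-vivo", "IFN-γ", 1.0, 24.0, 5.0)])
        with pytest.raises(KeyError):
            iq.select_reference_condition(rec, ("mice/in-vivo", "IFN-γ"), "S1", REF)


class TestNormalization:
    def test_ratio_arithmetic(self):
        rec = _records([
            (REF, "S1", "mice/in-vivo", "IFN-γ", 1.0, 24.0, 125.0),
            ("CPD-002", "S1", "mice/in-vivo", "IFN-γ", 1.0, 24.0, 250.0),
            ("CPD-003", "S1", "mice/in-vivo", "IFN-γ", 1.0, 24.0, 0.0)])
        out = iq.normalize_to_reference(rec, REF).set_index("compound_id")
        assert out.loc["CPD-002", "normalized"] == 2.0
        assert out.loc[REF, "normalized"] == 1.0
        assert out.loc["CPD-003", "normalized"] == 0.0

    def test_off_condition_records_excluded(self):
        rec = _records([
            (REF, "S1", "mice/in-vivo", "IFN-γ", 1.0, 24.0, 100.0),
            (REF, "S1", "mice/in-vivo", "IFN-γ", 10.0, 24.0, 40.0),
            ("CPD-002", "S1", "mice/in-vivo", "IFN-γ", 10.0, 24.0, 400.0)])
        out = iq.normalize_to_reference(rec, REF)
        # analogue only measured at the non-selected dose: dropped
        assert set(out["compound_id"]) == {REF}

    def test_zero_reference_dropped_with_warning(self):
        rec = _records([
            (REF, "S1", "mice/in-vivo", "IFN-γ", 1.0, 24.0, 0.0),
            ("CPD-002", "S1", "mice/in-vivo", "IFN-γ", 1.0, 24.0, 10.0)])
        with pytest.warns(UserWarning, match="reference response 0"):
            out = iq.normalize_to_reference(rec, REF)
        assert out.empty

    def test_idempotence_on_normalized_table(self):
        rec = _records([
            (REF, "S1", "mice/in-vivo", "IFN-γ", 1.0, 24.0, 1.0),
            ("CPD-002", "S1", "mice/in-vivo", "IFN-γ", 1.0, 24.0, 2.5),
            ("CPD-003", "S1", "mice/in-vivo", "IFN-γ", 1.0, 24.0, 0.4)])
        once = iq.normalize_to_reference(rec, REF)
        again = rec.copy()
        again["value"] = once.set_index("compound_id").loc[
            again["compound_id"], "normalized"].to_numpy()
        twice = iq.normalize_to_reference(again, REF)
        pd.testing.assert_series_equal(once["normalized"], twice["normalized"])


class TestAggregation:
    def test_mean_of_two_studies(self):
        norm = pd.DataFrame({
            "compound_id": ["A", "A", REF, REF],
            "study_id": ["S1", "S2", "S1", "S2"],
            "test_system": "mice/in-vivo", "marker": "IFN-γ",
            "dose": 1.0, "time": 24.0,
            "normalized": [1.0, 3.0, 1.0, 1.0]})
        matrix = iq.aggregate_replicates(norm, REF)
        assert matrix.cell("mice/in-vivo", "IFN-γ")["A"] == 2.0
        assert matrix.n_sources[("mice/in-vivo", "IFN-γ")]["A"] == 2

    def test_permutation_invariance(self, normalized_small):
        shuffled = normalized_small.sample(frac=1.0, random_state=0)
        a = iq.aggregate_replicates(normalized_small, REF)
        b = iq.aggregate_replicates(shuffled, REF)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_reference_is_unity_everywhere(self, matrix_small):
        ref_row = matrix_small.values.loc[REF].dropna()
        assert np.allclose(ref_row, 1.0)


class TestFrequencies:
    def test_literature_counts_reproduce_published_shares(self):
        table = iq.summarize_frequencies(LITERATURE_ASSAY_COUNTS)
        assert table.attrs["grand_total"] == 851
        shares = table.attrs["test_model_percent"]
        assert shares["human/in-vitro/cell-cell"] == 34.31
        assert shares["mice/in-vitro/cell-cell"] == 28.67
        assert shares["mice/in-vivo"] == 27.85
        cell = table.set_index(["test_system", "marker"])["percent"]
        assert cell[("mice/in-vitro/cell-cell", "IL-2")] == 10.22
        assert cell[("human/in-vitro/cell-cell", "IL-13")] == 6.58

    def test_percentages_sum_to_100(self, matrix_small):
        table = iq.summarize_frequencies(matrix_small)
        assert abs(table["percent"].sum() - 100.0) <= 0.05

    def test_single_record_is_100_percent(self):
        table = iq.summarize_frequencies({("mice/in-vivo", "IL-4"): 1})
        assert table.loc[0, "percent"] == 100.00

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            iq.summarize_frequencies({})
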