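"""Per-slice readouts, duplicate averaging, cohort matrices, Evans grading."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from slicequant.readouts import (
    DataError,
    MorphologyGrouping,
    average_duplicates,
    classify_group,
    cohort_matrix,
    compute_slice_readouts,
    evans_grade,
    slice_readouts,
    tumor_viability_index,
)
from conftest import make_slice_records


class TestClassifyGroup:
    @pytest.mark.parametrize(
        "cls, group",
        [
            ("flat", "viable"),
            ("cubic", "viable"),
            ("cylindrical", "viable"),
            ("clear", "viable"),
            ("swollen", "damaged"),
            ("necro_apoptotic", "damaged"),
        ],
    )
    def test_grouping(self, cls, group):
        assert classify_group(cls) == group

    def test_non_morphology_rejected(self):
        with pytest.raises(ValueError):
            classify_group("perimeter")

    def test_weights_must_be_positive(self):
        with pytest.raises(ValueError):
            MorphologyGrouping(weights={"viable": 0.0, "damaged": 1.0})


class TestTumorViabilityIndex:
    @pytest.mark.parametrize(
        "viable, damaged, expected",
        [(100.0, 0.0, 300.0), (0.0, 0.0, 0.0), (50.0, 10.0, 160.0), (0.0, 40.0, 40.0)],
    )
    def test_values(self, viable, damaged, expected):
        assert tumor_viability_index(viable, damaged) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tumor_viability_index(-1.0, 0.0)

    def test_exceeding_perimeter_rejected(self):
        with pytest.raises(ValueError):
            tumor_viability_index(80.0, 30.0)

    @given(
        v1=st.floats(0, 30), d1=st.floats(0, 20), v2=st.floats(0, 30), d2=st.floats(0, 20)
    )
    def test_linearity_and_bounds(self, v1, d1, v2, d2):
        a = tumor_viability_index(v1, d1)
        b = tumor_viability_index(v2, d2)
        assert tumor_viability_index(v1 + v2, d1 + d2) == pytest.approx(a + b, abs=1e-9)
        out = v1 + d1
        assert out - 1e-9 <= a <= 3 * out + 1e-9


class TestSliceReadouts:
    def test_worked_outgrowth_example(self):
        records = make_slice_records(perimeter=10_000, flat=2_000, swollen=1_000)
        r = slice_readouts(records)
        assert r.outgrowth_pct == pytest.approx(30.0)
        assert r.viable_len_pct == pytest.approx(20.0)
        assert r.damaged_len_pct == pytest.approx(10.0)
        assert r.tvi == pytest.approx(70.0)
        assert r.viability_pct == pytest.approx(100 * 2 / 3)
        assert r.mode == "outgrowth"

    def test_area_mode(self):
        records = pd.DataFrame(
            [
                dict(culture_id="DT2", slice_id="s1", replicate=1, condition="se5",
                     annotation_class="tumor_viable_area", measure_kind="area",
                     value=9_000.0, unit="um2"),
                dict(culture_id="DT2", slice_id="s1", replicate=1, condition="se5",
                     annotation_class="tumor_damaged_area", measure_kind="area",
                     value=1_000.0, unit="um2"),
            ]
        )
        r = slice_readouts(records)
        assert r.viability_pct == pytest.approx(90.0)
        assert math.isnan(r.tvi)
        assert r.mode == "area"

    def test_zero_outgrowth_degenerate(self, caplog):
        records = make_slice_records(perimeter=10_000)
        with caplog.at_level("WARNING"):
            r = slice_readouts(records)
        assert r.outgrowth_pct == 0.0
        assert r.tvi == 0.0
        assert math.isnan(r.viability_pct)

    def test_missing_perimeter_is_data_error(self):
        records = make_slice_records(perimeter=10_000, flat=100)
        with pytest.raises(DataError):
            slice_readouts(records[records["measure_kind"] != "perimeter"])

    def test_record_order_irrelevant(self, rng):
        records = make_slice_records(
            perimeter=12_345, flat=2_000, cubic=321, clear=77, swollen=1_000,
            necro_apoptotic=11,
        )
        shuffled = records.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a, b = slice_readouts(records), slice_readouts(shuffled)
        assert a.tvi == b.tvi and a.viability_pct == b.viability_pct

    def test_disjoint_annotations_of_one_class_summed(self):
        records = make_slice_records(perimeter=10_000, flat=1_000)
        extra = records[records["annotation_class"] == "flat"].copy()
        r = slice_readouts(pd.concat([records, extra], ignore_index=True))
        assert r.viable_len_pct == pytest.approx(20.0)

    def test_custom_weights(self):
        grouping = MorphologyGrouping(weights={"viable": 2.0, "damaged": 0.5})
        r = slice_readouts(
            make_slice_records(perimeter=10_000, flat=2_000, swollen=1_000), grouping
        )
        assert r.tvi == pytest.approx(2 * 20 + 0.5 * 10)


class TestAveragingAndMatrices:
    def _slices(self, viabilities, culture="DT1", condition="se5"):
        return pd.DataFrame(
            {
                "culture_id": culture,
                "condition": condition,
                "slice_id": [f"s{i}" for i in range(len(viabilities))],
                "mode": "outgrowth",
                "viability_pct": viabilities,
                "outgrowth_pct": 50.0,
                "tvi": 100.0,
            }
        )

    def test_duplicates_averaged(self):
        out = average_duplicates(self._slices([40.0, 60.0]))
        assert out.loc[0, "viability_pct"] == pytest.approx(50.0)
        assert out.loc[0, "n_slices"] == 2

    def test_single_slice_passthrough(self):
        out = average_duplicates(self._slices([42.0]))
        assert out.loc[0, "viability_pct"] == pytest.approx(42.0)
        assert out.loc[0, "n_slices"] == 1

    def test_missing_viability_ignored_in_mean(self):
        out = average_duplicates(self._slices([np.nan, 60.0]))
        assert out.loc[0, "viability_pct"] == pytest.approx(60.0)

    def test_cohort_matrix_medians(self):
        summaries = pd.DataFrame(
            {
                "culture_id": ["DT1", "DT1", "DT2", "DT2"],
                "condition": ["control_72h", "se5", "control_72h", "se5"],
                "viability_pct": [80.0, 40.0, 60.0, 20.0],
                "outgrowth_pct": [50.0] * 4,
                "tvi": [100.0] * 4,
                "n_slices": [2] * 4,
            }
        )
        matrix, medians, pooled = cohort_matrix(summaries, "viability_pct")
        assert matrix.shape == (2, 2)
        assert medians["control_72h"] == pytest.approx(70.0)
        assert medians["se5"] == pytest.approx(30.0)
        assert pooled == pytest.approx(30.0)

    def test_missing_cell_allowed(self):
        summaries = pd.DataFrame(
            {
                "culture_id": ["DT1", "DT1", "DT2"],
                "condition": ["control_72h", "se5", "control_72h"],
                "viability_pct": [80.0, 40.0, 60.0],
                "outgrowth_pct": [50.0] * 3,
                "tvi": [100.0] * 3,
                "n_slices": [2] * 3,
            }
        )
        matrix, medians, _ = cohort_matrix(summaries, "viability_pct")
        assert np.isnan(matrix.loc["DT2", "se5"])
        assert medians["se5"] == pytest.approx(40.0)

    def test_unknown_readout_rejected(self):
        with pytest.raises(ValueError):
            cohort_matrix(pd.DataFrame(columns=["culture_id", "condition"]), "nope")


class TestEvansGrade:
    @pytest.mark.parametrize(
        "damaged, grade",
        [
            (5.0, "I"),
            (10.0, "IIa"),
            (50.0, "IIa"),
            (50.1, "IIb"),
            (90.0, "IIb"),
            (95.0, "III"),
            (99.9, "III"),
            (100.0, "IV"),
        ],
    )
    def test_bands(self, damaged, grade):
        assert evans_grade(damaged) == grade

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            evans_grade(101.0)


def test_pipeline_readouts_recover_ground_truth(small_cohort):
    cfg, table, truth = small_cohort
    slices = compute_slice_readouts(table)
    for _, row in slices.iterrows():
        expected = truth.viable_fraction[(row["culture_id"], row["condition"])]
        assert row["viability_pct"] == pytest.approx(100 * expected, rel=1e-9)
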