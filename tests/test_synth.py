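"""Synthetic cohort and DE-table generator behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from slicequant.config import SyntheticConfig, ConditionSpec
from slicequant.synth import (
    DAMAGED_CLASSES,
    VIABLE_CLASSES,
    dose_response_viable_fraction,
    generate_cohort,
    generate_de_table,
)


def _viability_by_slice(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorised viable fraction per slice, independent of the readout module."""
    lengths = table[table["measure_kind"] == "length"]
    viable = (
        lengths[lengths["annotation_class"].isin(VIABLE_CLASSES)]
        .groupby(["culture_id", "condition", "slice_id"])["value"]
        .sum()
    )
    total = lengths.groupby(["culture_id", "condition", "slice_id"])["value"].sum()
    return (viable / total).rename("viable_frac").reset_index()


class TestDoseResponse:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(v0=0.8, dose=0.0, emax=0.9, ec50=7, hill=4), 0.8),
            (dict(v0=0.8, dose=7.0, emax=1.0, ec50=7, hill=2.5), 0.4),
            (dict(v0=0.8, dose=30.0, emax=0.0, ec50=7, hill=4), 0.8),
        ],
        ids=["zero-dose identity", "half-maximal at EC50", "no-effect limit"],
    )
    def test_known_points(self, kwargs, expected):
        assert dose_response_viable_fraction(**kwargs) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(v0=1.2, dose=1, emax=0.5, ec50=7, hill=4),
            dict(v0=0.5, dose=-1, emax=0.5, ec50=7, hill=4),
            dict(v0=0.5, dose=1, emax=1.5, ec50=7, hill=4),
            dict(v0=0.5, dose=1, emax=0.5, ec50=0, hill=4),
            dict(v0=0.5, dose=1, emax=0.5, ec50=7, hill=0),
        ],
    )
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            dose_response_viable_fraction(**bad)

    @given(
        v0=st.floats(0.01, 1.0),
        emax=st.floats(0.0, 1.0),
        ec50=st.floats(0.5, 50.0),
        hill=st.floats(0.5, 6.0),
        d1=st.floats(0.0, 100.0),
        d2=st.floats(0.0, 100.0),
    )
    def test_monotone_non_increasing_in_dose(self, v0, emax, ec50, hill, d1, d2):
        lo, hi = sorted([d1, d2])
        f_lo = dose_response_viable_fraction(v0, lo, emax, ec50, hill)
        f_hi = dose_response_viable_fraction(v0, hi, emax, ec50, hill)
        assert f_hi <= f_lo + 1e-12


class TestGenerateCohort:
    def test_slice_group_count(self):
        cfg = SyntheticConfig(n_patients=8, area_mode_patients=0, seed=3)
        table, _ = generate_cohort(cfg)
        groups = table.groupby(["culture_id", "condition", "slice_id"]).ngroups
        assert groups == 8 * 5 * 2

    def test_determinism_byte_identical(self):
        cfg = SyntheticConfig(seed=42)
        t1, _ = generate_cohort(cfg)
        t2, _ = generate_cohort(cfg)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_patient_substreams_stable_under_cohort_growth(self):
        small, _ = generate_cohort(SyntheticConfig(n_patients=3, area_mode_patients=0, seed=5))
        large, _ = generate_cohort(SyntheticConfig(n_patients=6, area_mode_patients=0, seed=5))
        small_dt2 = small[small["culture_id"] == "DT2"].reset_index(drop=True)
        large_dt2 = large[large["culture_id"] == "DT2"].reset_index(drop=True)
        pd.testing.assert_frame_equal(small_dt2, large_dt2)

    def test_class_lengths_partition_outgrowth_and_fit_perimeter(self):
        table, _ = generate_cohort(SyntheticConfig(seed=9, area_mode_patients=0))
        for _, grp in table.groupby("slice_id"):
            perim = grp.loc[grp["measure_kind"] == "perimeter", "value"].sum()
            lengths = grp[grp["measure_kind"] == "length"]
            assert lengths["value"].sum() <= perim * (1 + 1e-12)
            viable = lengths[lengths["annotation_class"].isin(VIABLE_CLASSES)]["value"]
            damaged = lengths[lengths["annotation_class"].isin(DAMAGED_CLASSES)]["value"]
            # residual-split construction: class lengths partition the group
            # totals to full floating precision
            assert viable.sum() + damaged.sum() == pytest.approx(
                lengths["value"].sum(), rel=1e-12
            )

    def test_noise_free_viable_fraction_matches_truth_and_monotone(self):
        cfg = SyntheticConfig(seed=13, noise_sd=0.0, area_mode_patients=0)
        table, truth = generate_cohort(cfg)
        obs = _viability_by_slice(table)
        for _, row in obs.iterrows():
            key = (row["culture_id"], row["condition"])
            assert row["viable_frac"] == pytest.approx(
                truth.viable_fraction[key], rel=1e-9
            )
        for culture in truth.v0:
            doses = {"control_72h": 0, "se5": 5, "se15": 15, "se30": 30}
            fracs = [truth.viable_fraction[(culture, c)] for c in doses]
            assert all(a >= b - 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_area_mode_patients_emit_area_records_only(self):
        table, truth = generate_cohort(SyntheticConfig(seed=1))
        area_cultures = [c for c, m in truth.mode.items() if m == "area"]
        assert len(area_cultures) == 2
        sub = table[table["culture_id"].isin(area_cultures)]
        assert set(sub["annotation_class"]) == {"tumor_viable_area", "tumor_damaged_area"}
        assert set(sub["unit"]) == {"um2"}

    def test_gem_responder_flag_controls_response(self):
        responders_cfg = SyntheticConfig(seed=2, noise_sd=0.0, gem_responder_prob=1.0,
                                         area_mode_patients=0)
        _, truth = generate_cohort(responders_cfg)
        for culture, v0 in truth.v0.items():
            assert truth.viable_fraction[(culture, "gem1")] == pytest.approx(
                v0 * (1 - responders_cfg.emax)
            )
        none_cfg = responders_cfg.model_copy(update={"gem_responder_prob": 0.0})
        _, truth0 = generate_cohort(none_cfg)
        for culture, v0 in truth0.v0.items():
            assert truth0.viable_fraction[(culture, "gem1")] == pytest.approx(v0)

    def test_high_dose_damage_exceeds_90pct_over_seeds(self):
        # Monte-Carlo: mean damaged % at 30 µM across patients and 200 seeds
        cfg0 = SyntheticConfig(
            emax=0.99, ec50_um=7.0, hill=4.0, noise_sd=0.1, area_mode_patients=0,
            conditions=(
                ConditionSpec(label="control_72h", dose_um=0.0),
                ConditionSpec(label="se30", dose_um=30.0),
            ),
        )
        damaged = []
        for seed in range(200):
            table, _ = generate_cohort(cfg0.model_copy(update={"seed": seed}))
            obs = _viability_by_slice(table)
            se30 = obs[obs["condition"] == "se30"]["viable_frac"]
            damaged.append(100.0 * (1.0 - se30.mean()))
        assert np.mean(damaged) > 90.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_patients=0)
        with pytest.raises(ValueError):
            SyntheticConfig(area_mode_patients=9, n_patients=8)
        with pytest.raises(ValueError):
            SyntheticConfig(emax=1.5)


class TestGenerateDETable:
    def test_signal_genes_pass_fold_change_threshold(self):
        table = generate_de_table(n_genes=10, n_signal=10, effect_log2fc=2.0, seed=0)
        assert (table["log2fc"].abs() >= 1.0).all()

    def test_determinism(self):
        a = generate_de_table(500, 20, seed=4)
        b = generate_de_table(500, 20, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_null_p_values_uniform(self):
        # pooled over 100 seeds the null p <= 0.05 fraction is ~5%
        hits, total = 0, 0
        for seed in range(100):
            table = generate_de_table(n_genes=1000, n_signal=0, seed=seed)
            hits += int((table["p_value"] <= 0.05).sum())
            total += len(table)
        frac = hits / total
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / total)

    def test_long_tailed_read_counts(self):
        table = generate_de_table(5000, 0, seed=8)
        below = (table["total_reads"] < 350).mean()
        assert 0.05 < below < 0.7

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            generate_de_table(-1, 0)
        with pytest.raises(ValueError):
            generate_de_table(5, 10)
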