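"""Median-mapping calibration: medians, monotonization, inversion, tables."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bonescale as bs
from bonescale import (
    Cohort,
    MedianCurve,
    Sex,
    SubjectRecord,
    build_correction_table,
    build_sms_scale,
    invert_to_bone_age,
    median_by_age,
    monotonize,
    scale_end,
)
from bonescale.errors import CalibrationError, OutOfRangeWarning
from bonescale.synthetic import DEFAULT_AGES


def _cohort_with_values(values_by_age, sex=Sex.MALE, measure="gp_ba"):
    recs = []
    for age, values in values_by_age.items():
        for i, v in enumerate(values):
            recs.append(
                SubjectRecord(f"s{age}_{i}", sex, ca=float(age), **{measure: float(v)})
            )
    return Cohort(recs)


class TestMedianByAge:
    def test_interpolated_median_conventions(self):
        cohort = _cohort_with_values({5: [1, 2, 3], 6: [1, 2, 3, 4]})
        curve = median_by_age(cohort, Sex.MALE, grid=[5, 6], n_min=3)
        assert curve.median_value[0] == 2.0  # odd bin: middle value
        assert curve.median_value[1] == 2.5  # even bin: mean of middle two

    def test_grid_ages_below_n_min_dropped_with_warning(self):
        cohort = _cohort_with_values({5: [1] * 10, 6: [2] * 10, 7: [3] * 4})
        with pytest.warns(UserWarning, match="dropped"):
            curve = median_by_age(cohort, Sex.MALE, grid=[5, 6, 7], n_min=10)
        assert np.array_equal(curve.ca_grid, [5.0, 6.0])

    def test_fewer_than_two_surviving_ages_is_calibration_error(self):
        cohort = _cohort_with_values({5: [1] * 10, 6: [2] * 3})
        with pytest.raises(CalibrationError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            median_by_age(cohort, Sex.MALE, grid=[5, 6], n_min=10)

    def test_non_uniform_grid_keeps_half_year_samples_separate(self):
        # records at 2.0 must not leak into the 2.5 bin and vice versa
        cohort = _cohort_with_values({2.0: [2.0] * 10, 2.5: [3.0] * 10, 3.0: [4.0] * 10})
        curve = median_by_age(cohort, Sex.MALE, grid=[2.0, 2.5, 3.0], n_min=10)
        assert np.array_equal(curve.median_value, [2.0, 3.0, 4.0])

    def test_median_recovery_with_constant_offset(self, const_half_cohort):
        # median SE ~ 1.2533 * 1.1 / sqrt(2000) ~ 0.031; 0.08 is ~2.6 SE
        cfg, cohort = const_half_cohort
        for sex in Sex:
            curve = median_by_age(cohort, sex, grid=DEFAULT_AGES)
            keep = curve.ca_grid >= 5  # positivity floor censors the youngest bins
            assert np.all(np.abs(curve.median_value[keep] - (curve.ca_grid[keep] + 0.5)) < 0.08)


class TestMonotonize:
    def test_already_monotone_returned_unchanged(self):
        curve = MedianCurve(Sex.MALE, "gp_ba", [1.0, 2, 3], [1.0, 2, 3])
        assert monotonize(curve) is curve

    def test_pool_adjacent_violators_hand_example(self):
        curve = MedianCurve(Sex.MALE, "gp_ba", [1.0, 2, 3], [5.0, 4.8, 5.2])
        assert np.allclose(monotonize(curve).median_value, [4.9, 4.9, 5.2])

    def test_constant_curve_unchanged(self):
        curve = MedianCurve(Sex.MALE, "gp_ba", [1.0, 2, 3], [5.0, 5.0, 5.0])
        assert np.array_equal(monotonize(curve).median_value, [5.0, 5.0, 5.0])


class TestInvertToBoneAge:
    def test_published_worked_example(self):
        # median GP BA 13.5 at CA 13 => a child with GP BA 13.5 gets bone age 13
        curve = MedianCurve(Sex.MALE, "gp_ba", [12.0, 13.0, 14.0], [12.4, 13.5, 14.6])
        assert invert_to_bone_age(curve, 13.5) == 13.0

    def test_identity_curve_inverts_to_itself(self):
        curve = MedianCurve(Sex.MALE, "gp_ba", np.arange(2.0, 21), np.arange(2.0, 21))
        for x in [2.0, 7.3, 13.5, 20.0]:
            assert invert_to_bone_age(curve, x) == pytest.approx(x)

    def test_linear_interpolation_between_grid_ages(self):
        curve = MedianCurve(Sex.MALE, "gp_ba", [12.0, 13.0], [12.4, 13.6])
        assert invert_to_bone_age(curve, 13.0) == pytest.approx(12.5)

    def test_flat_segment_resolves_to_midpoint_age(self):
        curve = MedianCurve(Sex.MALE, "gp_ba", [10.0, 11.0, 12.0, 13.0], [9.0, 9.5, 9.5, 10.0])
        assert invert_to_bone_age(curve, 9.5) == pytest.approx(11.5)

    def test_out_of_range_clamps_with_warning(self):
        curve = MedianCurve(Sex.MALE, "gp_ba", [10.0, 12.0], [9.0, 11.0])
        with pytest.warns(OutOfRangeWarning):
            assert invert_to_bone_age(curve, 8.0) == 10.0
        with pytest.warns(OutOfRangeWarning):
            assert invert_to_bone_age(curve, 12.0) == 12.0

    def test_non_monotone_curve_is_rejected(self):
        curve = MedianCurve(Sex.MALE, "gp_ba", [10.0, 11.0], [9.0, 8.0])
        with pytest.raises(CalibrationError):
            invert_to_bone_age(curve, 8.5)


class TestCorrectionTable:
    def test_identity_curve_gives_zero_corrections(self):
        curve = MedianCurve(Sex.MALE, "gp_ba", np.arange(2.0, 21), np.arange(2.0, 21))
        table = build_correction_table(curve)
        assert np.allclose(table.corrections, 0.0)
        assert table.gp_grid[0] == 2.0 and table.gp_grid[-1] == 20.0
        assert table.terminal_and_above

    def test_constant_offset_recovered(self, const_half_cohort):
        cfg, cohort = const_half_cohort
        for sex in Sex:
            curve = monotonize(median_by_age(cohort, sex, grid=DEFAULT_AGES))
            table = build_correction_table(curve)
            interior = (table.gp_grid >= 6) & (table.gp_grid <= table.gp_grid[-1] - 1)
            assert np.all(np.abs(table.corrections[interior] + 0.5) <= 0.1)

    def test_piecewise_offset_only_above_14(self):
        ages = np.arange(2.0, 21)
        medians = ages + np.where(ages > 14, 1.0, 0.0)  # jump between 14 and 15
        table = build_correction_table(MedianCurve(Sex.MALE, "gp_ba", ages, medians))
        low = table.gp_grid <= 14.0
        high = table.gp_grid >= 16.0
        assert np.allclose(table.corrections[low], 0.0)
        assert np.allclose(table.corrections[high], -1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.1, 2.0), min_size=4, max_size=12).map(np.cumsum),
    )
    def test_roundtrip_and_monotonicity_of_adapted_mapping(self, medians):
        medians = np.asarray(medians) + 2.0
        ages = np.arange(2.0, 2.0 + len(medians))
        curve = MedianCurve(Sex.MALE, "gp_ba", ages, medians)
        # pre-rounding: g + correction(g) equals invert(g) exactly and is increasing
        table = build_correction_table(curve, rounding=1e-9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OutOfRangeWarning)
            inverted = [invert_to_bone_age(curve, g) for g in table.gp_grid]
        assert np.allclose(table.adapted_ages(), inverted, atol=1e-6)
        interior = (table.gp_grid > medians[0]) & (table.gp_grid < medians[-1])
        assert np.all(np.diff(table.adapted_ages()[interior]) > -1e-9)
        # post-rounding: non-decreasing within one rounding unit
        rounded = build_correction_table(curve, rounding=0.1)
        assert np.all(np.diff(rounded.adapted_ages()) > -0.1 - 1e-9)


class TestSmsScale:
    def _anchors_cohort(self, sex=Sex.MALE, per_age=12):
        table = bs.packaged_sms_table(sex)
        ages = [a for a in table.bone_ages if a <= 16.0] if sex == Sex.MALE else [
            a for a in table.bone_ages if a <= 15.0
        ]
        return (
            _cohort_with_values(
                {a: [bs.maturity_to_sms(a, sex)] * per_age for a in ages}, sex, "sms"
            ),
            ages,
        )

    def test_noise_free_fixed_point_recovers_published_anchors(self):
        cohort, ages = self._anchors_cohort(Sex.MALE)
        scale = build_sms_scale(cohort, Sex.MALE, ba_grid=ages)
        table = bs.packaged_sms_table(Sex.MALE)
        assert np.allclose(scale.bone_ages[:-1], ages)
        assert np.allclose(scale.sms[:-1], table.sms[: len(ages)])

    def test_terminal_extension_by_linear_extrapolation(self):
        # last two anchors (15.0, 835) and (16.0, 959): slope 124/y, so SMS
        # 1000 is reached 41/124 y beyond 16.0
        cohort, ages = self._anchors_cohort(Sex.MALE)
        scale = build_sms_scale(cohort, Sex.MALE, ba_grid=ages)
        assert scale.sms[-1] == 1000.0
        assert scale.scale_end == pytest.approx(16.0 + 41.0 / 124.0, abs=1e-9)

    def test_monte_carlo_anchor_recovery(self, zero_offset_cohort_2000):
        cfg, cohort = zero_offset_cohort_2000
        for sex, top in ((Sex.MALE, 16.0), (Sex.FEMALE, 15.0)):
            scale = build_sms_scale(cohort, sex, ba_grid=DEFAULT_AGES)
            truth_table = bs.packaged_sms_table(sex)
            for a, s in zip(scale.bone_ages[:-1], scale.sms[:-1]):
                if not (5 <= a <= top):
                    continue
                # convert the SMS discrepancy to years through the local slope
                back = float(np.interp(s, truth_table.sms, truth_table.bone_ages))
                assert abs(back - a) < 0.15

    def test_needs_two_anchors_below_saturation(self):
        cohort = _cohort_with_values({18: [1000.0] * 12, 19: [1000.0] * 12}, measure="sms")
        with pytest.raises(CalibrationError):
            build_sms_scale(cohort, Sex.MALE, ba_grid=[18, 19])


class TestScaleEnd:
    def test_published_terminal_corrections(self):
        # GP scale ends at 19 y (boys) / 18 y (girls); both corrections -1.2
        assert scale_end(bs.packaged_correction_table(Sex.MALE), 19.0) == pytest.approx(17.8)
        assert scale_end(bs.packaged_correction_table(Sex.FEMALE), 18.0) == pytest.approx(16.8)

    def test_zero_table_is_identity(self):
        table = bs.CorrectionTable(Sex.MALE, np.arange(2.0, 18, 0.5), np.zeros(32))
        assert scale_end(table, 19.0) == 19.0
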