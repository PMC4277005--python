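"""Unit and property tests for the closed-form densitometric models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bodycomp import (
    CONSTANTS,
    POSTPARTUM_NONPREGNANT_FFM_DENSITY,
    AnthropometricMeasurement,
    DegenerateModelError,
    InvalidInputError,
    PhysiologicalRangeWarning,
    Stage,
    body_composition,
    fat_fraction_2cm,
    fat_fraction_3cm,
    ffm_density_from_fat_fraction,
    tbw_from_deuterium_space,
)
from conftest import TABLE1, FFM_DENSITY_ESTIMATES


def eq1_oracle(weight, tbw, density):
    # independently coded one-line 3CM formula
    return 2.118 / density - 0.78 * tbw / weight - 1.354


class TestDeuteriumConversion:
    @pytest.mark.parametrize("space, expected", [(1.04, 1.0), (32.76, 31.5)])
    def test_division_by_dilution_factor(self, space, expected):
        assert tbw_from_deuterium_space(space) == pytest.approx(expected, abs=1e-3)

    def test_nonpositive_space_rejected(self):
        with pytest.raises(InvalidInputError):
            tbw_from_deuterium_space(0.0)


class TestThreeComponentModel:
    def test_gw32_cohort_means(self):
        # model evaluated at the cohort means (not the printed per-subject mean)
        f = fat_fraction_3cm(77.3, 38.1, 1.021)
        assert f == pytest.approx(0.3360, abs=0.0005)

    def test_terms_cancel_to_zero_fat(self):
        assert fat_fraction_3cm(70.0, 0.0, 2.118 / 1.354) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(45, 110, 50)
        tbw = rng.uniform(20, 50, 50)
        d = rng.uniform(0.99, 1.08, 50)
        with np.errstate(all="ignore"):
            np.testing.assert_allclose(
                fat_fraction_3cm(w, tbw, d), eq1_oracle(w, tbw, d), rtol=0, atol=1e-12
            )

    def test_affine_in_inverse_density_with_slope_c1(self):
        # at fixed TBW/weight, f is affine in 1/D_B with slope 2.118
        d1, d2 = 1.01, 1.05
        f1 = fat_fraction_3cm(70.0, 35.0, d1)
        f2 = fat_fraction_3cm(70.0, 35.0, d2)
        slope = (f1 - f2) / (1 / d1 - 1 / d2)
        assert slope == pytest.approx(CONSTANTS.c1, rel=1e-12)

    def test_zero_weight_or_density_rejected(self):
        with pytest.raises(InvalidInputError):
            fat_fraction_3cm(0.0, 30.0, 1.02)
        with pytest.raises(InvalidInputError):
            fat_fraction_3cm(70.0, 30.0, 0.0)

    def test_implausible_fraction_flagged_not_clamped(self):
        with pytest.warns(PhysiologicalRangeWarning):
            f = fat_fraction_3cm(70.0, 60.0, 1.1)
        assert f < 0  # returned unclamped


class TestTwoComponentModel:
    @pytest.mark.parametrize(
        "density, ffm_density, expected",
        [(1.027, 1.099, 0.318), (1.020, 1.094, 0.338)],
    )
    def test_printed_cohort_examples(self, density, ffm_density, expected):
        assert fat_fraction_2cm(density, ffm_density) == pytest.approx(
            expected, abs=5e-4
        )

    def test_all_ffm_body(self):
        assert fat_fraction_2cm(1.1, 1.1) == pytest.approx(0.0, abs=1e-12)

    def test_all_fat_body(self):
        assert fat_fraction_2cm(CONSTANTS.fat_density, 1.1) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_degenerate_ffm_density(self):
        with pytest.raises(DegenerateModelError):
            fat_fraction_2cm(1.02, CONSTANTS.fat_density)

    def test_monotone_decreasing_in_body_density(self):
        d = np.linspace(0.95, 1.09, 40)
        f = fat_fraction_2cm(d, 1.1)
        assert np.all(np.diff(f) < 0)

    def test_monotone_increasing_in_ffm_density(self):
        d_ffm = np.linspace(1.03, 1.12, 40)
        f = fat_fraction_2cm(1.02, d_ffm)
        assert np.all(np.diff(f) > 0)


class TestFFMDensityInversion:
    @pytest.mark.parametrize(
        "density, f, expected",
        [(1.021, 0.331, 1.093), (1.020, 0.352, 1.099)],
    )
    def test_printed_stage_estimates(self, density, f, expected):
        assert ffm_density_from_fat_fraction(density, f) == pytest.approx(
            expected, abs=1e-3
        )

    def test_zero_fat_returns_body_density(self):
        for d in (0.98, 1.02, 1.1):
            assert ffm_density_from_fat_fraction(d, 0.0) == pytest.approx(d, abs=1e-15)

    def test_degenerate_body(self):
        with pytest.raises(DegenerateModelError):
            ffm_density_from_fat_fraction(1.1, 0.95)

    @given(
        d_b=st.floats(0.95, 1.09),
        d_ffm=st.floats(1.03, 1.15),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_with_2cm(self, d_b, d_ffm):
        f = fat_fraction_2cm(d_b, d_ffm)
        assert ffm_density_from_fat_fraction(d_b, f) == pytest.approx(d_ffm, abs=1e-9)


class TestBodyComposition:
    def test_two_component_registry_default_gw32(self, stage_mean_measurements):
        bc = body_composition(stage_mean_measurements[Stage.GW32], "two_component")
        assert bc.tbf_percent == pytest.approx(32.7, abs=0.1)

    def test_postpartum_with_nonpregnant_reference(self, stage_mean_measurements):
        bc = body_composition(
            stage_mean_measurements[Stage.POSTPARTUM_2W],
            "two_component",
            ffm_density_ref=POSTPARTUM_NONPREGNANT_FFM_DENSITY,
        )
        assert bc.tbf_percent == pytest.approx(35.4, abs=0.1)

    @pytest.mark.parametrize("method", ["two_component", "three_component"])
    def test_mass_closure(self, stage_mean_measurements, method):
        for m in stage_mean_measurements.values():
            bc = body_composition(m, method)
            assert bc.fat_mass + bc.ffm_mass == pytest.approx(
                m.body_weight, abs=1e-9
            )
            assert bc.body_volume == pytest.approx(
                m.body_weight / m.body_density, abs=1e-12
            )

    def test_three_component_reports_subject_ffm_density(
        self, stage_mean_measurements
    ):
        # the record's FFM density is the chained per-subject inversion and
        # sits near the stage estimate (model-at-means vs mean-of-model gap)
        for stage, m in stage_mean_measurements.items():
            bc = body_composition(m, "three_component")
            chained = ffm_density_from_fat_fraction(
                m.body_density,
                fat_fraction_3cm(m.body_weight, m.total_body_water, m.body_density),
            )
            assert bc.ffm_density == pytest.approx(chained, abs=1e-12)
            assert bc.ffm_density == pytest.approx(
                FFM_DENSITY_ESTIMATES[stage], abs=3e-3
            )

    def test_models_agree_at_subject_ffm_density(self, stage_mean_measurements):
        # the 2CM equals the 3CM exactly when fed the subject's own FFM density
        m = stage_mean_measurements[Stage.GW14]
        bc3 = body_composition(m, "three_component")
        bc2 = body_composition(m, "two_component", ffm_density_ref=bc3.ffm_density)
        assert bc2.fat_fraction == pytest.approx(bc3.fat_fraction, abs=1e-12)

    def test_unknown_method_rejected(self, stage_mean_measurements):
        with pytest.raises(InvalidInputError):
            body_composition(
                stage_mean_measurements[Stage.GW14], "four_component"
            )


class TestMeasurementValidation:
    def test_invariant_violations_rejected(self):
        with pytest.raises(InvalidInputError):
            AnthropometricMeasurement("s", Stage.GW14, 0.0, 30.0, 1.02)
        with pytest.raises(InvalidInputError):
            AnthropometricMeasurement("s", Stage.GW14, 70.0, 75.0, 1.02)

    def test_density_sanity_window_warns_only(self):
        with pytest.warns(PhysiologicalRangeWarning):
            m = AnthropometricMeasurement("s", Stage.GW14, 70.0, 35.0, 1.2)
        assert m.body_density == 1.2
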