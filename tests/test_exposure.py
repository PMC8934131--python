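import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbmodel import (
    DomainError,
    ValidationError,
    apply_prevalence_shift,
    apply_sitting_reduction,
    category_of,
    load_exposure_table,
    stratum_mean,
)
from sbmodel.exposure import AGE_BANDS, CATEGORIES, SEXES, ExposureStratum, ExposureTable


def make_stratum(proportion=(0.3, 0.4, 0.3), means=(180.0, 350.0, 630.0), sex="female",
                 band="45-54", prop_se=(0.0, 0.0, 0.0), mean_se=(0.0, 0.0, 0.0)):
    return ExposureStratum(
        sex=sex,
        age_band=band,
        proportion=np.asarray(proportion, dtype=float),
        proportion_se=np.asarray(prop_se, dtype=float),
        mean_minutes=np.asarray(means, dtype=float),
        mean_se=np.asarray(mean_se, dtype=float),
    )


def single_stratum_table(**kwargs):
    st_ = make_stratum(**kwargs)
    return ExposureTable({(st_.sex, st_.age_band): st_})


class TestLoadExposureTable:
    def test_fixture_has_14_strata(self, exposure_fixture):
        assert len(exposure_fixture) == 14
        assert exposure_fixture.is_complete

    def test_fixture_female_45_54_high(self, exposure_fixture):
        stratum = exposure_fixture.stratum("female", "45-54")
        assert stratum.mean_minutes[2] == pytest.approx(618.50)
        assert stratum.proportion[2] == pytest.approx(0.3069, abs=1e-9)

    def test_single_stratum_csv_valid(self):
        csv = io.StringIO(
            "sex,age_band,category,proportion,proportion_se,mean_minutes,mean_se\n"
            "female,45-54,low,1,0,180,0\n"
            "female,45-54,moderate,0,0,350,0\n"
            "female,45-54,high,0,0,630,0\n"
        )
        table = load_exposure_table(csv)
        assert len(table) == 1
        assert table.stratum("female", "45-54").proportion[0] == 1.0

    def test_proportions_summing_to_half_rejected(self):
        csv = io.StringIO(
            "sex,age_band,category,proportion,proportion_se,mean_minutes,mean_se\n"
            "female,45-54,low,0.2,0,180,0\n"
            "female,45-54,moderate,0.2,0,350,0\n"
            "female,45-54,high,0.1,0,630,0\n"
        )
        with pytest.raises(ValidationError, match="45-54"):
            load_exposure_table(csv)

    def test_mild_misnormalisation_renormalised(self):
        csv = io.StringIO(
            "sex,age_band,category,proportion,proportion_se,mean_minutes,mean_se\n"
            "male,18-24,low,0.30,0,180,0\n"
            "male,18-24,moderate,0.35,0,350,0\n"
            "male,18-24,high,0.34,0,630,0\n"
        )
        table = load_exposure_table(csv)
        assert table.stratum("male", "18-24").proportion.sum() == pytest.approx(1.0, abs=1e-12)

    def test_fixture_proportions_sum_to_one(self, exposure_fixture):
        for stratum in exposure_fixture:
            assert stratum.proportion.sum() == pytest.approx(1.0, abs=1e-6)


class TestCategoryOf:
    @pytest.mark.parametrize(
        "minutes,expected",
        [(0, "low"), (239, "low"), (240, "moderate"), (479.9, "moderate"),
         (480, "high"), (600, "high"), (1440, "high")],
    )
    def test_binning(self, minutes, expected):
        assert category_of(minutes) == expected

    @pytest.mark.parametrize("minutes", [-1, 1441])
    def test_out_of_range(self, minutes):
        with pytest.raises(DomainError):
            category_of(minutes)


class TestPrevalenceShift:
    def test_zero_fraction_is_identity(self, exposure_fixture):
        shifted = apply_prevalence_shift(exposure_fixture, "high", "moderate", 0.0)
        for stratum in shifted:
            original = exposure_fixture.stratum(stratum.sex, stratum.age_band)
            np.testing.assert_array_equal(stratum.proportion, original.proportion)

    def test_full_shift_empties_source(self, exposure_fixture):
        shifted = apply_prevalence_shift(exposure_fixture, "high", "moderate", 1.0)
        for stratum in shifted:
            assert stratum.proportion[2] == 0.0

    def test_female_45_54_scenario2_arithmetic(self, exposure_fixture):
        # 30% of the high proportion moves to moderate
        shifted = apply_prevalence_shift(exposure_fixture, "high", "moderate", 0.3)
        stratum = shifted.stratum("female", "45-54")
        assert stratum.proportion[2] == pytest.approx(0.21483, abs=1e-9)
        assert stratum.proportion[1] == pytest.approx(0.40017, abs=1e-9)

    def test_means_unchanged(self, exposure_fixture):
        shifted = apply_prevalence_shift(exposure_fixture, "high", "moderate", 0.3)
        for stratum in shifted:
            original = exposure_fixture.stratum(stratum.sex, stratum.age_band)
            np.testing.assert_array_equal(stratum.mean_minutes, original.mean_minutes)

    def test_same_category_rejected(self, exposure_fixture):
        with pytest.raises(DomainError):
            apply_prevalence_shift(exposure_fixture, "high", "high", 0.3)

    @given(
        f1=st.floats(0, 1), f2=st.floats(0, 1),
        p=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
    )
    @settings(max_examples=50, deadline=None)
    def test_mass_conserved_and_nonnegative(self, f1, f2, p):
        p = np.asarray(p) / np.sum(p)
        table = single_stratum_table(proportion=p)
        out = apply_prevalence_shift(table, "high", "moderate", f1)
        out = apply_prevalence_shift(out, "moderate", "low", f2)
        stratum = next(iter(out))
        assert stratum.proportion.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(stratum.proportion >= -1e-12)


class TestSittingReduction:
    def test_zero_minutes_identity(self, exposure_fixture):
        out = apply_sitting_reduction(exposure_fixture, 0.0)
        for stratum in out:
            original = exposure_fixture.stratum(stratum.sex, stratum.age_band)
            np.testing.assert_array_equal(stratum.mean_minutes, original.mean_minutes)

    def test_trial_effect_reduces_targeted_means(self, exposure_fixture):
        out = apply_sitting_reduction(exposure_fixture, 36.3, ("moderate", "high"))
        for stratum in out:
            original = exposure_fixture.stratum(stratum.sex, stratum.age_band)
            assert stratum.mean_minutes[0] == original.mean_minutes[0]
            assert stratum.mean_minutes[1] == pytest.approx(original.mean_minutes[1] - 36.3)
            assert stratum.mean_minutes[2] == pytest.approx(original.mean_minutes[2] - 36.3)

    def test_floored_at_category_lower_bound(self):
        table = single_stratum_table(means=(180.0, 250.0, 500.0))
        out = apply_sitting_reduction(table, 100.0, ("moderate", "high"))
        stratum = next(iter(out))
        assert stratum.mean_minutes[1] == 240.0
        assert stratum.mean_minutes[2] == 480.0

    @given(m1=st.floats(0, 200), m2=st.floats(0, 200))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_minutes(self, m1, m2):
        table = single_stratum_table()
        lo, hi = sorted([m1, m2])
        mean_lo = stratum_mean(next(iter(apply_sitting_reduction(table, hi))))
        mean_hi = stratum_mean(next(iter(apply_sitting_reduction(table, lo))))
        assert mean_lo <= mean_hi + 1e-12


class TestStratumMean:
    def test_degenerate_all_low(self):
        assert stratum_mean(make_stratum(proportion=(1, 0, 0))) == 180.0

    def test_equal_thirds(self):
        stratum = make_stratum(proportion=(1 / 3, 1 / 3, 1 / 3), means=(180, 360, 600))
        assert stratum_mean(stratum) == pytest.approx(380.0)

    def test_fixture_female_45_54(self, exposure_fixture):
        stratum = exposure_fixture.stratum("female", "45-54")
        expected = 0.3850 * 163.02 + 0.3081 * 343.66 + 0.3069 * 618.50
        assert stratum_mean(stratum) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(358.46, abs=0.01)


def test_category_of_consistent_with_bounds():
    # binning is bounds-consistent by construction
    from sbmodel.exposure import CATEGORY_BOUNDS

    for cat, (lo, hi) in CATEGORY_BOUNDS.items():
        assert category_of(lo) == cat
        assert category_of(min(hi - 1e-9, 1440.0)) == cat


def test_stratum_invariant_violations():
    with pytest.raises(ValidationError):
        make_stratum(means=(350.0, 180.0, 630.0))  # not increasing
    with pytest.raises(ValidationError):
        make_stratum(prop_se=(-0.1, 0, 0))
    with pytest.raises(ValidationError):
        make_stratum(proportion=(0.5, 0.4, 0.3))  # sums to 1.2


def test_require_complete(exposure_fixture):
    table = single_stratum_table()
    with pytest.raises(ValidationError, match="missing"):
        table.require_complete()
    exposure_fixture.require_complete()  # no error


def test_roundtrip_frame(exposure_fixture):
    from sbmodel.exposure import exposure_table_from_frame

    again = exposure_table_from_frame(exposure_fixture.to_frame())
    for stratum in again:
        original = exposure_fixture.stratum(stratum.sex, stratum.age_band)
        np.testing.assert_allclose(stratum.proportion, original.proportion)
        np.testing.assert_allclose(stratum.mean_minutes, original.mean_minutes)
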