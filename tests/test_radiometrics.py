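"""Decay correction, %ID/g, cohort summaries, group statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from phlipkit.radiometrics import (
    GA68_HALF_LIFE_MIN,
    BiodistTable,
    DoseReference,
    OrganMeasurement,
    RadiometricsError,
    bound_fraction,
    cohort_summary,
    compare_groups,
    decay_correct,
    percent_id_per_gram,
    radiochemical_accounting,
    read_measurements_csv,
    tidy_percent_id,
)


class TestDecayCorrect:
    @pytest.mark.parametrize(
        "elapsed, expected", [(0.0, 100.0), (67.71, 200.0), (135.42, 400.0)]
    )
    def test_half_life_closed_form(self, elapsed, expected):
        assert decay_correct(100.0, elapsed, 67.71) == pytest.approx(expected)

    def test_negative_elapsed_rejected(self):
        with pytest.raises(RadiometricsError):
            decay_correct(100.0, -1.0, 67.71)

    def test_multiplicative_in_time(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c, t1, t2 = rng.uniform(1, 1e5), rng.uniform(0, 300), rng.uniform(0, 300)
            chained = decay_correct(decay_correct(c, t1, 67.71), t2, 67.71)
            assert chained == pytest.approx(decay_correct(c, t1 + t2, 67.71), rel=1e-12)


def measurement(counts, weight, t, organ="tumor", animal="a1"):
    return OrganMeasurement(
        animal_id=animal, organ=organ, counts=counts, weight=weight,
        time_post_injection=t,
    )


class TestPercentId:
    def test_whole_dose_in_one_gram(self):
        m = measurement(80000.0, 1.0, 0.0)
        assert percent_id_per_gram(m, DoseReference(80000.0)) == pytest.approx(100.0)

    def test_inverse_linear_in_weight(self):
        m = measurement(80000.0, 2.0, 0.0)
        assert percent_id_per_gram(m, DoseReference(80000.0)) == pytest.approx(50.0)

    def test_hand_arithmetic_with_decay(self):
        # 1000 cpm measured one half-life after injection: 2000 cpm at t=0;
        # 2000/80000/0.25 g * 100 = 10 %ID/g
        m = measurement(1000.0, 0.25, 67.71)
        assert percent_id_per_gram(
            m, DoseReference(80000.0), GA68_HALF_LIFE_MIN
        ) == pytest.approx(10.0)

    def test_linear_in_counts(self):
        dose = DoseReference(5e5)
        a = percent_id_per_gram(measurement(1000.0, 0.3, 60.0), dose)
        b = percent_id_per_gram(measurement(3000.0, 0.3, 60.0), dose)
        assert b == pytest.approx(3 * a, rel=1e-12)

    def test_invalid_measurements_rejected(self):
        with pytest.raises(RadiometricsError):
            measurement(-1.0, 1.0, 0.0)
        with pytest.raises(RadiometricsError):
            measurement(1.0, 0.0, 0.0)
        with pytest.raises(RadiometricsError):
            DoseReference(0.0)


class TestCohortSummary:
    def test_identical_values_have_zero_sd(self):
        table = BiodistTable(
            measurements=tuple(
                measurement(1000.0, 0.5, 60.0, animal=f"a{i}") for i in range(3)
            ),
            dose=DoseReference(1e6),
        )
        summary = cohort_summary(table)
        assert summary.loc[0, "n"] == 3
        assert summary.loc[0, "sd"] == pytest.approx(0.0)

    def test_two_value_closed_form(self):
        # %ID/g of 4 and 6 at t=0: mean 5, sample SD sqrt(2)
        table = BiodistTable(
            measurements=(
                measurement(4000.0, 1.0, 0.0, animal="a"),
                measurement(6000.0, 1.0, 0.0, animal="b"),
            ),
            dose=DoseReference(1e5),
        )
        summary = cohort_summary(table)
        assert summary.loc[0, "mean"] == pytest.approx(5.0)
        assert summary.loc[0, "sd"] == pytest.approx(math.sqrt(2.0))

    def test_corrected_and_uncorrected_columns_differ(self):
        table = BiodistTable(
            measurements=(measurement(1000.0, 0.5, 67.71),),
            dose=DoseReference(1e6),
        )
        tidy = tidy_percent_id(table)
        assert tidy.loc[0, "pid_g_corrected"] == pytest.approx(
            2 * tidy.loc[0, "pid_g_uncorrected"]
        )

    def test_dose_conservation_on_conserving_dataset(self):
        # organs carrying exactly the whole dose at t=0: sum of
        # %ID/g * weight must be 100 (no excretion in this construction)
        dose = DoseReference(1e6)
        weights = [1.2, 0.4, 0.3]
        fractions = [0.5, 0.3, 0.2]
        table = BiodistTable(
            measurements=tuple(
                measurement(f * 1e6, w, 0.0, organ=f"o{i}")
                for i, (f, w) in enumerate(zip(fractions, weights))
            ),
            dose=dose,
        )
        tidy = tidy_percent_id(table)
        recovered = (tidy["pid_g_corrected"] * tidy["weight_g"]).sum()
        assert recovered == pytest.approx(100.0)


class TestCompareGroups:
    def test_identical_groups_give_zero_f(self):
        _, f, p = compare_groups([1, 2, 3], [1, 2, 3])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        # between-SS 4, within-SS 1, df (1, 2): F = 8, p ~ 0.1056
        _, f, p = compare_groups([1, 2], [3, 4])
        assert f == pytest.approx(8.0)
        assert p == pytest.approx(0.1056, abs=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(RadiometricsError, match="zero variance"):
            compare_groups([2.0, 2.0], [2.0, 2.0])

    def test_small_group_rejected(self):
        with pytest.raises(RadiometricsError):
            compare_groups([1.0], [2.0, 3.0])

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            a = rng.normal(5, 1, size=int(rng.integers(3, 10)))
            b = rng.normal(6, 1, size=int(rng.integers(3, 10)))
            _, f, p_f = compare_groups(a, b)
            t, p_t = stats.ttest_ind(a, b, equal_var=True)
            assert f == pytest.approx(t * t, rel=1e-9)
            assert p_f == pytest.approx(p_t, rel=1e-9)

    def test_levene_detects_unequal_spread(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 0.1, 50)
        b = rng.normal(0, 3.0, 50)
        levene_p, _, _ = compare_groups(a, b)
        assert levene_p < 0.05


class TestFractionsAndYields:
    @pytest.mark.parametrize(
        "sup, sed, expected", [(50, 50, 50.0), (100, 0, 0.0), (679, 321, 32.1)]
    )
    def test_bound_fraction(self, sup, sed, expected):
        assert bound_fraction(sup, sed) == pytest.approx(expected)

    def test_bound_fraction_requires_activity(self):
        with pytest.raises(RadiometricsError):
            bound_fraction(0.0, 0.0)

    def test_accounting_round_trip(self):
        y, p = radiochemical_accounting(89.5, 100.0, 9795.0, 10000.0)
        assert y == pytest.approx(89.5)
        assert p == pytest.approx(97.95)

    def test_accounting_identity_cases(self):
        y, p = radiochemical_accounting(5.0, 5.0, 3.0, 3.0)
        assert y == pytest.approx(100.0) and p == pytest.approx(100.0)

    def test_accounting_zero_denominator(self):
        with pytest.raises(RadiometricsError):
            radiochemical_accounting(1.0, 0.0, 1.0, 1.0)


class TestCsvInput:
    def test_round_trip(self, tmp_path):
        import pandas as pd

        path = tmp_path / "m.csv"
        pd.DataFrame(
            {
                "animal_id": ["a1", "a1"],
                "group": ["tracer", "tracer"],
                "timepoint_min": [60.0, 60.0],
                "organ": ["tumor", "liver"],
                "counts_cpm": [1000.0, 5000.0],
                "weight_g": [0.4, 1.1],
            }
        ).to_csv(path, index=False)
        table = read_measurements_csv(path, DoseReference(1e6))
        assert len(table.measurements) == 2
        assert table.measurements[1].organ == "liver"

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("animal_id,organ\na1,tumor\n")
        with pytest.raises(RadiometricsError, match="counts_cpm"):
            read_measurements_csv(path, DoseReference(1e6))
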