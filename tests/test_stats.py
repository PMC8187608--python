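import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from workburden import (
    ALL_CAUSES,
    CalendarInterval,
    DataIntegrityError,
    Employee,
    HeadcountTable,
    SAEpisode,
    Sex,
    Stratum,
    build_burden_table,
    compare_strata,
    default_strata,
    per_myriad,
    person_burden,
    person_year_denominator,
    rate_ci,
    share,
)

D = dt.date
DENOM = 506_883  # male + female person-years of the six-year study


def headcounts_df(rows):
    return pd.DataFrame(rows, columns=["year", "sex", "age_band", "count"])


class TestDenominator:
    def test_one_row_is_count_person_years(self):
        h = headcounts_df([(2012, "M", "40-44", 5000)])
        assert person_year_denominator(h) == 5000.0

    def test_sex_margins_add_up(self):
        # annual male rows summing to 409,678 and female to 97,205
        rows = [(2012 + i, "M", "30-34", 409_678 // 6 + (i < 409_678 % 6))
                for i in range(6)]
        rows += [(2012 + i, "F", "30-34", 97_205 // 6 + (i < 97_205 % 6))
                 for i in range(6)]
        h = HeadcountTable(headcounts_df(rows))
        male = h.person_years(Stratum("m", Sex.MALE))
        female = h.person_years(Stratum("f", Sex.FEMALE))
        assert male == 409_678.0
        assert female == 97_205.0
        assert h.person_years() == DENOM

    def test_linearity(self):
        rows = [(2012, "M", "20-24", 100), (2013, "F", "45-49", 50)]
        single = person_year_denominator(headcounts_df(rows))
        doubled = person_year_denominator(
            headcounts_df([(y, s, b, 2 * c) for y, s, b, c in rows])
        )
        assert doubled == 2 * single

    def test_empty_stratum_errors(self):
        h = HeadcountTable(headcounts_df([(2012, "M", "40-44", 10)]))
        with pytest.raises(DataIntegrityError):
            h.person_years(Stratum("f", Sex.FEMALE))

    def test_band_straddling_a_stratum_errors(self):
        h = HeadcountTable(headcounts_df([(2012, "M", "38-42", 10)]))
        with pytest.raises(DataIntegrityError):
            h.person_years(Stratum("m young", Sex.MALE, 20, 40))

    def test_duplicate_rows_rejected(self):
        with pytest.raises(DataIntegrityError):
            HeadcountTable(
                headcounts_df([(2012, "M", "40-44", 10), (2012, "M", "40-44", 9)])
            )


class TestPerMyriad:
    def test_hundred_per_myriad(self):
        # 100 person-years lost in 10,000 person-years of working time
        assert per_myriad(100, 10_000) == 100.0

    def test_zero_loss(self):
        assert per_myriad(0, 123_456) == 0.0

    def test_inverts_the_all_cause_row(self):
        assert round(per_myriad(4354.1, DENOM), 1) == 85.9

    def test_bad_denominator(self):
        with pytest.raises(ValueError):
            per_myriad(1.0, 0.0)


class TestRateCI:
    def test_reproduces_mental_disorders_interval(self):
        lo, hi = rate_ci(47.0e-4 * DENOM, DENOM)
        assert (round(lo, 1), round(hi, 1)) == (45.1, 48.9)

    def test_reproduces_sickness_absence_interval(self):
        lo, hi = rate_ci(40.8e-4 * DENOM, DENOM)
        assert (round(lo, 1), round(hi, 1)) == (39.0, 42.6)

    def test_zero_degenerates(self):
        assert rate_ci(0.0, 1000.0) == (0.0, 0.0)

    def test_bounds_bracket_the_estimate(self):
        lo, hi = rate_ci(50.0, 10_000.0)
        assert lo <= per_myriad(50.0, 10_000.0) <= hi

    def test_level_validation(self):
        with pytest.raises(ValueError):
            rate_ci(10.0, 100.0, level=1.5)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(1.0, 1e4), st.floats(1e3, 1e7))
    def test_width_scales_inversely_with_sqrt_denominator(self, lost, denom):
        # at a fixed rate, quadrupling the denominator halves the CI width
        lo1, hi1 = rate_ci(lost, denom)
        lo4, hi4 = rate_ci(4 * lost, 4 * denom)
        if lo1 > 0:  # unfloored regime
            assert (hi4 - lo4) == pytest.approx((hi1 - lo1) / 2, rel=1e-9)


class TestShare:
    def test_mental_share_of_total(self):
        assert round(share(47.0, 85.9), 1) == 54.7

    def test_self_share_is_100(self):
        assert share(12.3, 12.3) == pytest.approx(100.0)

    def test_neoplasm_share_of_mortality(self):
        assert round(share(6.5, 17.0), 1) == 38.2

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            share(1.0, 0.0)


class TestCompareStrata:
    def test_equal_proportions_give_zero_statistic(self):
        stat, p = compare_strata(100, 10_000, 100, 10_000)
        assert stat == 0.0
        assert p == 1.0

    def test_matches_direct_chi_square_formula(self):
        stat, _ = compare_strata(100, 10_000, 50, 10_000)
        # independent oracle: sum over cells of (O - E)^2 / E
        obs = np.array([[100, 9900], [50, 9950]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-12)

    def test_symmetric_in_the_strata(self):
        a = compare_strata(100, 10_000, 50, 8_000)
        b = compare_strata(50, 8_000, 100, 10_000)
        assert a == pytest.approx(b)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(ValueError):
            compare_strata(0, 10_000, 0, 10_000)


class TestBurdenTable:
    def test_single_employee_single_cell(self):
        e = Employee("e1", Sex.MALE, D(1980, 1, 1))
        ep = SAEpisode(
            "e1",
            CalendarInterval(D(2013, 1, 1), D(2013, 1, 1) + dt.timedelta(days=366)),
            "F32",
        )
        pb = person_burden(e, [ep])
        h = headcounts_df([(2012, "M", "30-34", 10_000)])
        table = build_burden_table([pb], [e], h, strata=[Stratum("all")])
        cell = table.cell("all", "Mental and behavioural disorders", "sa")
        assert cell.per_myriad == pytest.approx(366 / 365.25 / 10_000 * 10_000)
        total = table.cell("all", "Mental and behavioural disorders", "total")
        assert total.per_myriad == cell.per_myriad

    def test_empty_burden_list_gives_all_zero_table(self):
        h = headcounts_df([(2012, "M", "30-34", 100)])
        table = build_burden_table([], [], h, strata=[Stratum("all")])
        assert (table.data["days_lost"] == 0).all()
        assert (table.data["per_myriad"] == 0.0).all()

    def test_age_split_partitions_a_crossing_employee_exactly(self):
        # turns 40 on 2015-06-15, one long spell straddling that birthday
        e = Employee("e1", Sex.MALE, D(1975, 6, 15))
        ep = SAEpisode(
            "e1", CalendarInterval(D(2015, 5, 1), D(2015, 8, 1)), "F32"
        )
        pb = person_burden(e, [ep])
        h = headcounts_df(
            [(2015, "M", "35-39", 100), (2015, "M", "40-44", 100)]
        )
        strata = [
            Stratum("all"),
            Stratum("M 20-39", Sex.MALE, 20, 40),
            Stratum("M 40-59", Sex.MALE, 40, 60),
        ]
        table = build_burden_table([pb], [e], h, strata=strata)
        young = table.cell("M 20-39", "Mental and behavioural disorders", "sa")
        old = table.cell("M 40-59", "Mental and behavioural disorders", "sa")
        whole = table.cell("all", "Mental and behavioural disorders", "sa")
        assert young.years_lost + old.years_lost == pytest.approx(whole.years_lost)
        # days before the 40th birthday: 2015-05-01 .. 2015-06-15
        assert young.years_lost == pytest.approx(45 / 365.25)

    def test_missing_headcounts_for_a_stratum_errors(self):
        e = Employee("e1", Sex.FEMALE, D(1980, 1, 1))
        h = headcounts_df([(2012, "M", "30-34", 100)])
        with pytest.raises(DataIntegrityError):
            build_burden_table([], [e], h, strata=default_strata())
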