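import datetime as dt

import numpy as np
import pytest

from workburden import (
    CalendarInterval,
    Consequence,
    DataIntegrityError,
    DeathEvent,
    Employee,
    ObservationWindow,
    Outcome,
    ReferentialIntegrityError,
    SAEpisode,
    Sex,
    filter_ltsa,
    merge_episodes,
    person_burden,
    personal_window,
)
from conftest import burden_day_counts, day_by_day_burden, random_case

D = dt.date
YEAR = 365.25


def emp(birth, sex=Sex.MALE, id="e1"):
    return Employee(id, sex, birth)


def spell(start, end, code="F32", outcome=Outcome.RETURN_TO_WORK,
          outcome_date=None, id="e1"):
    return SAEpisode(id, CalendarInterval(start, end), code, outcome, outcome_date)


class TestPersonalWindow:
    def test_sixtieth_birthday_truncates(self, window):
        assert personal_window(emp(D(1955, 1, 15)), window) == CalendarInterval(
            D(2012, 4, 1), D(2015, 1, 15)
        )

    def test_twentieth_birthday_starts_the_clock(self, window):
        assert personal_window(emp(D(1994, 6, 1)), window) == CalendarInterval(
            D(2014, 6, 1), D(2018, 3, 31)
        )

    def test_mid_career_employee_gets_the_full_window(self, window):
        assert personal_window(emp(D(1980, 1, 1)), window) == window.window

    def test_outside_working_age_is_empty(self, window):
        assert personal_window(emp(D(1940, 1, 1)), window).is_empty
        assert personal_window(emp(D(2005, 1, 1)), window).is_empty


class TestFilterLTSA:
    def test_threshold_is_inclusive(self):
        short = spell(D(2013, 1, 1), D(2013, 1, 30))   # 29 days
        exact = spell(D(2013, 1, 1), D(2013, 1, 31))   # 30 days
        assert filter_ltsa([short, exact]) == [exact]

    def test_filter_applies_to_the_raw_spell_then_clipping(self, window):
        # 45 raw days, only the last 10 inside the window
        ep = spell(D(2012, 2, 26), D(2012, 4, 11))
        assert ep.span.days == 45
        kept = filter_ltsa([ep])
        assert kept == [ep]
        pb = person_burden(emp(D(1980, 1, 1)), kept, w=window)
        assert pb.total_years() == pytest.approx(10 / YEAR)

    def test_min_days_must_be_positive(self):
        with pytest.raises(ValueError):
            filter_ltsa([], min_days=0)


class TestMergeEpisodes:
    def test_disjoint_spells_preserved(self):
        a = spell(D(2013, 1, 1), D(2013, 2, 10))
        b = spell(D(2013, 6, 1), D(2013, 7, 21))
        merged = merge_episodes([b, a])
        assert [m.span for m in merged] == [a.span, b.span]
        assert sum(m.span.days for m in merged) == 90

    def test_abutting_same_group_spells_fuse(self):
        a = spell(D(2013, 1, 1), D(2013, 2, 1))
        b = spell(D(2013, 2, 1), D(2013, 3, 1), code="F41")  # same group
        (m,) = merge_episodes([a, b])
        assert m.span == CalendarInterval(D(2013, 1, 1), D(2013, 3, 1))

    def test_overlap_keeps_terminal_outcome(self):
        a = spell(D(2013, 1, 1), D(2013, 3, 1))
        b = spell(D(2013, 2, 1), D(2013, 4, 1), outcome=Outcome.DEATH)
        (m,) = merge_episodes([a, b])
        assert m.outcome is Outcome.DEATH
        assert m.resolved_outcome_date == D(2013, 4, 1)

    def test_conflicting_diagnoses_raise(self):
        a = spell(D(2013, 1, 1), D(2013, 3, 1), code="F32")
        b = spell(D(2013, 2, 1), D(2013, 4, 1), code="C50")
        with pytest.raises(DataIntegrityError, match="e1"):
            merge_episodes([a, b])

    def test_merged_days_never_exceed_input_days(self):
        a = spell(D(2013, 1, 1), D(2013, 3, 1))
        b = spell(D(2013, 2, 1), D(2013, 4, 1))
        merged = merge_episodes([a, b])
        assert sum(m.span.days for m in merged) <= a.span.days + b.span.days


class TestPersonBurden:
    def test_return_to_work_counts_only_absence_days(self, window):
        # 60-day spell fully inside the window
        pb = person_burden(
            emp(D(1980, 1, 1)), [spell(D(2013, 1, 1), D(2013, 3, 2))], w=window
        )
        by = pb.years_by_consequence()
        assert by[Consequence.SA] == pytest.approx(60 / YEAR)
        assert Consequence.MORTALITY not in by
        assert Consequence.RETIREMENT not in by

    def test_direct_death_counts_to_window_end(self, window):
        pb = person_burden(
            emp(D(1980, 1, 1)), [],
            [DeathEvent("e1", D(2015, 4, 1), "I21")], w=window,
        )
        by = pb.years_by_consequence()
        assert by[Consequence.MORTALITY] == pytest.approx(1095 / YEAR)
        assert pb.contributions[0].disease_group == (
            "Diseases of the circulatory system"
        )

    def test_retirement_handoff_and_sixtieth_birthday(self, window):
        # spell Jan-Jul 2017, retirement Jul 1, 60th birthday Oct 1 2017
        e = emp(D(1957, 10, 1))
        ep = spell(
            D(2017, 1, 1), D(2017, 7, 1),
            outcome=Outcome.ILL_HEALTH_RETIREMENT, outcome_date=D(2017, 7, 1),
        )
        by = person_burden(e, [ep], w=window).years_by_consequence()
        assert by[Consequence.SA] == pytest.approx(181 / YEAR)
        assert by[Consequence.RETIREMENT] == pytest.approx(92 / YEAR)

    def test_no_events_no_burden(self, window):
        assert person_burden(emp(D(1980, 1, 1)), [], w=window).contributions == ()

    def test_death_on_sixtieth_birthday_contributes_nothing(self, window):
        e = emp(D(1956, 4, 1))
        pb = person_burden(e, [], [DeathEvent("e1", D(2016, 4, 1), "I21")], w=window)
        assert pb.total_years() == 0.0

    def test_spell_ending_on_window_start_contributes_nothing(self, window):
        pb = person_burden(
            emp(D(1980, 1, 1)), [spell(D(2012, 2, 1), D(2012, 4, 1))], w=window
        )
        assert pb.total_years() == 0.0

    def test_death_certificate_refines_the_cause(self, window):
        ep = spell(D(2014, 1, 1), D(2014, 6, 1), code="F32", outcome=Outcome.DEATH)
        pb = person_burden(
            emp(D(1980, 1, 1)), [ep],
            [DeathEvent("e1", D(2014, 6, 1), "X70")], w=window,
        )
        mort = [c for c in pb.contributions if c.consequence is Consequence.MORTALITY]
        assert mort[0].disease_group == "Intentional self-harm"

    def test_death_before_spell_start_is_an_error(self, window):
        eps = [spell(D(2015, 1, 1), D(2015, 6, 1))]
        with pytest.raises(DataIntegrityError, match="precedes"):
            person_burden(
                emp(D(1980, 1, 1)), eps,
                [DeathEvent("e1", D(2014, 1, 1), "I21")], w=window,
            )

    def test_retirement_and_death_together_are_an_error(self, window):
        ep = spell(
            D(2014, 1, 1), D(2014, 6, 1),
            outcome=Outcome.ILL_HEALTH_RETIREMENT,
        )
        with pytest.raises(DataIntegrityError, match="both"):
            person_burden(
                emp(D(1980, 1, 1)), [ep],
                [DeathEvent("e1", D(2015, 1, 1), "I21")], w=window,
            )

    def test_foreign_event_is_a_referential_error(self, window):
        with pytest.raises(ReferentialIntegrityError):
            person_burden(
                emp(D(1980, 1, 1)),
                [spell(D(2013, 1, 1), D(2013, 3, 1), id="someone-else")],
                w=window,
            )


class TestOracleAndInvariants:
    def test_matches_day_by_day_oracle(self, window):
        rng = np.random.default_rng(20240)
        for i in range(300):
            e, eps, deaths = random_case(rng, i)
            got = burden_day_counts(person_burden(e, eps, deaths, window))
            want = day_by_day_burden(e, eps, deaths, window)
            assert got == want, f"case {i}: {got} != {want}"

    def test_consequence_day_sets_are_disjoint(self, window):
        # day labels are single-valued, so summed day counts can never
        # exceed the personal window length
        rng = np.random.default_rng(7)
        for i in range(200):
            e, eps, deaths = random_case(rng, i)
            pb = person_burden(e, eps, deaths, window)
            p = personal_window(e, window)
            total_days = sum(c.span.days for c in pb.contributions)
            assert total_days <= p.days
            assert all(c.years_lost >= 0 for c in pb.contributions)

    def test_window_enlargement_never_decreases_burden(self, window):
        big = ObservationWindow(
            CalendarInterval(D(2011, 4, 1), D(2019, 3, 31))
        )
        rng = np.random.default_rng(99)
        for i in range(200):
            e, eps, deaths = random_case(rng, i)
            small = burden_day_counts(person_burden(e, eps, deaths, window))
            large = burden_day_counts(person_burden(e, eps, deaths, big))
            for key, days in small.items():
                assert large.get(key, 0) >= days
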