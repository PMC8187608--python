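"""Shared fixtures: a brute-force day-by-day burden oracle and a generator
of randomized (but always valid) employee case histories."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from workburden import (
    CalendarInterval,
    Consequence,
    DeathEvent,
    Employee,
    ObservationWindow,
    Outcome,
    SAEpisode,
    Sex,
    assign_group,
    filter_ltsa,
    merge_episodes,
)

CODES = ["F32", "C50", "I21", "M54", "X70"]


@pytest.fixture
def window() -> ObservationWindow:
    return ObservationWindow()


def day_by_day_burden(emp, episodes, deaths, w, group_of=assign_group):
    """Independent oracle: label every day of the personal window as
    {none, sa, mortality, retirement} and count days per (group,
    consequence).  Iterates calendar days; no interval arithmetic."""
    from workburden import personal_window

    p = personal_window(emp, w)

    terminal = None  # (date, consequence, group)
    term_eps = [ep for ep in episodes if ep.outcome.is_terminal]
    assert len(term_eps) <= 1 and len(deaths) <= 1
    if term_eps:
        ep = term_eps[0]
        date = ep.outcome_date if ep.outcome_date is not None else ep.span.end
        if ep.outcome is Outcome.DEATH:
            cause = deaths[0].cause if deaths else ep.diagnosis
            terminal = (date, Consequence.MORTALITY, group_of(cause))
        else:
            terminal = (date, Consequence.RETIREMENT, group_of(ep.diagnosis))
    elif deaths:
        terminal = (deaths[0].date, Consequence.MORTALITY, group_of(deaths[0].cause))

    counts: dict[tuple[str, Consequence], int] = {}
    for day in p.iter_days():
        if terminal is not None and day >= terminal[0]:
            key = (terminal[2], terminal[1])
        else:
            covering = [ep for ep in episodes if day in ep.span]
            if not covering:
                continue
            key = (group_of(covering[0].diagnosis), Consequence.SA)
        counts[key] = counts.get(key, 0) + 1
    return counts


def burden_day_counts(pb) -> dict:
    """Day counts per (group, consequence) from a PersonBurden."""
    out: dict[tuple[str, Consequence], int] = {}
    for c in pb.contributions:
        key = (c.disease_group, c.consequence)
        out[key] = out.get(key, 0) + c.span.days
    return out


def random_case(rng: np.random.Generator, i: int):
    """One random, internally consistent employee history.

    Returns (employee, prepared_episodes, deaths) where the episodes have
    already been long-term-filtered and merged, i.e. they satisfy the
    person_burden preconditions.  Spells and deaths are placed so that
    window edges, the 20th/60th birthdays, terminal handoffs and straddling
    spells all occur with useful frequency.
    """
    birth = dt.date(1952, 1, 1) + dt.timedelta(days=int(rng.integers(0, 46 * 365)))
    emp = Employee(
        f"R{i:05d}",
        Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
        birth,
    )
    episodes: list[SAEpisode] = []
    deaths: list[DeathEvent] = []

    cursor = dt.date(2010, 6, 1).toordinal() + int(rng.integers(0, 2800))
    for _ in range(int(rng.integers(0, 4))):
        start = cursor + int(rng.integers(0, 250))
        duration = int(rng.integers(1, 500))
        end = start + duration
        episodes.append(
            SAEpisode(
                emp.id,
                CalendarInterval(
                    dt.date.fromordinal(start), dt.date.fromordinal(end)
                ),
                CODES[int(rng.integers(0, len(CODES)))],
            )
        )
        cursor = end + int(rng.integers(1, 300))

    r = rng.random()
    if episodes and r < 0.35:
        last = episodes[-1]
        outcome = (
            Outcome.DEATH if r < 0.175 else Outcome.ILL_HEALTH_RETIREMENT
        )
        back = int(rng.integers(0, last.span.days))
        episodes[-1] = SAEpisode(
            last.employee_id,
            last.span,
            last.diagnosis,
            outcome,
            outcome_date=last.span.end - dt.timedelta(days=back),
        )
    elif r < 0.5:
        # direct death strictly after every spell start
        death_day = cursor + int(rng.integers(0, 600))
        deaths.append(
            DeathEvent(
                emp.id,
                dt.date.fromordinal(death_day),
                CODES[int(rng.integers(0, len(CODES)))],
            )
        )

    prepared = merge_episodes(filter_ltsa(episodes))
    # the long-term filter may have dropped the terminal spell entirely
    return emp, prepared, deaths
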