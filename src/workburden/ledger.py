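"""Per-person working-life-years-lost accounting.

An employee loses working life to three mutually exclusive consequences:

* **sickness absence** — days inside a medically certified long-term
  absence spell;
* **mortality** — days from the date of death to the end of the personal
  observation window;
* **retirement** — days from the date of ill-health retirement to the end
  of the personal observation window.

Every event is clipped against the *personal window*: the intersection of
the study observation window with the employee's working-age span (20th to
60th birthday).  All spans are half-open ``[start, end)``, so a day is never
counted twice: absence days run strictly before the terminal (death or
retirement) date, and the terminal consequence starts on that date.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from dateutil.relativedelta import relativedelta

from .exceptions import DataIntegrityError, ReferentialIntegrityError
from .icd import assign_group
from .intervals import DAYS_PER_YEAR, CalendarInterval

#: Long-term sickness absence threshold: spells shorter than this many
#: consecutive days are not counted.
DEFAULT_LTSA_DAYS = 30

#: Default study observation window (April 2012 to March 2018, half-open).
DEFAULT_WINDOW_START = dt.date(2012, 4, 1)
DEFAULT_WINDOW_END = dt.date(2018, 3, 31)


class Sex(str, enum.Enum):
    MALE = "M"
    FEMALE = "F"


class Outcome(str, enum.Enum):
    """How a sickness-absence spell ended."""

    RETURN_TO_WORK = "return"
    ILL_HEALTH_RETIREMENT = "retirement"
    DEATH = "death"

    @property
    def is_terminal(self) -> bool:
        return self is not Outcome.RETURN_TO_WORK


class Consequence(str, enum.Enum):
    """The three mutually exclusive ways working life is lost."""

    SA = "sa"
    MORTALITY = "mortality"
    RETIREMENT = "retirement"


@dataclass(frozen=True)
class ObservationWindow:
    """The study window plus the working-age limits.

    The default covers April 2012 to March 2018 with working age 20-59
    (the 60th birthday ends observation).
    """

    window: CalendarInterval = field(
        default_factory=lambda: CalendarInterval(
            DEFAULT_WINDOW_START, DEFAULT_WINDOW_END
        )
    )
    min_age_years: int = 20
    max_age_years: int = 60

    def __post_init__(self) -> None:
        if self.min_age_years >= self.max_age_years:
            raise ValueError("min_age_years must be below max_age_years")
        if self.window.is_empty:
            raise ValueError("observation window must be non-empty")


@dataclass(frozen=True)
class Employee:
    id: str
    sex: Sex
    birth_date: dt.date

    def birthday(self, age_years: int) -> dt.date:
        """The date the employee turns ``age_years`` (Feb 29 clamps to
        Feb 28 in non-leap years)."""
        return self.birth_date + relativedelta(years=age_years)


@dataclass(frozen=True)
class SAEpisode:
    """One certified sickness-absence spell.

    ``outcome_date`` is required to lie within ``[span.start, span.end]``;
    for terminal outcomes it defaults to the spell end (the spell hands over
    to the terminal consequence with zero gap).
    """

    employee_id: str
    span: CalendarInterval
    diagnosis: str
    outcome: Outcome = Outcome.RETURN_TO_WORK
    outcome_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.span.is_empty:
            raise ValueError(
                f"employee {self.employee_id}: empty SA span at {self.span.start}"
            )
        if self.outcome_date is not None and not (
            self.span.start <= self.outcome_date <= self.span.end
        ):
            raise ValueError(
                f"employee {self.employee_id}: outcome date {self.outcome_date} "
                f"outside spell [{self.span.start}, {self.span.end})"
            )

    @property
    def resolved_outcome_date(self) -> dt.date | None:
        """Outcome date, defaulting to the spell end for terminal outcomes."""
        if not self.outcome.is_terminal:
            return None
        return self.outcome_date if self.outcome_date is not None else self.span.end


@dataclass(frozen=True)
class DeathEvent:
    """A death not embedded in (or corroborating) a sickness-absence spell."""

    employee_id: str
    date: dt.date
    cause: str


@dataclass(frozen=True)
class Contribution:
    """One clipped span of lost working life for one employee."""

    disease_group: str
    consequence: Consequence
    span: CalendarInterval

    @property
    def years_lost(self) -> float:
        return self.span.days / DAYS_PER_YEAR


@dataclass(frozen=True)
class PersonBurden:
    """An employee's working-years lost, decomposed by disease group and
    consequence.  Underlying day-spans are kept so strata can later split
    contributions at age boundaries without losing exactness."""

    employee_id: str
    contributions: tuple[Contribution, ...]

    def total_years(self) -> float:
        return sum(c.years_lost for c in self.contributions)

    def years_by_consequence(self) -> dict[Consequence, float]:
        out: dict[Consequence, float] = {}
        for c in self.contributions:
            out[c.consequence] = out.get(c.consequence, 0.0) + c.years_lost
        return out


GroupAssigner = Callable[[str], str]


def personal_window(e: Employee, w: ObservationWindow) -> CalendarInterval:
    """The employee's observable working-age span.

    Intersection of the study window with ``[20th birthday, 60th
    birthday)`` (using the configured age limits).  Empty for employees
    outside working age for the whole window.
    """
    working_age = CalendarInterval(
        e.birthday(w.min_age_years), e.birthday(w.max_age_years)
    )
    return w.window.intersect(working_age)


def filter_ltsa(
    episodes: Iterable[SAEpisode], min_days: int = DEFAULT_LTSA_DAYS
) -> list[SAEpisode]:
    """Keep only long-term spells: raw length >= ``min_days``.

    The threshold applies to the spell as certified, *before* any window
    clipping — a long spell truncated by the window edge is still
    long-term illness.
    """
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    return [ep for ep in episodes if ep.span.days >= min_days]


def merge_episodes(
    episodes: Sequence[SAEpisode], group_of: GroupAssigner = assign_group
) -> list[SAEpisode]:
    """Merge overlapping or abutting spells of the same disease group.

    Spells are sorted by start date.  Overlapping or abutting spells whose
    diagnoses fall in the same disease group are fused into one spell (the
    fused spell keeps the terminal outcome if either part has one).
    Overlapping spells with *different* disease groups are a data-integrity
    error: concurrent conflicting certificates are surfaced, not resolved
    by guesswork.
    """
    eps = sorted(episodes, key=lambda ep: (ep.span.start, ep.span.end))
    if not eps:
        return []
    ids = {ep.employee_id for ep in eps}
    if len(ids) > 1:
        raise DataIntegrityError(f"episodes from several employees: {sorted(ids)}")

    merged: list[SAEpisode] = [eps[0]]
    for ep in eps[1:]:
        prev = merged[-1]
        if ep.span.start < prev.span.end:  # overlap
            if group_of(ep.diagnosis) != group_of(prev.diagnosis):
                raise DataIntegrityError(
                    f"employee {ep.employee_id}: overlapping spells with "
                    f"conflicting diagnoses {prev.diagnosis!r} "
                    f"[{prev.span.start}, {prev.span.end}) and "
                    f"{ep.diagnosis!r} [{ep.span.start}, {ep.span.end})"
                )
            merged[-1] = _fuse(prev, ep)
        elif ep.span.start == prev.span.end and group_of(ep.diagnosis) == group_of(
            prev.diagnosis
        ):
            merged[-1] = _fuse(prev, ep)
        else:
            merged.append(ep)
    return merged


def _fuse(a: SAEpisode, b: SAEpisode) -> SAEpisode:
    if a.outcome.is_terminal and b.outcome.is_terminal:
        raise DataIntegrityError(
            f"employee {a.employee_id}: two terminal outcomes "
            f"({a.outcome.value} and {b.outcome.value}) in overlapping spells"
        )
    terminal = a if a.outcome.is_terminal else b
    outcome = terminal.outcome
    outcome_date = terminal.outcome_date if outcome.is_terminal else None
    return SAEpisode(
        employee_id=a.employee_id,
        span=a.span.hull(b.span),
        diagnosis=a.diagnosis,
        outcome=outcome,
        outcome_date=outcome_date,
    )


def _resolve_terminal(
    e: Employee,
    episodes: Sequence[SAEpisode],
    deaths: Sequence[DeathEvent],
    group_of: GroupAssigner,
) -> tuple[dt.date, Consequence, str] | None:
    """Find the single terminal event: (date, consequence, disease group)."""
    terminals = [ep for ep in episodes if ep.outcome.is_terminal]
    if len(terminals) > 1:
        kinds = ", ".join(t.outcome.value for t in terminals)
        raise DataIntegrityError(
            f"employee {e.id}: multiple terminal events ({kinds})"
        )
    if len(deaths) > 1:
        raise DataIntegrityError(f"employee {e.id}: multiple death records")
    death = deaths[0] if deaths else None
    terminal = terminals[0] if terminals else None

    if terminal is not None and terminal.outcome is Outcome.ILL_HEALTH_RETIREMENT:
        if death is not None:
            raise DataIntegrityError(
                f"employee {e.id}: both ill-health retirement "
                f"({terminal.resolved_outcome_date}) and death ({death.date}) recorded"
            )
        return (
            terminal.resolved_outcome_date,
            Consequence.RETIREMENT,
            group_of(terminal.diagnosis),
        )

    if terminal is not None:  # SA ending in death
        date = terminal.resolved_outcome_date
        if death is not None:
            if death.date != date:
                raise DataIntegrityError(
                    f"employee {e.id}: death certificate date {death.date} "
                    f"conflicts with spell outcome date {date}"
                )
            cause = death.cause  # certificate refines the cause of death
        else:
            cause = terminal.diagnosis
        return date, Consequence.MORTALITY, group_of(cause)

    if death is not None:
        return death.date, Consequence.MORTALITY, group_of(death.cause)
    return None


def person_burden(
    e: Employee,
    episodes: Sequence[SAEpisode],
    deaths: Sequence[DeathEvent] = (),
    w: ObservationWindow | None = None,
    group_of: GroupAssigner = assign_group,
) -> PersonBurden:
    """Clip one employee's events into working-years-lost contributions.

    ``episodes`` must already be long-term-filtered and merged (see
    :func:`filter_ltsa`, :func:`merge_episodes`).  Absence days are counted
    strictly before the terminal date; the terminal consequence runs from
    that date to the end of the personal window.  No calendar day is
    attributed to two consequences.
    """
    w = w or ObservationWindow()
    for ev in list(episodes) + list(deaths):
        if ev.employee_id != e.id:
            raise ReferentialIntegrityError(
                f"event for employee {ev.employee_id!r} passed to {e.id!r}"
            )
    window = personal_window(e, w)
    terminal = _resolve_terminal(e, episodes, deaths, group_of)

    contributions: list[Contribution] = []
    cutoff = terminal[0] if terminal else None
    if cutoff is not None and terminal[1] is Consequence.MORTALITY:
        for ep in episodes:
            if ep.span.start >= cutoff:
                raise DataIntegrityError(
                    f"employee {e.id}: death on {cutoff} precedes SA spell "
                    f"starting {ep.span.start}"
                )

    for ep in episodes:
        span = ep.span if cutoff is None else ep.span.clip_before(cutoff)
        span = span.intersect(window)
        if not span.is_empty:
            contributions.append(
                Contribution(group_of(ep.diagnosis), Consequence.SA, span)
            )

    if terminal is not None:
        date, consequence, group = terminal
        lost = window.clip_from(date)
        if not lost.is_empty:
            contributions.append(Contribution(group, consequence, lost))

    return PersonBurden(e.id, tuple(contributions))
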