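"""Model / Results surface for the working-years-lost analysis.

:class:`WorkingYearsLostModel` is built from cohort data (typed objects,
data frames, or CSV files); :meth:`~WorkingYearsLostModel.fit` runs the
person-time accounting pipeline — long-term filter, spell merging,
per-person clipping, stratified aggregation — and returns a
:class:`WorkingYearsLostResults` carrying the burden table, its confidence
intervals, and comparison/diagnostic helpers.

Example
-------
>>> from workburden import CohortParams, WorkingYearsLostModel, simulate_cohort
>>> cohort = simulate_cohort(CohortParams(n_employees=5000, seed=11))
>>> res = WorkingYearsLostModel.from_frames(
...     cohort.employees, cohort.sa_episodes,
...     cohort.deaths, cohort.headcounts).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import io as wio
from .exceptions import ReferentialIntegrityError
from .icd import assign_group
from .ledger import (
    DeathEvent,
    Employee,
    ObservationWindow,
    PersonBurden,
    SAEpisode,
    filter_ltsa,
    merge_episodes,
    person_burden,
)
from .stats import (
    ALL_CAUSES,
    TOTAL,
    BurdenTable,
    HeadcountTable,
    Stratum,
    build_burden_table,
    compare_strata,
    default_strata,
    share,
)


class WorkingYearsLostModel:
    """Working-life-years-lost burden of an occupational cohort.

    Parameters
    ----------
    employees : mapping or sequence of Employee
        The roster.
    episodes : sequence of SAEpisode
        Certified sickness-absence spells (any length; the long-term
        filter is applied at fit time).
    deaths : sequence of DeathEvent
        Deaths not embedded in a recorded absence spell.
    headcounts : HeadcountTable or DataFrame
        Annual workforce counts (the person-year denominator).
    window : ObservationWindow, optional
        Study window and working-age limits; defaults to April 2012 -
        March 2018, ages 20-59.
    ltsa_min_days : int
        Long-term absence threshold in consecutive days (default 30),
        applied to the raw spell before any clipping.
    strata : sequence of Stratum, optional
        Defaults to the whole cohort plus the four sex x age-group cells.
    unmapped : {"error", "bucket"}
        Policy for ICD-10 codes outside every disease category.
    """

    def __init__(
        self,
        employees: Mapping[str, Employee] | Sequence[Employee],
        episodes: Sequence[SAEpisode],
        deaths: Sequence[DeathEvent] = (),
        headcounts: HeadcountTable | pd.DataFrame | None = None,
        window: ObservationWindow | None = None,
        ltsa_min_days: int = 30,
        strata: Sequence[Stratum] | None = None,
        unmapped: str = "error",
    ):
        self.roster: Mapping[str, Employee] = (
            employees if isinstance(employees, Mapping)
            else {e.id: e for e in employees}
        )
        self.episodes = list(episodes)
        self.deaths = list(deaths)
        if headcounts is None:
            raise ValueError("headcounts are required for the denominator")
        self.headcounts = (
            headcounts
            if isinstance(headcounts, HeadcountTable)
            else HeadcountTable(headcounts)
        )
        self.window = window or ObservationWindow()
        self.ltsa_min_days = ltsa_min_days
        self.strata = list(strata) if strata is not None else default_strata(
            self.window.min_age_years, self.window.max_age_years
        )
        self.group_of = functools.partial(assign_group, unmapped=unmapped)

        unknown = sorted(
            {e.employee_id for e in self.episodes if e.employee_id not in self.roster}
            | {d.employee_id for d in self.deaths if d.employee_id not in self.roster}
        )
        if unknown:
            raise ReferentialIntegrityError(
                f"events reference employees absent from the roster: {unknown}"
            )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_frames(
        cls,
        employees: pd.DataFrame,
        sa_episodes: pd.DataFrame,
        deaths: pd.DataFrame,
        headcounts: pd.DataFrame,
        **kwargs,
    ) -> "WorkingYearsLostModel":
        """Build from data frames in the documented CSV schemas."""
        return cls(
            wio.load_employees(employees),
            wio.load_episodes(sa_episodes),
            wio.load_deaths(deaths),
            wio.load_headcounts(headcounts),
            **kwargs,
        )

    @classmethod
    def from_csv(cls, directory=None, config: wio.RunConfig | None = None,
                 **paths) -> "WorkingYearsLostModel":
        """Build from the four CSV files (see :mod:`workburden.io`)."""
        cohort = wio.read_inputs(directory, **paths)
        kwargs = {}
        if config is not None:
            kwargs = dict(
                window=config.window,
                ltsa_min_days=config.ltsa_min_days,
                unmapped=config.unmapped,
                strata=default_strata(
                    config.min_age, config.max_age, config.age_split
                ),
            )
        return cls(
            cohort.employees, cohort.episodes, cohort.deaths,
            cohort.headcounts, **kwargs,
        )

    # -- fitting ------------------------------------------------------------

    def fit(self, ci_level: float = 0.95) -> "WorkingYearsLostResults":
        """Run the accounting pipeline and return the results object."""
        by_employee: dict[str, list[SAEpisode]] = {}
        for ep in self.episodes:
            by_employee.setdefault(ep.employee_id, []).append(ep)
        deaths_by: dict[str, list[DeathEvent]] = {}
        for d in self.deaths:
            deaths_by.setdefault(d.employee_id, []).append(d)

        burdens: list[PersonBurden] = []
        for emp_id in sorted(set(by_employee) | set(deaths_by)):
            eps = merge_episodes(
                filter_ltsa(by_employee.get(emp_id, []), self.ltsa_min_days),
                group_of=self.group_of,
            )
            pb = person_burden(
                self.roster[emp_id], eps, deaths_by.get(emp_id, ()),
                self.window, group_of=self.group_of,
            )
            if pb.contributions:
                burdens.append(pb)

        table = build_burden_table(
            burdens, self.roster, self.headcounts,
            strata=self.strata, ci_level=ci_level,
        )
        return WorkingYearsLostResults(self, table, burdens, ci_level)


@dataclass
class WorkingYearsLostResults:
    """Fitted burden estimates.

    Attributes
    ----------
    table : BurdenTable
        Stratum x disease group x consequence per-myriad estimates with
        confidence intervals (integer lost-day ledger included).
    person_burdens : list of PersonBurden
        The per-employee decompositions behind the table.
    """

    model: WorkingYearsLostModel
    table: BurdenTable
    person_burdens: list[PersonBurden] = field(repr=False)
    ci_level: float = 0.95

    def denominator(self, stratum: str = "all") -> float:
        df = self.table.data
        return float(df.loc[df["stratum"] == stratum, "denominator"].iloc[0])

    def per_myriad(self, disease_group: str = ALL_CAUSES,
                   consequence: str = TOTAL, stratum: str = "all") -> float:
        return self.table.cell(stratum, disease_group, consequence).per_myriad

    def share(self, disease_group: str, consequence: str = TOTAL,
              stratum: str = "all") -> float:
        """Percentage of the stratum's all-cause burden due to one group."""
        return share(
            self.table.cell(stratum, disease_group, consequence),
            self.table.cell(stratum, ALL_CAUSES, consequence),
        )

    def compare(self, stratum1: str, stratum2: str,
                disease_group: str = ALL_CAUSES,
                consequence: str = TOTAL) -> tuple[float, float]:
        """Chi-squared comparison of the lost-years proportion between two
        strata; returns (statistic, p-value)."""
        a = self.table.cell(stratum1, disease_group, consequence)
        b = self.table.cell(stratum2, disease_group, consequence)
        return compare_strata(a.years_lost, a.denominator,
                              b.years_lost, b.denominator)

    def summary(self, strata: Sequence[str] | None = None) -> str:
        """Aligned-text burden table (per-myriad, ``est (lo, hi)`` cells)."""
        return self.table.to_report(strata=strata)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)
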