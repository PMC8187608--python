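"""Readers, writers and run configuration.

Input schemas (UTF-8 CSV, header row required, dates ISO 8601):

* ``employees.csv`` — id, sex (M/F), birth_date
* ``sa_episodes.csv`` — employee_id, start_date, end_date (exclusive),
  icd10_code, outcome (return/retirement/death), outcome_date (optional)
* ``deaths.csv`` — employee_id, date, icd10_code
* ``headcounts.csv`` — year, sex, age_band (e.g. "40-44"), count

Spell end dates are *exclusive* (half-open spans), matching the package's
interval convention.  Unknown columns are ignored with a logged warning;
row-level validation problems are collected with their line numbers and
reported together before aborting.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import ReferentialIntegrityError, SchemaError
from .intervals import CalendarInterval
from .ledger import (
    DEFAULT_LTSA_DAYS,
    DEFAULT_WINDOW_END,
    DEFAULT_WINDOW_START,
    DeathEvent,
    Employee,
    ObservationWindow,
    Outcome,
    SAEpisode,
    Sex,
)
from .stats import HeadcountTable

logger = logging.getLogger("workburden")


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings (defaults mirror the 6-year study design:
    April 2012 - March 2018 window, working age 20-59, 30-day long-term
    absence threshold, 95% confidence level)."""

    window_start: dt.date = DEFAULT_WINDOW_START
    window_end: dt.date = DEFAULT_WINDOW_END
    min_age: int = 20
    max_age: int = 60
    age_split: int = 40
    ltsa_min_days: int = DEFAULT_LTSA_DAYS
    ci_level: float = 0.95
    unmapped: str = "error"  # or "bucket"

    def __post_init__(self) -> None:
        if self.ltsa_min_days < 1:
            raise ValueError("ltsa_min_days must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.unmapped not in ("error", "bucket"):
            raise ValueError("unmapped must be 'error' or 'bucket'")
        if not self.min_age < self.age_split < self.max_age:
            raise ValueError("need min_age < age_split < max_age")

    @property
    def window(self) -> ObservationWindow:
        return ObservationWindow(
            CalendarInterval(self.window_start, self.window_end),
            self.min_age,
            self.max_age,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window_start", "window_end"):
            if key in raw and not isinstance(raw[key], dt.date):
                raw[key] = _parse_date(raw[key])
        return cls(**raw)


class _RowErrors:
    """Collects row-level validation problems so a dirty file is reported
    in one pass instead of failing at the first bad row."""

    def __init__(self, filename: str):
        self.filename = filename
        self.messages: list[str] = []

    def add(self, line: int, message: str) -> None:
        self.messages.append(f"{self.filename}:{line}: {message}")

    def raise_if_any(self) -> None:
        if self.messages:
            raise SchemaError(
                f"{len(self.messages)} invalid row(s):\n" + "\n".join(self.messages)
            )


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    return dt.date.fromisoformat(str(value).strip())


def _read_csv(path, required: list[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"missing input file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} ({path}) missing columns: {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, extra)
    return df[required]


def load_employees(source) -> dict[str, Employee]:
    """Read the roster into a dict keyed by employee id."""
    df = (
        source
        if isinstance(source, pd.DataFrame)
        else _read_csv(source, ["id", "sex", "birth_date"], "employees")
    )
    errors = _RowErrors("employees")
    roster: dict[str, Employee] = {}
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            emp = Employee(str(row.id), Sex(row.sex), _parse_date(row.birth_date))
        except (ValueError, KeyError) as exc:
            errors.add(pos, str(exc))
            continue
        if emp.id in roster:
            errors.add(pos, f"duplicate employee id {emp.id!r}")
        roster[emp.id] = emp
    errors.raise_if_any()
    return roster


def load_episodes(source) -> list[SAEpisode]:
    cols = ["employee_id", "start_date", "end_date", "icd10_code",
            "outcome", "outcome_date"]
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = _read_csv(source, cols, "sa_episodes")
    errors = _RowErrors("sa_episodes")
    episodes: list[SAEpisode] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            outcome_date = (
                _parse_date(row.outcome_date)
                if str(row.outcome_date).strip() not in ("", "nan")
                else None
            )
            episodes.append(
                SAEpisode(
                    employee_id=str(row.employee_id),
                    span=CalendarInterval(
                        _parse_date(row.start_date), _parse_date(row.end_date)
                    ),
                    diagnosis=str(row.icd10_code),
                    outcome=Outcome(row.outcome),
                    outcome_date=outcome_date,
                )
            )
        except ValueError as exc:
            errors.add(pos, str(exc))
    errors.raise_if_any()
    return episodes


def load_deaths(source) -> list[DeathEvent]:
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = _read_csv(source, ["employee_id", "date", "icd10_code"], "deaths")
    errors = _RowErrors("deaths")
    deaths: list[DeathEvent] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            deaths.append(
                DeathEvent(str(row.employee_id), _parse_date(row.date),
                           str(row.icd10_code))
            )
        except ValueError as exc:
            errors.add(pos, str(exc))
    errors.raise_if_any()
    return deaths


def load_headcounts(source) -> HeadcountTable:
    if isinstance(source, pd.DataFrame):
        return HeadcountTable(source)
    df = _read_csv(source, ["year", "sex", "age_band", "count"], "headcounts")
    return HeadcountTable(df)


@dataclass
class Cohort:
    """Validated in-memory cohort ready for the accounting pipeline."""

    employees: dict[str, Employee]
    episodes: list[SAEpisode]
    deaths: list[DeathEvent]
    headcounts: HeadcountTable


def read_inputs(
    directory=None,
    employees=None,
    sa_episodes=None,
    deaths=None,
    headcounts=None,
) -> Cohort:
    """Read and cross-validate the four input files.

    Either pass ``directory`` containing the conventionally named files, or
    the four paths explicitly.  Every episode and death must reference a
    rostered employee; violations are reported together.
    """
    if directory is not None:
        d = Path(directory)
        employees = employees or d / "employees.csv"
        sa_episodes = sa_episodes or d / "sa_episodes.csv"
        deaths = deaths or d / "deaths.csv"
        headcounts = headcounts or d / "headcounts.csv"
    roster = load_employees(employees)
    eps = load_episodes(sa_episodes)
    dths = load_deaths(deaths)
    counts = load_headcounts(headcounts)

    unknown = sorted(
        {e.employee_id for e in eps if e.employee_id not in roster}
        | {d.employee_id for d in dths if d.employee_id not in roster}
    )
    if unknown:
        raise ReferentialIntegrityError(
            f"events reference employees absent from the roster: {unknown}"
        )
    logger.info(
        "read %d employees, %d SA episodes, %d deaths, %d headcount rows",
        len(roster), len(eps), len(dths), len(counts.data),
    )
    return Cohort(roster, eps, dths, counts)
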