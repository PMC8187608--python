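"""Aggregation of person burdens into per-myriad rates with confidence
intervals, the stratified burden table, and stratum comparisons.

The burden of a disease group is expressed *per myriad*: person-years of
working life lost per 10,000 person-years of working time.  The denominator
comes from annual headcounts by sex and 5-year age band, each annual count
contributing one person-year per head.  Confidence intervals treat the
person-years lost as a Poisson count ``c`` and use the normal approximation
``(c - z sqrt(c), c + z sqrt(c)) / denominator * 10,000`` with the lower
bound floored at zero.

Internally every cell of the burden table is an integer count of lost
calendar *days*, so the decomposition identities (consequences sum to the
total, disease groups sum to the all-cause row, sex-age strata sum to the
whole cohort) hold exactly before any rounding; days are converted to years
(/365.25) only when rates are computed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataIntegrityError, SchemaError
from .icd import default_group_table
from .intervals import DAYS_PER_YEAR, CalendarInterval
from .ledger import Consequence, Employee, PersonBurden, Sex

MYRIAD = 10_000.0

#: Pseudo-group label for the all-cause row of a burden table.
ALL_CAUSES = "All causes"

#: Column holding the consequence total in a burden table.
TOTAL = "total"

_BAND_RE = re.compile(r"^(\d+)\s*-\s*(\d+)$")


# ---------------------------------------------------------------------------
# strata


@dataclass(frozen=True)
class Stratum:
    """A sub-population: optional sex and half-open age range ``[lo, hi)``."""

    label: str
    sex: Sex | None = None
    age_lo: int | None = None
    age_hi: int | None = None

    @property
    def is_marginal(self) -> bool:
        return self.sex is None and self.age_lo is None


ALL_STRATUM = Stratum("all")


def default_strata(min_age: int = 20, max_age: int = 60, split: int = 40):
    """The whole cohort plus the four sex x age-group cells
    (20-39 / 40-59 by default)."""
    strata = [ALL_STRATUM]
    for sex in (Sex.MALE, Sex.FEMALE):
        for lo, hi in ((min_age, split), (split, max_age)):
            strata.append(Stratum(f"{sex.value} {lo}-{hi - 1}", sex, lo, hi))
    return strata


# ---------------------------------------------------------------------------
# headcounts / denominators


class HeadcountTable:
    """Annual workforce counts by year x sex x 5-year age band.

    Each row contributes ``count`` person-years to the denominator of its
    stratum (one person-year per head per annual census).
    """

    def __init__(self, data: pd.DataFrame):
        required = {"year", "sex", "age_band", "count"}
        missing = required - set(data.columns)
        if missing:
            raise SchemaError(f"headcount table missing columns: {sorted(missing)}")
        df = data.copy()
        df["year"] = df["year"].astype(int)
        df["sex"] = df["sex"].map(lambda s: Sex(s).value)
        df["count"] = df["count"].astype(int)
        if (df["count"] < 0).any():
            raise DataIntegrityError("negative headcount")
        bands = df["age_band"].map(_parse_band)
        df["age_lo"] = [b[0] for b in bands]
        df["age_hi"] = [b[1] for b in bands]
        if df.duplicated(["year", "sex", "age_band"]).any():
            dups = df[df.duplicated(["year", "sex", "age_band"], keep=False)]
            raise DataIntegrityError(
                f"duplicate headcount rows: {dups[['year', 'sex', 'age_band']].values.tolist()}"
            )
        self.data = df

    def person_years(self, stratum: Stratum = ALL_STRATUM) -> float:
        """Person-year denominator for a stratum (sum of annual counts)."""
        df = self.data
        if stratum.sex is not None:
            df = df[df["sex"] == stratum.sex.value]
        if stratum.age_lo is not None:
            inside = (df["age_lo"] >= stratum.age_lo) & (df["age_hi"] <= stratum.age_hi)
            straddle = ~inside & (df["age_lo"] < stratum.age_hi) & (
                df["age_hi"] > stratum.age_lo
            )
            if straddle.any():
                raise DataIntegrityError(
                    f"age band straddles stratum {stratum.label}: "
                    f"{df.loc[straddle, 'age_band'].unique().tolist()}"
                )
            df = df[inside]
        if df.empty:
            raise DataIntegrityError(f"no headcount rows for stratum {stratum.label!r}")
        return float(df["count"].sum())


def _parse_band(text: str) -> tuple[int, int]:
    m = _BAND_RE.match(str(text).strip())
    if m is None:
        raise SchemaError(f"unparseable age band {text!r} (expected e.g. '40-44')")
    lo, hi = int(m.group(1)), int(m.group(2)) + 1  # "40-44" covers ages 40..44
    if hi <= lo:
        raise SchemaError(f"inverted age band {text!r}")
    return lo, hi


def person_year_denominator(
    headcounts: HeadcountTable | pd.DataFrame, stratum: Stratum = ALL_STRATUM
) -> float:
    """Person-year denominator for a stratum from annual headcounts."""
    if not isinstance(headcounts, HeadcountTable):
        headcounts = HeadcountTable(headcounts)
    return headcounts.person_years(stratum)


# ---------------------------------------------------------------------------
# rates and intervals


def per_myriad(years_lost: float, denominator: float) -> float:
    """Person-years lost per 10,000 person-years of working time."""
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    if years_lost < 0:
        raise ValueError(f"years_lost must be non-negative, got {years_lost}")
    return years_lost / denominator * MYRIAD


def rate_ci(
    years_lost: float, denominator: float, level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation Poisson interval for a per-myriad burden.

    The person-years lost are treated as a Poisson count ``c``; the bounds
    are ``(c - z sqrt(c), c + z sqrt(c)) / denominator * 10,000`` with the
    lower bound floored at zero.  ``years_lost = 0`` degenerates to (0, 0).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    half = z * np.sqrt(years_lost)
    lo = max(years_lost - half, 0.0) / denominator * MYRIAD
    hi = (years_lost + half) / denominator * MYRIAD
    return lo, hi


def share(group, total) -> float:
    """Percentage share of one burden estimate in another.

    Accepts per-myriad floats or :class:`BurdenEstimate` objects.
    """
    g = getattr(group, "per_myriad", group)
    t = getattr(total, "per_myriad", total)
    if t <= 0:
        raise ValueError("total burden must be positive to compute a share")
    return g / t * 100.0


def compare_strata(
    lost1: float, denom1: float, lost2: float, denom2: float
) -> tuple[float, float]:
    """Chi-squared test (1 df, no continuity correction) comparing the
    proportion of working years lost between two strata.

    Person-years are rounded to whole counts to form the 2x2 table of
    years lost vs years not lost.
    """
    table = np.array(
        [
            [round(lost1), round(denom1 - lost1)],
            [round(lost2), round(denom2 - lost2)],
        ]
    )
    if (table < 0).any():
        raise ValueError("years lost exceed the denominator")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table: a margin is zero")
    if (table[:, 0] == 0).all() or (table[:, 1] == 0).all():
        raise ValueError("degenerate 2x2 table: a margin is zero")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# the burden table


@dataclass(frozen=True)
class BurdenEstimate:
    """One cell of a burden table: years lost, denominator, per-myriad rate
    and its confidence bounds."""

    years_lost: float
    denominator: float
    per_myriad: float
    ci_low: float
    ci_high: float


_COLUMNS = [
    "stratum",
    "disease_group",
    "consequence",
    "days_lost",
    "years_lost",
    "denominator",
    "per_myriad",
    "ci_low",
    "ci_high",
]

_CONSEQUENCES = [Consequence.SA.value, Consequence.MORTALITY.value,
                 Consequence.RETIREMENT.value, TOTAL]


@dataclass
class BurdenTable:
    """Stratum x disease group x consequence matrix of burden estimates.

    ``data`` is a long-format frame with one row per cell; ``days_lost`` is
    the exact integer ledger from which all rates derive.
    """

    data: pd.DataFrame
    ci_level: float = 0.95

    def cell(self, stratum: str, disease_group: str, consequence: str) -> BurdenEstimate:
        df = self.data
        row = df[
            (df["stratum"] == stratum)
            & (df["disease_group"] == disease_group)
            & (df["consequence"] == consequence)
        ]
        if row.empty:
            raise KeyError((stratum, disease_group, consequence))
        r = row.iloc[0]
        return BurdenEstimate(
            years_lost=float(r["years_lost"]),
            denominator=float(r["denominator"]),
            per_myriad=float(r["per_myriad"]),
            ci_low=float(r["ci_low"]),
            ci_high=float(r["ci_high"]),
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, ci_level: float = 0.95) -> "BurdenTable":
        df = pd.read_csv(path)
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"burden table missing columns: {sorted(missing)}")
        return cls(df[_COLUMNS], ci_level=ci_level)

    # -- presentation -------------------------------------------------------

    def to_report(self, strata: Sequence[str] | None = None) -> str:
        """Aligned-text report, one section per stratum.

        Rows are disease groups ordered by descending total burden;
        columns are Total, Sickness absence, Mortality, Ill health
        retirement, with ``est (lo, hi)`` cells rounded to one decimal.
        The renderer only formats numbers, it never changes them.
        """
        if strata is None:
            strata = list(dict.fromkeys(self.data["stratum"]))
        headers = ["Disease category", "Total", "Sickness absence",
                   "Mortality", "Ill health retirement"]
        order = [TOTAL, Consequence.SA.value, Consequence.MORTALITY.value,
                 Consequence.RETIREMENT.value]
        sections = []
        for stratum in strata:
            df = self.data[self.data["stratum"] == stratum]
            denom = float(df["denominator"].iloc[0])
            totals = (
                df[(df["consequence"] == TOTAL) & (df["disease_group"] != ALL_CAUSES)]
                .sort_values("per_myriad", ascending=False)
            )
            rows = []
            for group in list(totals["disease_group"]) + [ALL_CAUSES]:
                cells = [group if group != ALL_CAUSES else "Total"]
                for cons in order:
                    est = self.cell(stratum, group, cons)
                    cells.append(
                        f"{est.per_myriad:.1f} ({est.ci_low:.1f}, {est.ci_high:.1f})"
                    )
                rows.append(cells)
            widths = [
                max(len(h), *(len(r[i]) for r in rows))
                for i, h in enumerate(headers)
            ]
            lines = [
                f"Stratum: {stratum}   (denominator {denom:,.0f} person-years; "
                f"per 10,000 person-years, {self.ci_level:.0%} CI)",
                "  ".join(h.ljust(w) for h, w in zip(headers, widths)).rstrip(),
                "  ".join("-" * w for w in widths),
            ]
            for r in rows:
                lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip())
            sections.append("\n".join(lines))
        return ("\n\n".join(sections)) + "\n"


def build_burden_table(
    burdens: Iterable[PersonBurden],
    roster: Mapping[str, Employee] | Sequence[Employee],
    headcounts: HeadcountTable | pd.DataFrame,
    strata: Sequence[Stratum] | None = None,
    ci_level: float = 0.95,
    groups: Sequence[str] | None = None,
) -> BurdenTable:
    """Aggregate person burdens into the stratified burden table.

    Burden days are assigned to the age stratum the employee occupies on
    each day (a person crossing the age split mid-window contributes to
    both cells), so the stratum partition of the whole-cohort burden is
    exact.
    """
    if not isinstance(headcounts, HeadcountTable):
        headcounts = HeadcountTable(headcounts)
    if not isinstance(roster, Mapping):
        roster = {e.id: e for e in roster}
    if strata is None:
        strata = default_strata()
    if groups is None:
        groups = list(default_group_table().labels)

    days: dict[tuple[str, str, str], int] = {}
    seen_groups = set(groups)
    for pb in burdens:
        emp = roster.get(pb.employee_id)
        if emp is None:
            raise DataIntegrityError(
                f"person burden for employee {pb.employee_id!r} not on the roster"
            )
        for contrib in pb.contributions:
            seen_groups.add(contrib.disease_group)
            for stratum in strata:
                span = _restrict(contrib.span, emp, stratum)
                if span.days <= 0:
                    continue
                key = (stratum.label, contrib.disease_group,
                       contrib.consequence.value)
                days[key] = days.get(key, 0) + span.days

    group_list = [g for g in groups] + sorted(seen_groups - set(groups))
    records = []
    for stratum in strata:
        denom = headcounts.person_years(stratum)
        all_cause = {c: 0 for c in _CONSEQUENCES}
        for group in group_list:
            cons_days = {
                c: days.get((stratum.label, group, c), 0)
                for c in _CONSEQUENCES[:3]
            }
            cons_days[TOTAL] = sum(cons_days.values())
            for c in _CONSEQUENCES:
                all_cause[c] += cons_days[c]
                records.append(
                    _record(stratum.label, group, c, cons_days[c], denom, ci_level)
                )
        for c in _CONSEQUENCES:
            records.append(
                _record(stratum.label, ALL_CAUSES, c, all_cause[c], denom, ci_level)
            )
    return BurdenTable(pd.DataFrame.from_records(records, columns=_COLUMNS),
                       ci_level=ci_level)


def _record(stratum, group, consequence, days_lost, denom, level):
    years = days_lost / DAYS_PER_YEAR
    lo, hi = rate_ci(years, denom, level)
    return {
        "stratum": stratum,
        "disease_group": group,
        "consequence": consequence,
        "days_lost": days_lost,
        "years_lost": years,
        "denominator": denom,
        "per_myriad": per_myriad(years, denom),
        "ci_low": lo,
        "ci_high": hi,
    }


def _restrict(span: CalendarInterval, emp: Employee, stratum: Stratum) -> CalendarInterval:
    if stratum.sex is not None and emp.sex is not stratum.sex:
        return CalendarInterval(span.start, span.start)
    if stratum.age_lo is None:
        return span
    age_span = CalendarInterval(
        emp.birthday(stratum.age_lo), emp.birthday(stratum.age_hi)
    )
    return span.intersect(age_span)
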