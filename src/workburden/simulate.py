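"""Seeded synthetic occupational cohorts with known burden rates.

The generator emulates the record structure of a multi-company
occupational cohort: an employee roster (sex, birth date), long-term
sickness-absence spells with an ICD-10 diagnosis and an outcome
(return-to-work, ill-health retirement, or death), deaths not preceded by a
recorded long-term absence (the death-certificate path), and annual
headcounts by sex and 5-year age band.

Per employee, absence onsets follow a homogeneous Poisson process over the
personal working-age window; each onset draws a disease group (categorical
by rate share), a log-normal duration in days, and an outcome.  A new spell
cannot start while a previous one is running (such onsets are discarded),
so overlapping conflicting certificates never occur by construction.  The
first terminal outcome censors all later events.  Spells may straddle the
observation window and the 60th birthday by construction, so the boundary
clipping rules are exercised with realistic frequency.

A spell shorter than the 30-day long-term threshold whose outcome is death
is emitted through the death-certificate path instead (the absence itself
is too short to be recorded); a short spell ending in retirement leaves the
workforce silently, which only the headcounts see.  Direct deaths are drawn
independently (exponential waiting time) for employees with no terminal
spell.

Identical seeds give identical output tables.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import DAYS_PER_YEAR
from .ledger import DEFAULT_LTSA_DAYS, ObservationWindow

#: A representative three-character code per disease category, used when a
#: simulated event needs a concrete ICD-10 code for its group.
REPRESENTATIVE_CODE: dict[str, str] = {
    "Mental and behavioural disorders": "F32",
    "Neoplasms": "C50",
    "Diseases of the circulatory system": "I21",
    "External causes/injuries except intentional self-harm": "S72",
    "Diseases of the musculoskeletal system and connective tissue": "M54",
    "Intentional self-harm": "X70",
    "Diseases of the nervous system": "G40",
    "Diseases of the digestive system": "K80",
    "Symptoms, signs and abnormal clinical and laboratory findings, not elsewhere classified": "R53",
    "Pregnancy, childbirth and the puerperium": "O21",
    "Diseases of the respiratory system": "J45",
    "Endocrine, nutritional and metabolic diseases": "E11",
    "Diseases of the genitourinary system": "N18",
    "Diseases of the eye and adnexa": "H35",
    "Diseases of the ear and mastoid process": "H81",
    "Certain infectious and parasitic diseases": "A41",
    "Diseases of the skin and subcutaneous tissue": "L40",
    "Congenital malformations, deformations and chromosomal abnormalities": "Q21",
    "Diseases of the blood and blood-forming organs and certain disorders involving the immune mechanism": "D61",
    "Factors influencing health status and contact with health services": "Z51",
}


@dataclass(frozen=True)
class CohortParams:
    """Generator parameters.

    Defaults describe a workforce of the scale and composition of a large
    Japanese multi-company cohort: 80,000 workers, 81% male, ages uniform
    over 20-60 at the window start, absence onset dominated by mental and
    behavioural disorders, and direct mortality dominated by neoplasms,
    circulatory disease and suicide.  Rates are per person-year; durations
    are log-normal in days.
    """

    n_employees: int = 80_000
    sex_ratio: float = 0.81  # male fraction
    age_bands: tuple[tuple[float, float, float], ...] = ((20.0, 60.0, 1.0),)
    onset_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "Mental and behavioural disorders": 0.009,
            "Neoplasms": 0.0025,
            "Diseases of the circulatory system": 0.0025,
        }
    )
    duration_log_mean: float = math.log(90.0)
    duration_log_sd: float = 0.8
    outcome_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "Mental and behavioural disorders": (0.93, 0.065, 0.005),
            "Neoplasms": (0.84, 0.08, 0.08),
            "Diseases of the circulatory system": (0.87, 0.06, 0.07),
        }
    )
    direct_death_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "Neoplasms": 1.0e-4,
            "Diseases of the circulatory system": 0.7e-4,
            "Intentional self-harm": 0.7e-4,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_employees < 0:
            raise ValueError("n_employees must be non-negative")
        if not 0.0 < self.sex_ratio < 1.0:
            raise ValueError("sex_ratio must be in (0, 1)")
        if self.duration_log_sd <= 0:
            raise ValueError("duration_log_sd must be positive")
        for rates in (self.onset_rates, self.direct_death_rates):
            for g, r in rates.items():
                if r < 0:
                    raise ValueError(f"negative rate for {g!r}")
        for g in self.onset_rates:
            probs = self.outcome_probs.get(g, (1.0, 0.0, 0.0))
            if len(probs) != 3 or any(q < 0 for q in probs):
                raise ValueError(f"bad outcome probabilities for {g!r}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"outcome probabilities for {g!r} must sum to 1")
        for lo, hi, wgt in self.age_bands:
            if not (lo < hi) or wgt < 0:
                raise ValueError("age bands must have lo < hi and weight >= 0")

    def code_for(self, group: str) -> str:
        try:
            return REPRESENTATIVE_CODE[group]
        except KeyError:
            raise ValueError(f"no representative ICD-10 code for group {group!r}")


@dataclass
class SimulatedCohort:
    """The four generated tables, in the exact CSV schemas the readers
    consume (dates ISO 8601; spell end dates exclusive)."""

    employees: pd.DataFrame
    sa_episodes: pd.DataFrame
    deaths: pd.DataFrame
    headcounts: pd.DataFrame

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.employees.to_csv(d / "employees.csv", index=False)
        self.sa_episodes.to_csv(d / "sa_episodes.csv", index=False)
        self.deaths.to_csv(d / "deaths.csv", index=False)
        self.headcounts.to_csv(d / "headcounts.csv", index=False)


def _birthday_ordinals(birth_ord: np.ndarray, years: int) -> np.ndarray:
    """Ordinal of each birth date shifted by ``years`` calendar years,
    clamping Feb 29 to Feb 28 in non-leap years (same convention as the
    accounting layer)."""
    births = pd.to_datetime(birth_ord - 719_163, unit="D")  # 719163 = 1970-01-01
    y = births.year.to_numpy() + years
    m = births.month.to_numpy()
    d = births.day.to_numpy()
    leap = (y % 4 == 0) & ((y % 100 != 0) | (y % 400 == 0))
    d = np.where((m == 2) & (d == 29) & ~leap, 28, d)
    shifted = pd.to_datetime({"year": y, "month": m, "day": d})
    return (shifted.astype("int64") // 86_400_000_000_000).to_numpy() + 719_163


def simulate_cohort(
    p: CohortParams, w: ObservationWindow | None = None
) -> SimulatedCohort:
    """Generate one synthetic cohort (roster, spells, deaths, headcounts)."""
    w = w or ObservationWindow()
    rng = np.random.default_rng(p.seed)
    n = p.n_employees
    w_start = w.window.start.toordinal()
    w_end = w.window.end.toordinal()

    # roster ---------------------------------------------------------------
    male = rng.random(n) < p.sex_ratio
    bands = np.asarray(p.age_bands, dtype=float)
    weights = bands[:, 2] / bands[:, 2].sum()
    which = rng.choice(len(bands), size=n, p=weights)
    age = bands[which, 0] + rng.random(n) * (bands[which, 1] - bands[which, 0])
    birth_ord = w_start - np.round(age * DAYS_PER_YEAR).astype(np.int64)

    b_min = _birthday_ordinals(birth_ord, w.min_age_years)
    b_max = _birthday_ordinals(birth_ord, w.max_age_years)
    p_start = np.maximum(w_start, b_min)
    p_end = np.minimum(w_end, b_max)
    length_days = np.maximum(0, p_end - p_start)
    length_years = length_days / DAYS_PER_YEAR

    # sickness-absence onsets ---------------------------------------------
    groups = list(p.onset_rates)
    rates = np.array([p.onset_rates[g] for g in groups], dtype=float)
    total_rate = float(rates.sum())
    group_p = rates / total_rate if total_rate > 0 else None
    n_onsets = (
        rng.poisson(total_rate * length_years)
        if total_rate > 0
        else np.zeros(n, dtype=np.int64)
    )

    episodes: list[tuple[int, int, int, str, str, int | None]] = []
    terminal_ord = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    terminal_is_death = np.zeros(n, dtype=bool)
    cert_deaths: list[tuple[int, int, str]] = []  # short-spell deaths

    for i in np.nonzero(n_onsets)[0]:
        k = int(n_onsets[i])
        onsets = np.sort(p_start[i] + rng.integers(0, length_days[i], size=k))
        gidx = rng.choice(len(groups), size=k, p=group_p)
        durations = np.maximum(
            1, np.round(rng.lognormal(p.duration_log_mean, p.duration_log_sd, k))
        ).astype(np.int64)
        u = rng.random(k)
        cur_end = -1
        for j in range(k):
            start = int(onsets[j])
            if start < cur_end:
                continue  # still absent: a new spell cannot begin
            group = groups[int(gidx[j])]
            end = start + int(durations[j])
            probs = p.outcome_probs.get(group, (1.0, 0.0, 0.0))
            if u[j] < probs[0]:
                outcome = "return"
            elif u[j] < probs[0] + probs[1]:
                outcome = "retirement"
            else:
                outcome = "death"
            if outcome == "death" and end - start < DEFAULT_LTSA_DAYS:
                # too short to be recorded as long-term absence: the death
                # surfaces through the death-certificate path instead
                cert_deaths.append((i, end, p.code_for(group)))
                terminal_ord[i] = end
                terminal_is_death[i] = True
                break
            if outcome == "retirement" and end - start < DEFAULT_LTSA_DAYS:
                # silent exit from the workforce; only headcounts notice
                terminal_ord[i] = end
                break
            episodes.append(
                (i, start, end, p.code_for(group), outcome,
                 end if outcome != "return" else None)
            )
            cur_end = end
            if outcome != "return":
                terminal_ord[i] = end
                terminal_is_death[i] = outcome == "death"
                break

    # direct deaths (employees with no terminal spell) ---------------------
    dgroups = list(p.direct_death_rates)
    drates = np.array([p.direct_death_rates[g] for g in dgroups], dtype=float)
    dtotal = float(drates.sum())
    direct_deaths: list[tuple[int, int, str]] = []
    if dtotal > 0:
        wait_days = rng.exponential(1.0 / dtotal, size=n) * DAYS_PER_YEAR
        death_ord = p_start + np.floor(wait_days).astype(np.int64)
        cause_idx = rng.choice(len(dgroups), size=n, p=drates / dtotal)
        eligible = (
            (terminal_ord == np.iinfo(np.int64).max)
            & (death_ord < p_end)
            & (length_days > 0)
        )
        for i in np.nonzero(eligible)[0]:
            d_ord = int(death_ord[i])
            direct_deaths.append((i, d_ord, p.code_for(dgroups[int(cause_idx[i])])))
            terminal_ord[i] = d_ord
            terminal_is_death[i] = True

    # a death censors any spell that has not yet begun
    death_of = {i: d for i, d, _ in direct_deaths}
    episodes = [
        ep for ep in episodes
        if ep[0] not in death_of or ep[1] < death_of[ep[0]]
    ]

    # headcounts: one census on April 1 of each year inside the window -----
    census = [
        dt.date(year, 4, 1).toordinal()
        for year in range(w.window.start.year, w.window.end.year + 1)
        if dt.date(year, 4, 1) in w.window
    ]
    births = pd.to_datetime(birth_ord - 719_163, unit="D")
    by, bm, bd = births.year.to_numpy(), births.month.to_numpy(), births.day.to_numpy()
    head_rows = []
    for c_ord in census:
        c = dt.date.fromordinal(c_ord)
        active = (p_start <= c_ord) & (c_ord < p_end) & (terminal_ord > c_ord)
        if not active.any():
            continue
        # exact age in completed years on the census date
        age_c = (c.year - by) - (
            (bm > c.month) | ((bm == c.month) & (bd > c.day))
        ).astype(int)
        lo5 = (age_c // 5) * 5
        for sex_val, sex_mask in (("M", male), ("F", ~male)):
            mask = active & sex_mask
            for lo in np.unique(lo5[mask]):
                head_rows.append(
                    {
                        "year": c.year,
                        "sex": sex_val,
                        "age_band": f"{lo}-{lo + 4}",
                        "count": int((mask & (lo5 == lo)).sum()),
                    }
                )

    # assemble output tables ----------------------------------------------
    iso = lambda o: dt.date.fromordinal(int(o)).isoformat()
    ids = np.array([f"E{i:06d}" for i in range(n)])
    employees = pd.DataFrame(
        {
            "id": ids,
            "sex": np.where(male, "M", "F"),
            "birth_date": [iso(o) for o in birth_ord],
        }
    )
    sa_episodes = pd.DataFrame(
        [
            {
                "employee_id": ids[i],
                "start_date": iso(s),
                "end_date": iso(e),
                "icd10_code": code,
                "outcome": outcome,
                "outcome_date": iso(od) if od is not None else "",
            }
            for i, s, e, code, outcome, od in episodes
        ],
        columns=[
            "employee_id", "start_date", "end_date",
            "icd10_code", "outcome", "outcome_date",
        ],
    )
    deaths = pd.DataFrame(
        [
            {"employee_id": ids[i], "date": iso(d), "icd10_code": code}
            for i, d, code in sorted(cert_deaths + direct_deaths)
        ],
        columns=["employee_id", "date", "icd10_code"],
    )
    headcounts = pd.DataFrame(
        head_rows, columns=["year", "sex", "age_band", "count"]
    )
    return SimulatedCohort(employees, sa_episodes, deaths, headcounts)


def expected_burden(
    p: CohortParams,
    w: ObservationWindow | None = None,
    n_replicates: int = 20,
    strata: Sequence | None = None,
) -> pd.DataFrame:
    """Monte-Carlo expected per-myriad burden under the generator.

    Runs ``n_replicates`` independent simulations (replicate seeds drawn
    from a generator seeded with ``p.seed``, so the schedule is fully
    determined by the scenario seed), pushes each through the full
    accounting pipeline, and averages the whole-cohort per-myriad
    estimates.  Returns one row per disease group x consequence with the
    replicate mean, standard deviation and count — the "truth" against
    which recovery tests compare a single pipeline run.
    """
    from .model import WorkingYearsLostModel

    w = w or ObservationWindow()
    seed_rng = np.random.default_rng(p.seed)
    seeds = seed_rng.integers(0, 2**31 - 1, size=n_replicates)
    rows = []
    for rep, seed in enumerate(seeds):
        cohort = simulate_cohort(dataclasses.replace(p, seed=int(seed)), w)
        result = WorkingYearsLostModel.from_frames(
            cohort.employees, cohort.sa_episodes, cohort.deaths,
            cohort.headcounts, window=w, strata=strata,
        ).fit()
        df = result.table.data
        sub = df[df["stratum"] == "all"][
            ["disease_group", "consequence", "per_myriad"]
        ].copy()
        sub["replicate"] = rep
        rows.append(sub)
    stacked = pd.concat(rows, ignore_index=True)
    out = (
        stacked.groupby(["disease_group", "consequence"])["per_myriad"]
        .agg(mean="mean", sd="std", n_replicates="count")
        .reset_index()
    )
    return out
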