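"""Half-open calendar intervals — the atom of all person-time arithmetic.

Every span of working time, sickness absence, or lost working life in this
package is a ``CalendarInterval``: a half-open span ``[start, end)`` of
calendar dates.  Half-open spans make lengths additive and guarantee that
abutting spells (one ending the day another begins) never double-count a
calendar day.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

#: Days per year used to convert day counts to person-years.  A Julian year
#: keeps multi-year spans stable across leap years.
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True, order=True)
class CalendarInterval:
    """A half-open span of calendar dates ``[start, end)``.

    Parameters
    ----------
    start : datetime.date
        First day of the span (inclusive).
    end : datetime.date
        Day after the last day of the span (exclusive).  Must satisfy
        ``start <= end``; the span is empty iff ``start == end``.
    """

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} is after its end {self.end}"
            )

    @property
    def days(self) -> int:
        """Length in days (``end - start``)."""
        return (self.end - self.start).days

    @property
    def years(self) -> float:
        """Length in years (days / 365.25)."""
        return self.days / DAYS_PER_YEAR

    @property
    def is_empty(self) -> bool:
        return self.start == self.end

    def __contains__(self, day: dt.date) -> bool:
        return self.start <= day < self.end

    def intersect(self, other: "CalendarInterval") -> "CalendarInterval":
        """Maximal interval contained in both spans.

        Disjoint spans yield an empty interval (never an error).
        """
        start = max(self.start, other.start)
        end = min(self.end, other.end)
        if start >= end:
            # collapse to a canonical empty interval at the later start
            return CalendarInterval(start, start)
        return CalendarInterval(start, end)

    def overlaps(self, other: "CalendarInterval") -> bool:
        return not self.intersect(other).is_empty

    def abuts(self, other: "CalendarInterval") -> bool:
        """True if the spans share exactly one boundary and do not overlap."""
        return self.end == other.start or other.end == self.start

    def hull(self, other: "CalendarInterval") -> "CalendarInterval":
        """Smallest interval containing both spans."""
        return CalendarInterval(
            min(self.start, other.start), max(self.end, other.end)
        )

    def clip_before(self, cutoff: dt.date) -> "CalendarInterval":
        """The part of the span strictly before ``cutoff``."""
        end = min(self.end, cutoff)
        if end <= self.start:
            return CalendarInterval(self.start, self.start)
        return CalendarInterval(self.start, end)

    def clip_from(self, cutoff: dt.date) -> "CalendarInterval":
        """The part of the span on or after ``cutoff``."""
        start = max(self.start, cutoff)
        if start >= self.end:
            return CalendarInterval(self.end, self.end)
        return CalendarInterval(start, self.end)

    def iter_days(self):
        """Iterate the calendar days in the span (test oracles only)."""
        day = self.start
        one = dt.timedelta(days=1)
        while day < self.end:
            yield day
            day += one


def intersect(a: CalendarInterval, b: CalendarInterval) -> CalendarInterval:
    """Functional alias for :meth:`CalendarInterval.intersect`."""
    return a.intersect(b)
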