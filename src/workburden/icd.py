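"""ICD-10 parsing and disease-category assignment.

Diagnosis and cause-of-death codes are grouped into 20 disease categories:
the standard ICD-10 chapters, except that the two external-cause chapters
(S00-T98 injuries and V01-Y98 external causes of morbidity/mortality) are
pooled and then re-split into "Intentional self-harm" (X60-X84) and
everything else.  Only the three-character base code (letter + two digits)
decides the category; certificate sub-classification digits are ignored.

The category table ships as a human-readable CSV
(``workburden/data/disease_groups.csv``: label, blocks, exclusions) so users
can audit or extend the mapping.

Notes
-----
The endocrine/metabolic row is accepted as E00-E99 rather than the nominal
chapter IV extent E00-E90; codes E91-E99 are unassigned in ICD-10, so the
wider range is harmless and matches common tabulations.  U codes and codes
in unassigned gaps (e.g. D49, K94-K99, the perinatal chapter P00-P96, V00,
Y99) have no category and raise :class:`~workburden.exceptions.UnmappableCodeError`
by default; an explicit "unclassified" bucket can be requested instead.
"""

from __future__ import annotations

import csv
import functools
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

from .exceptions import ICDParseError, UnmappableCodeError

#: Label used when unmappable codes are bucketed instead of rejected.
UNCLASSIFIED = "Unclassified"

_CODE_RE = re.compile(r"^\s*([A-Za-z])(\d{2})(?:\.?[0-9A-Za-z]*)\s*$")


@dataclass(frozen=True, order=True)
class ICD10Code:
    """A three-character ICD-10 base code, e.g. ``F32``.

    Ordered lexicographically on (letter, number), which matches the
    ordering of ICD-10 block ranges like S00-T98.
    """

    letter: str
    number: int

    def __str__(self) -> str:
        return f"{self.letter}{self.number:02d}"


def parse_code(raw: str | ICD10Code) -> ICD10Code:
    """Parse a diagnosis string to its canonical three-character code.

    Accepts forms like ``"F32"``, ``"F32.1"``, ``"f321"``; the
    sub-classification is stripped and case is normalised.

    Raises
    ------
    ICDParseError
        If the text does not start with a letter followed by two digits.
    """
    if isinstance(raw, ICD10Code):
        return raw
    if not isinstance(raw, str) or not raw.strip():
        raise ICDParseError(f"empty or non-string ICD-10 code: {raw!r}")
    m = _CODE_RE.match(raw)
    if m is None:
        raise ICDParseError(f"malformed ICD-10 code: {raw!r}")
    return ICD10Code(m.group(1).upper(), int(m.group(2)))


@dataclass(frozen=True)
class CodeRange:
    """An inclusive range of three-character codes, e.g. S00-T98."""

    lo: ICD10Code
    hi: ICD10Code

    def __contains__(self, code: ICD10Code) -> bool:
        return self.lo <= code <= self.hi

    def __str__(self) -> str:
        return f"{self.lo}-{self.hi}"

    @classmethod
    def parse(cls, text: str) -> "CodeRange":
        lo, _, hi = text.strip().partition("-")
        return cls(parse_code(lo), parse_code(hi or lo))


@dataclass(frozen=True)
class DiseaseGroup:
    """A named disease category: inclusive code ranges minus exclusions."""

    label: str
    blocks: tuple[CodeRange, ...]
    exclusions: tuple[CodeRange, ...] = ()

    def __contains__(self, code: ICD10Code) -> bool:
        if any(code in r for r in self.exclusions):
            return False
        return any(code in r for r in self.blocks)


class GroupTable:
    """The ordered collection of disease categories.

    Categories must be disjoint after exclusions are applied; assignment
    returns the unique matching label.
    """

    def __init__(self, groups: Iterable[DiseaseGroup]):
        self.groups: tuple[DiseaseGroup, ...] = tuple(groups)
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate disease-group labels")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.groups)

    def assign(self, code: str | ICD10Code, unmapped: str = "error") -> str:
        """Category label for a code.

        Parameters
        ----------
        code : str or ICD10Code
            Diagnosis code; strings are parsed first.
        unmapped : {"error", "bucket"}
            Policy for codes outside every category: raise
            :class:`UnmappableCodeError` (default) or return the
            :data:`UNCLASSIFIED` bucket label.
        """
        c = parse_code(code)
        matches = [g.label for g in self.groups if c in g]
        if len(matches) > 1:  # pragma: no cover - table invariant
            raise ValueError(f"code {c} matches several groups: {matches}")
        if matches:
            return matches[0]
        if unmapped == "bucket":
            return UNCLASSIFIED
        raise UnmappableCodeError(
            f"ICD-10 code {c} falls outside every disease category"
        )

    @classmethod
    def from_csv(cls, path) -> "GroupTable":
        with open(path, newline="", encoding="utf-8") as fh:
            return cls._from_rows(csv.DictReader(fh))

    @classmethod
    def _from_rows(cls, rows) -> "GroupTable":
        groups = []
        for row in rows:
            blocks = tuple(
                CodeRange.parse(b) for b in row["blocks"].split(";") if b.strip()
            )
            excl = tuple(
                CodeRange.parse(b)
                for b in (row.get("exclusions") or "").split(";")
                if b.strip()
            )
            groups.append(DiseaseGroup(row["label"].strip(), blocks, excl))
        return cls(groups)


@functools.lru_cache(maxsize=1)
def default_group_table() -> GroupTable:
    """The packaged 20-category table."""
    ref = resources.files("workburden").joinpath("data/disease_groups.csv")
    with ref.open("r", encoding="utf-8", newline="") as fh:
        return GroupTable._from_rows(csv.DictReader(fh))


def assign_group(code: str | ICD10Code, unmapped: str = "error") -> str:
    """Assign a code to a category using the packaged default table."""
    return default_group_table().assign(code, unmapped=unmapped)
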