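"""Hierarchical SOC 2000 occupation codes, analysis groupings, and
disclosure-control merging.

The UK Standard Occupational Classification 2000 is a four-level digit
hierarchy: one-digit major groups down to four-digit unit groups, a code's
parent being its prefix one digit shorter.  Analyses of linked
census-mortality data typically work at the three-digit level and must
respect statistical-disclosure rules: occupation groups observed with fewer
than a threshold number of deaths (ten, by convention) may not be published
and are merged upwards within the hierarchy, or suppressed when no sibling
exists to absorb them.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "SocCode",
    "OccupationGroup",
    "GroupingScheme",
    "parse_soc",
    "assign_group",
    "collapse_until_publishable",
]

_CODE_RE = re.compile(r"^[1-9][0-9]{0,3}$")

#: Default disclosure-control threshold: groups with fewer deaths than this
#: may not be published.
MIN_DEATHS = 10


@dataclass(frozen=True)
class SocCode:
    """A SOC 2000 code: a digit string of length 1-4, optionally labelled."""

    code: str
    label: str = ""

    def __post_init__(self) -> None:
        if not _CODE_RE.match(self.code):
            raise ValueError(f"invalid SOC code {self.code!r}")

    @property
    def parent(self) -> Optional["SocCode"]:
        """The code one digit shorter, or None for a major (1-digit) group."""
        return SocCode(self.code[:-1]) if len(self.code) > 1 else None

    def __str__(self) -> str:
        return self.code


def parse_soc(text: Optional[str], row: Optional[int] = None) -> Optional[SocCode]:
    """Parse a raw occupation-code field.

    Empty or whitespace-only text marks "no occupation reported" and maps to
    ``None``.  Digit strings are validated as SOC codes.  Anything else is a
    parse error; *row* is included in the message when given.
    """
    if text is None or not str(text).strip():
        return None
    s = str(text).strip()
    if not _CODE_RE.match(s):
        where = f" (row {row})" if row is not None else ""
        raise ValueError(f"unparseable occupation code {s!r}{where}")
    return SocCode(s)


@dataclass(frozen=True)
class OccupationGroup:
    """One analysis group: a prefix-closed set of SOC codes for one sex.

    Membership is by prefix: a record coded ``8211`` belongs to a group
    whose ``member_codes`` contain ``821``.  The special no-occupation group
    has no member codes and collects records with a blank occupation field.
    """

    group_id: str
    label: str
    member_codes: frozenset[str] = frozenset()
    sex: str = ""
    includes_no_occupation: bool = False
    suppressed: bool = False

    def __post_init__(self) -> None:
        for c in self.member_codes:
            if not _CODE_RE.match(c):
                raise ValueError(f"group {self.group_id!r}: bad member code {c!r}")
        if not self.member_codes and not self.includes_no_occupation:
            raise ValueError(f"group {self.group_id!r} has no member codes")


class GroupingScheme:
    """An ordered set of occupation groups for one sex and geography.

    Groups' member codes must be disjoint (as strings; nesting by prefix is
    allowed across groups and resolved by longest-prefix match).
    """

    def __init__(
        self,
        groups: Sequence[OccupationGroup],
        sex: str = "",
        geography: str = "",
        min_deaths: int = MIN_DEATHS,
    ) -> None:
        self.groups = list(groups)
        self.sex = sex
        self.geography = geography
        self.min_deaths = int(min_deaths)
        self._by_code: dict[str, str] = {}
        seen_ids: set[str] = set()
        self._no_occupation_id: Optional[str] = None
        for g in self.groups:
            if g.group_id in seen_ids:
                raise ValueError(f"duplicate group id {g.group_id!r}")
            seen_ids.add(g.group_id)
            if g.includes_no_occupation:
                if self._no_occupation_id is not None:
                    raise ValueError("more than one no-occupation group")
                self._no_occupation_id = g.group_id
            for c in g.member_codes:
                if c in self._by_code:
                    raise ValueError(
                        f"code {c!r} claimed by both {self._by_code[c]!r} "
                        f"and {g.group_id!r}"
                    )
                self._by_code[c] = g.group_id

    # ------------------------------------------------------------------ API
    def group(self, group_id: str) -> OccupationGroup:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    @property
    def no_occupation_id(self) -> Optional[str]:
        return self._no_occupation_id

    def assign(self, code: Optional[SocCode | str]) -> str:
        """Longest-prefix group assignment; ``None`` goes to no-occupation."""
        return assign_group(code, self)

    def check_coverage(self, codes: Iterable[Optional[str]]) -> None:
        """Raise listing every code no group covers."""
        codes = list(codes)
        distinct = {str(c) for c in codes if c is not None and str(c).strip()}
        orphans = sorted(c for c in distinct if not self._covers(c))
        if orphans:
            raise ValueError(f"codes not covered by any group: {orphans}")
        if any(c is None or not str(c).strip() for c in codes) and (
            self._no_occupation_id is None
        ):
            raise ValueError("cohort has no-occupation records but the "
                             "scheme has no no-occupation group")

    def _covers(self, code: str) -> bool:
        return any(code[:k] in self._by_code for k in range(len(code), 0, -1))

    # ------------------------------------------------------------------- IO
    @classmethod
    def from_csv(cls, path, sex: str = "", geography: str = "",
                 min_deaths: int = MIN_DEATHS) -> "GroupingScheme":
        """Read a grouping file: group_id,sex,label,member_codes,
        includes_no_occupation with member codes ';'-separated."""
        groups = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                if sex and row["sex"] and row["sex"] != sex:
                    continue
                codes = frozenset(
                    c.strip() for c in row["member_codes"].split(";") if c.strip()
                )
                groups.append(
                    OccupationGroup(
                        group_id=row["group_id"],
                        label=row["label"],
                        member_codes=codes,
                        sex=row["sex"],
                        includes_no_occupation=row["includes_no_occupation"]
                        in ("1", "true", "True"),
                    )
                )
        return cls(groups, sex=sex, geography=geography, min_deaths=min_deaths)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["group_id", "sex", "label", "member_codes",
                        "includes_no_occupation"])
            for grp in self.groups:
                w.writerow([
                    grp.group_id, grp.sex, grp.label,
                    ";".join(sorted(grp.member_codes)),
                    int(grp.includes_no_occupation),
                ])


def assign_group(code: Optional[SocCode | str], scheme: GroupingScheme) -> str:
    """Assign a SOC code (or the none marker) to its analysis group.

    A code matches the group owning its longest prefix, so four-digit input
    codes fall into three-digit (or broader) groups automatically.
    """
    if code is None:
        if scheme.no_occupation_id is None:
            raise ValueError("no no-occupation group in scheme")
        return scheme.no_occupation_id
    s = str(code)
    if not _CODE_RE.match(s):
        raise ValueError(f"invalid SOC code {s!r}")
    for k in range(len(s), 0, -1):
        gid = scheme._by_code.get(s[:k])
        if gid is not None:
            return gid
    raise ValueError(f"code {s!r} not covered by any group")


def _common_prefix(a: str, b: str) -> str:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return a[:n]


def _prefix_level(g: OccupationGroup, h: OccupationGroup) -> int:
    """Longest common code prefix between any member codes of g and h."""
    best = 0
    for a in g.member_codes:
        for b in h.member_codes:
            best = max(best, len(_common_prefix(a, b)))
    return best


def _sort_key(g: OccupationGroup) -> str:
    return min(g.member_codes) if g.member_codes else "~" + g.group_id


def collapse_until_publishable(
    counts: Mapping[str, int], scheme: GroupingScheme
) -> GroupingScheme:
    """Merge under-threshold groups up the SOC hierarchy until publishable.

    Any group with fewer than ``scheme.min_deaths`` deaths is merged with
    the sibling sharing the longest common code prefix, one hierarchy level
    at a time; the deficient group with fewest deaths is handled first, and
    among equally close siblings the one with fewest deaths absorbs it (ties
    broken by ascending code).  Groups with no sibling at any level (and the
    no-occupation group) cannot be merged and are flagged suppressed
    instead.  The result satisfies: every non-suppressed group has at least
    ``min_deaths`` deaths.  Applying the operation again is a no-op.
    """
    groups = [replace(g) for g in scheme.groups]
    deaths = {g.group_id: int(counts.get(g.group_id, 0)) for g in groups}
    existing_ids = {g.group_id for g in groups}

    def deficient():
        return [
            g for g in groups
            if not g.suppressed and deaths[g.group_id] < scheme.min_deaths
        ]

    while True:
        todo = deficient()
        if not todo:
            break
        g = min(todo, key=lambda g: (deaths[g.group_id], _sort_key(g)))
        partners = [
            (h, _prefix_level(g, h)) for h in groups
            if h is not g and not h.suppressed and h.member_codes
        ]
        best = max((lvl for _, lvl in partners), default=0)
        if best < 1:
            i = groups.index(g)
            groups[i] = replace(g, suppressed=True)
            continue
        sibs = [h for h, lvl in partners if lvl == best]
        h = min(sibs, key=lambda h: (deaths[h.group_id], _sort_key(h)))
        prefix = max(
            (_common_prefix(a, b) for a in g.member_codes for b in h.member_codes),
            key=len,
        )
        new_id = prefix + "x"
        while new_id in existing_ids:
            new_id += "x"
        existing_ids.add(new_id)
        first, second = sorted((g, h), key=_sort_key)
        merged = OccupationGroup(
            group_id=new_id,
            label=f"{first.label} / {second.label}",
            member_codes=g.member_codes | h.member_codes,
            sex=g.sex or h.sex,
            includes_no_occupation=False,
            suppressed=False,
        )
        deaths[new_id] = deaths.pop(g.group_id) + deaths.pop(h.group_id)
        i = min(groups.index(g), groups.index(h))
        groups.remove(g)
        groups.remove(h)
        groups.insert(i, merged)

    out = GroupingScheme(
        groups, sex=scheme.sex, geography=scheme.geography,
        min_deaths=scheme.min_deaths,
    )
    # the collapsed death tallies ride along for callers that need them
    out.collapsed_deaths = deaths  # type: ignore[attr-defined]
    return out
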