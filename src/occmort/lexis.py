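"""Lexis splitting: person-level follow-up into deaths and person-years by
(sex, geography, occupation group, 5-year age band).

Two age bases are supported.  The default, ``attained``, partitions each
person's follow-up interval at the exact ages where they cross a band
boundary, so a cohort aged 20-59 at baseline followed for ten years spreads
over bands [20, 70).  The alternative, ``baseline``, attributes all of a
person's time (and any death) to the band of their age at census, over
bands [20, 60).  All arithmetic uses a 365.25-day year.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS, CohortRecord, DAYS_PER_YEAR
from .soc import GroupingScheme

__all__ = ["AgeBand", "StratumCount", "default_bands", "split_person_time",
           "tabulate"]


@dataclass(frozen=True, order=True)
class AgeBand:
    """Half-open attained-age interval [lower, upper)."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"empty band [{self.lower}, {self.upper})")

    def __str__(self) -> str:
        up = "+" if np.isinf(self.upper) else f"-{self.upper:g}"
        return f"{self.lower:g}{up}"


@dataclass(frozen=True)
class StratumCount:
    """Deaths and person-years in one analysis cell."""

    sex: str
    geography: str
    group_id: str
    age_band: AgeBand
    deaths: int
    person_years: float

    def __post_init__(self) -> None:
        if self.deaths < 0 or self.person_years < 0:
            raise ValueError("negative deaths or person-years")
        if self.deaths > 0 and self.person_years <= 0:
            raise ValueError("deaths recorded in a cell with no person-time")


def default_bands(lower: float = 20.0, upper: float = 70.0,
                  width: float = 5.0) -> list[AgeBand]:
    """Contiguous 5-year bands tiling [lower, upper)."""
    edges = np.arange(lower, upper + width / 2, width)
    return [AgeBand(a, b) for a, b in zip(edges[:-1], edges[1:])]


#: Catch-all band for follow-up beyond the configured range.
OVERFLOW_BAND = AgeBand(70.0, np.inf)


def _band_edges(bands: Sequence[AgeBand]) -> np.ndarray:
    bands = sorted(bands)
    edges = [bands[0].lower]
    for b in bands:
        if b.lower != edges[-1]:
            raise ValueError("bands do not tile contiguously")
        edges.append(b.upper)
    return np.asarray(edges, dtype=float)


def split_person_time(
    record: CohortRecord,
    bands: Optional[Sequence[AgeBand]] = None,
    age_basis: str = "attained",
) -> list[tuple[AgeBand, float, bool]]:
    """Partition one person's follow-up into per-band contributions.

    Returns ``(band, person_years, died_in_band)`` triples whose
    person-years sum exactly to the follow-up length.  A death is
    attributed to the band in which the person's attained age at exit
    falls (the last band they contributed time to).  Time beyond the top
    band edge is routed to a catch-all 70+ band with a warning.
    """
    if bands is None:
        bands = default_bands() if age_basis == "attained" else default_bands(20, 60)
    if age_basis == "baseline":
        for b in sorted(bands):
            if b.lower <= record.age_at_census < b.upper:
                return [(b, record.follow_up_years, record.died)]
        raise ValueError(
            f"{record.person_id}: baseline age {record.age_at_census} "
            "outside the band range"
        )
    if age_basis != "attained":
        raise ValueError(f"unknown age basis {age_basis!r}")

    bands = sorted(bands)
    a0 = record.age_at_census
    a1 = a0 + record.follow_up_years
    out: list[tuple[AgeBand, float, bool]] = []
    for b in bands:
        py = min(a1, b.upper) - max(a0, b.lower)
        if py > 0:
            out.append((b, py, False))
    top = bands[-1].upper
    if a1 > top:
        warnings.warn(
            f"{record.person_id}: follow-up reaches age {a1:.2f}, beyond the "
            f"top band edge {top:g}; routed to a catch-all {top:g}+ band",
            stacklevel=2,
        )
        out.append((AgeBand(top, np.inf), a1 - max(a0, top), False))
    if record.died and out:
        band, py, _ = out[-1]
        out[-1] = (band, py, True)
    return out


def tabulate(
    cohort: pd.DataFrame,
    scheme: GroupingScheme,
    bands: Optional[Sequence[AgeBand]] = None,
    age_basis: str = "attained",
) -> pd.DataFrame:
    """Aggregate a cohort into stratum counts (vectorised Lexis expansion).

    Output columns: sex, geography, group_id, band_lower, deaths,
    person_years.  Total person-years equal the summed follow-up of the
    cohort and total deaths the number of died records, whatever the
    grouping — regrouping moves person-time between rows, never loses it.
    """
    if bands is None:
        bands = default_bands() if age_basis == "attained" else default_bands(20, 60)
    bands = sorted(bands)
    edges = _band_edges(bands)

    if cohort.empty:
        return pd.DataFrame(
            columns=["sex", "geography", "group_id", "band_lower", "deaths",
                     "person_years"]
        )

    codes = cohort["soc_code"].fillna("").astype(str)
    scheme.check_coverage([c if c.strip() else None for c in codes.unique()])
    code_map = {
        c: scheme.assign(c if c.strip() else None) for c in codes.unique()
    }
    gids = codes.map(code_map)

    a0 = cohort["age_at_census"].to_numpy(dtype=float)
    days = np.array([
        (x - e).days for e, x in zip(cohort["entry_date"], cohort["exit_date"])
    ])
    years = days / DAYS_PER_YEAR
    died = cohort["died"].to_numpy(dtype=int).astype(bool)

    if age_basis == "baseline":
        band_idx = np.searchsorted(edges, a0, side="right") - 1
        if (band_idx < 0).any() or (a0 >= edges[-1]).any():
            raise ValueError("baseline ages outside the band range")
        py_rows = pd.DataFrame({
            "sex": cohort["sex"].to_numpy(),
            "geography": cohort["geography"].to_numpy(),
            "group_id": gids.to_numpy(),
            "band_lower": edges[band_idx],
            "deaths": died.astype(int),
            "person_years": years,
        })
        agg = py_rows.groupby(
            ["sex", "geography", "group_id", "band_lower"], as_index=False
        ).sum()
        return agg.sort_values(
            ["sex", "geography", "group_id", "band_lower"]
        ).reset_index(drop=True)
    if age_basis != "attained":
        raise ValueError(f"unknown age basis {age_basis!r}")

    a1 = a0 + years
    if (a1 > edges[-1]).any():
        n_over = int((a1 > edges[-1]).sum())
        warnings.warn(
            f"{n_over} records reach beyond the top band edge "
            f"{edges[-1]:g}; their overflow time goes to a catch-all band",
            stacklevel=2,
        )
        edges = np.append(edges, np.inf)
        bands = list(bands) + [AgeBand(bands[-1].upper, np.inf)]

    pieces = []
    for k, b in enumerate(bands):
        py = np.clip(np.minimum(a1, edges[k + 1]) - np.maximum(a0, edges[k]),
                     0.0, None)
        mask = py > 0
        if not mask.any():
            continue
        # death goes to the band containing the attained age at exit; an
        # exit age exactly on a band edge belongs to the band below it
        d_band = mask & died & (a1 > edges[k]) & (a1 <= edges[k + 1])
        pieces.append(pd.DataFrame({
            "sex": cohort["sex"].to_numpy()[mask],
            "geography": cohort["geography"].to_numpy()[mask],
            "group_id": gids.to_numpy()[mask],
            "band_lower": b.lower,
            "deaths": d_band[mask].astype(int),
            "person_years": py[mask],
        }))
    agg = (
        pd.concat(pieces, ignore_index=True)
        .groupby(["sex", "geography", "group_id", "band_lower"], as_index=False)
        .sum()
    )
    return agg.sort_values(
        ["sex", "geography", "group_id", "band_lower"]
    ).reset_index(drop=True)
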