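"""Packaged reference data.

Ships the European Standard Population 2013 weights and the published
age-standardised occupational mortality rate tables for working-age adults:
England & Wales with 2001-11 follow-up, and Scotland with both 1991-2001
and 2001-11 follow-up, for men and women separately.  The occupation
groupings behind those tables (one group per published SOC code, plus the
no-occupation group) are shipped as grouping files; the published groupings
were modified for disclosure control without a public key, so they are
treated as user-replaceable configuration rather than hard-coded truth.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .rates import StandardPopulation
from .soc import GroupingScheme, MIN_DEATHS

__all__ = ["esp2013", "published_rates", "published_grouping"]

_RATE_FILES = {
    ("EW", "male"): "rates_ew_men_2001.csv",
    ("EW", "female"): "rates_ew_women_2001.csv",
    ("SCO", "male"): "rates_scotland_men.csv",
    ("SCO", "female"): "rates_scotland_women.csv",
}

_GROUP_FILES = {"male": "soc_groups_men.csv", "female": "soc_groups_women.csv"}


def esp2013() -> StandardPopulation:
    """European Standard Population 2013, 5-year bands (0-4 ... 90+)."""
    return StandardPopulation.esp2013()


def published_rates(geography: str, sex: str,
                    period: str | None = None) -> pd.DataFrame:
    """A published rate table as a DataFrame.

    ``geography`` is ``"EW"`` (England & Wales) or ``"SCO"`` (Scotland);
    ``period`` selects the follow-up start census year (``"1991"`` or
    ``"2001"``); England & Wales has only 2001.  Rows ``none`` (no
    occupation reported) and ``all`` (everyone reporting an occupation,
    E&W only) sit alongside the per-occupation groups.
    """
    try:
        fname = _RATE_FILES[(geography.upper(), sex.lower())]
    except KeyError:
        raise KeyError(f"no packaged table for {geography!r}/{sex!r}") from None
    with resources.files("occmort.data").joinpath(fname).open() as fh:
        frame = pd.read_csv(fh, dtype={"group_id": str, "period": str})
    if period is not None:
        frame = frame[frame["period"] == str(period)].reset_index(drop=True)
        if frame.empty:
            raise KeyError(f"no {period!r} rates for {geography!r}/{sex!r}")
    return frame


def published_grouping(sex: str, geography: str = "",
                       min_deaths: int = MIN_DEATHS) -> GroupingScheme:
    """The occupation grouping used by the packaged published tables."""
    try:
        fname = _GROUP_FILES[sex.lower()]
    except KeyError:
        raise KeyError(f"no packaged grouping for sex {sex!r}") from None
    path = resources.files("occmort.data").joinpath(fname)
    with resources.as_file(path) as p:
        return GroupingScheme.from_csv(p, sex=sex.lower(), geography=geography,
                                       min_deaths=min_deaths)
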