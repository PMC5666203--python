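"""Direct age-standardisation of mortality rates.

A directly standardised rate replaces the group's own age structure with a
fixed external standard.  With deaths d_a and person-years PY_a in 5-year
band a, and standard weights w_a renormalised to sum to one over the bands
in range,

    R  = 100 000 * sum_a w_a * d_a / PY_a
    Var(R) = 100 000^2 * sum_a w_a^2 * d_a / PY_a^2

the variance treating band death counts as Poisson, with a symmetric
normal 95% interval R +/- 1.96 se.  Weights come from the 2013 revision of
the European Standard Population (5-year bands), shipped as packaged data.

Rates are reported per 100 000 person-years.  Disclosure control marks
groups with fewer than ``min_deaths`` (default 10) deaths as suppressed;
suppressed groups are kept for totals but omitted from published tables.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .soc import MIN_DEATHS

__all__ = [
    "Z95",
    "StandardPopulation",
    "StandardisedRate",
    "direct_rate",
    "standardised_rates",
    "apply_suppression",
    "rank_table",
]

#: Two-sided 95% normal quantile, used for every symmetric interval.
Z95 = 1.959964

RATE_COLUMNS = ["group_id", "label", "sex", "geography", "person_years",
                "deaths", "rate", "se", "ci_low", "ci_high", "suppressed"]


class StandardPopulation:
    """A standard population: positive weight per 5-year band."""

    def __init__(self, weights: Mapping[float, float]) -> None:
        if not weights:
            raise ValueError("empty standard population")
        if any(w <= 0 for w in weights.values()):
            raise ValueError("standard weights must be positive")
        self.weights = {float(k): float(v) for k, v in weights.items()}

    @classmethod
    def esp2013(cls) -> "StandardPopulation":
        """The European Standard Population 2013 (packaged)."""
        with resources.files("occmort.data").joinpath("esp2013.csv").open() as fh:
            frame = pd.read_csv(fh)
        return cls(dict(zip(frame["band_lower"], frame["weight"])))

    @classmethod
    def from_csv(cls, path) -> "StandardPopulation":
        frame = pd.read_csv(path)
        return cls(dict(zip(frame["band_lower"], frame["weight"])))

    def normalised(self, band_lowers: Sequence[float]) -> np.ndarray:
        """Weights for the given bands, renormalised to sum to one."""
        missing = [b for b in band_lowers if float(b) not in self.weights]
        if missing:
            raise KeyError(f"no standard weight for bands {missing}")
        w = np.array([self.weights[float(b)] for b in band_lowers])
        return w / w.sum()


@dataclass(frozen=True)
class StandardisedRate:
    """Directly standardised rate per 100 000 person-years with normal CI."""

    group_id: str
    rate: float
    se: float
    ci_low: float
    ci_high: float
    deaths: int
    person_years: float
    label: str = ""
    suppressed: bool = False

    def __post_init__(self) -> None:
        if not self.ci_low <= self.rate <= self.ci_high:
            raise ValueError(f"{self.group_id}: CI does not bracket the rate")


def direct_rate(
    strata: pd.DataFrame,
    std: StandardPopulation,
    group_id: str = "",
    label: str = "",
) -> StandardisedRate:
    """Standardise one group's strata (columns band_lower, deaths,
    person_years).

    Bands with no person-time and no deaths are dropped and the weights
    renormalised over the remainder, with a warning; a group with no
    person-time at all has no defined rate.
    """
    d = strata["deaths"].to_numpy(dtype=float)
    py = strata["person_years"].to_numpy(dtype=float)
    keep = py > 0
    if ((~keep) & (d > 0)).any():
        raise ValueError(f"group {group_id!r}: deaths in a band with no "
                         "person-time")
    if not keep.any():
        raise ValueError(f"group {group_id!r}: no person-time in any band; "
                         "rate undefined")
    if (~keep).any():
        warnings.warn(
            f"group {group_id!r}: {int((~keep).sum())} empty band(s) dropped; "
            "standard weights renormalised over the remainder",
            stacklevel=2,
        )
    bands = strata["band_lower"].to_numpy(dtype=float)[keep]
    d, py = d[keep], py[keep]
    w = std.normalised(bands)
    rate = 1e5 * float(w @ (d / py))
    var = 1e10 * float((w ** 2) @ (d / py ** 2))
    se = float(np.sqrt(var))
    return StandardisedRate(
        group_id=group_id,
        label=label,
        rate=rate,
        se=se,
        ci_low=rate - Z95 * se,
        ci_high=rate + Z95 * se,
        deaths=int(round(d.sum())),
        person_years=float(py.sum()),
    )


def standardised_rates(
    strata: pd.DataFrame,
    std: StandardPopulation,
    min_deaths: int = MIN_DEATHS,
    labels: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Standardise every (sex, geography, group) in a stratum table.

    Returns the rates table (one row per group, RATE_COLUMNS) with
    disclosure suppression already applied at *min_deaths*.
    """
    labels = labels or {}
    rows = []
    for (sex, geo, gid), grp in strata.groupby(["sex", "geography", "group_id"]):
        r = direct_rate(grp, std, group_id=gid, label=labels.get(gid, gid))
        rows.append({
            "group_id": gid, "label": r.label, "sex": sex, "geography": geo,
            "person_years": r.person_years, "deaths": r.deaths,
            "rate": r.rate, "se": r.se,
            "ci_low": r.ci_low, "ci_high": r.ci_high,
        })
    out = pd.DataFrame(rows, columns=RATE_COLUMNS[:-1])
    return apply_suppression(out, min_deaths=min_deaths)


def apply_suppression(rates: pd.DataFrame, min_deaths: int = MIN_DEATHS) -> pd.DataFrame:
    """Flag groups with fewer than *min_deaths* deaths as suppressed."""
    out = rates.copy()
    out["suppressed"] = out["deaths"] < min_deaths
    return out


def rank_table(rates: pd.DataFrame) -> pd.DataFrame:
    """Publication-style ranking of non-suppressed groups.

    Rows are ordered by ascending rate (ties broken by label) and given a
    1-based rank; rates are rounded to whole numbers per 100 000 for
    display as ``rate (low-high)``.  The ratio of the highest to the lowest
    published rate is attached as ``table.attrs['max_min_ratio']``.
    """
    if "suppressed" in rates.columns:
        pub = rates.loc[~rates["suppressed"].astype(bool)].copy()
    else:
        pub = rates.copy()
    pub = pub.sort_values(["rate", "label"], kind="stable").reset_index(drop=True)
    pub.insert(0, "rank", np.arange(1, len(pub) + 1))
    pub["display"] = [
        f"{r:.0f} ({lo:.0f}–{hi:.0f})"
        for r, lo, hi in zip(pub["rate"], pub["ci_low"], pub["ci_high"])
    ]
    out = pub[["rank", "group_id", "label", "person_years", "rate", "display"]]
    if len(pub):
        out.attrs["max_min_ratio"] = float(pub["rate"].max() / pub["rate"].min())
    return out
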