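"""Synthetic linked census-mortality cohorts.

The real UK census-mortality linkage studies (the ONS Longitudinal Study,
the Scottish Longitudinal Study and the Northern Ireland Mortality Study)
are access-restricted, so this module generates person-level cohorts with
the statistical structure such an analysis assumes: adults aged 20-59 at a
census date, an occupation (or none) drawn from configured prevalences, and
roughly ten years of all-cause mortality follow-up driven by a
piecewise-constant hazard over attained 5-year age bands.

The hazard for a person in occupation group g at attained age a is

    lambda_g(a) = (r_g / 100 000) * m_band(a)

where r_g is the group's target *directly age-standardised* rate per
100 000 person-years and m_a are age-shape multipliers normalised so that
the standard-population-weighted mean of m_a over the in-range bands equals
one.  Under that normalisation the expected standardised rate of the
simulated cohort equals r_g exactly, which makes the generator usable as a
ground truth for parameter-recovery checks; the crude rate differs from r_g
whenever the m_a are not flat.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .soc import parse_soc

__all__ = [
    "CohortRecord",
    "GroupSpec",
    "SimulationConfig",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "normalise_multipliers",
]

#: Year length used for all age / person-time arithmetic, in days.
DAYS_PER_YEAR = 365.25

#: Default census date (the 2001 UK census day).
CENSUS_2001 = dt.date(2001, 4, 29)

COHORT_COLUMNS = [
    "person_id", "sex", "age_at_census", "soc_code", "geography",
    "entry_date", "exit_date", "died",
]


@dataclass(frozen=True)
class CohortRecord:
    """One person's linkage row.

    ``exit_date`` is the death date when ``died`` is set, otherwise the
    administrative censoring date.  ``soc_code`` is ``None`` when no
    occupation was reported.
    """

    person_id: str
    sex: str
    age_at_census: float
    soc_code: Optional[str]
    geography: str
    entry_date: dt.date
    exit_date: dt.date
    died: bool

    def __post_init__(self) -> None:
        if not self.entry_date < self.exit_date:
            raise ValueError(
                f"{self.person_id}: entry {self.entry_date} not before "
                f"exit {self.exit_date}"
            )

    @property
    def follow_up_years(self) -> float:
        return (self.exit_date - self.entry_date).days / DAYS_PER_YEAR


@dataclass(frozen=True)
class GroupSpec:
    """Target occupation group in a simulation: prevalence share and
    standardised mortality rate (per 100 000 person-years)."""

    group_id: str
    prevalence: float
    rate: float
    soc_code: Optional[str] = None  # blank = no occupation reported

    def __post_init__(self) -> None:
        if self.prevalence < 0:
            raise ValueError(f"{self.group_id}: negative prevalence")
        if self.rate < 0:
            raise ValueError(f"{self.group_id}: negative rate")
        if self.soc_code:
            parse_soc(self.soc_code)


def normalise_multipliers(
    raw: Sequence[float], weights: Sequence[float]
) -> np.ndarray:
    """Scale age-shape multipliers so their weighted mean is exactly one.

    *weights* are the standard-population weights for the same bands; they
    are renormalised internally, so any positive scaling is accepted.
    """
    m = np.asarray(raw, dtype=float)
    w = np.asarray(weights, dtype=float)
    if m.shape != w.shape:
        raise ValueError("multipliers and weights differ in length")
    if (m <= 0).any() or (w <= 0).any():
        raise ValueError("multipliers and weights must be positive")
    w = w / w.sum()
    return m / float(w @ m)


@dataclass
class SimulationConfig:
    """Full recipe for one (sex, geography) cohort.

    ``age_multipliers`` has one entry per 5-year attained-age band covering
    ``[age_range[0], age_range[1] + follow_up_years)`` and must satisfy
    sum(w_a * m_a) = 1 under the (renormalised) standard weights supplied
    in ``band_weights``; use :func:`normalise_multipliers` to construct it.
    """

    sex: str
    geography: str
    groups: Sequence[GroupSpec]
    n: int
    follow_up_years: float = 10.0
    census_date: dt.date = CENSUS_2001
    age_range: tuple[float, float] = (20.0, 60.0)
    age_multipliers: Optional[Sequence[float]] = None
    band_weights: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size n must be positive")
        prev = np.array([g.prevalence for g in self.groups], dtype=float)
        if prev.size == 0:
            raise ValueError("no groups configured")
        if abs(prev.sum() - 1.0) > 1e-9:
            raise ValueError(f"prevalences sum to {prev.sum()}, not 1")
        lo, hi = self.age_range
        self._band_edges = np.arange(
            5 * int(lo // 5),
            5 * int(-(-(hi + self.follow_up_years) // 5)) + 1,
            5,
            dtype=float,
        )
        nbands = len(self._band_edges) - 1
        if self.age_multipliers is None:
            self.age_multipliers = np.ones(nbands)
        self.age_multipliers = np.asarray(self.age_multipliers, dtype=float)
        if len(self.age_multipliers) != nbands:
            raise ValueError(
                f"need {nbands} age multipliers for bands "
                f"{self._band_edges[0]:g}-{self._band_edges[-1]:g}, "
                f"got {len(self.age_multipliers)}"
            )
        if (self.age_multipliers <= 0).any():
            raise ValueError("age multipliers must be positive")
        if self.band_weights is not None:
            w = np.asarray(self.band_weights, dtype=float)
            w = w / w.sum()
            if abs(float(w @ self.age_multipliers) - 1.0) > 1e-12:
                raise ValueError(
                    "age multipliers are not normalised against the "
                    "supplied band weights (sum w_a * m_a must be 1)"
                )

    @property
    def band_edges(self) -> np.ndarray:
        return self._band_edges


def simulate_cohort(config: SimulationConfig, seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Simulate a cohort; fully reproducible from *seed*.

    Death times are drawn band by band: within each attained-age band the
    hazard is constant, so the residual time to death in the band is
    exponential; a draw exceeding the time spent in the band means the
    person survives into the next one.  Censoring is administrative at
    ``follow_up_years`` after the census.

    Returns a :class:`pandas.DataFrame` with the cohort CSV schema; see
    :func:`records_from_frame` for dataclass rows.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = config.n
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, n)
    prev = np.array([g.prevalence for g in config.groups])
    gidx = rng.choice(len(config.groups), size=n, p=prev / prev.sum())
    rates = np.array([g.rate for g in config.groups])[gidx] / 1e5

    edges = config.band_edges
    mult = np.asarray(config.age_multipliers, dtype=float)
    T = config.follow_up_years
    end_age = ages + T
    b0 = np.searchsorted(edges, ages, side="right") - 1

    time_to_death = np.full(n, np.inf)
    alive = np.ones(n, dtype=bool)
    max_segments = int(np.ceil(T / 5)) + 1
    for k in range(max_segments):
        band = b0 + k
        valid = band < len(mult)
        seg_lo = np.maximum(ages, edges[np.minimum(band, len(mult))])
        seg_hi = np.minimum(end_age, edges[np.minimum(band + 1, len(mult))])
        dur = np.clip(seg_hi - seg_lo, 0.0, None)
        lam = np.where(valid, rates * mult[np.minimum(band, len(mult) - 1)], 0.0)
        # exponential residual lifetime within the band (inf when hazard 0)
        u = rng.random(n)
        with np.errstate(divide="ignore"):
            t_seg = np.where(lam > 0, -np.log(u) / np.where(lam > 0, lam, 1.0),
                             np.inf)
        dies_here = alive & valid & (dur > 0) & (t_seg < dur)
        time_to_death[dies_here] = (seg_lo + t_seg)[dies_here] - ages[dies_here]
        alive &= ~dies_here

    died = np.isfinite(time_to_death)
    follow = np.where(died, time_to_death, T)
    days = np.maximum(1, np.rint(follow * DAYS_PER_YEAR).astype(int))
    entry = config.census_date
    exit_dates = [entry + dt.timedelta(days=int(d)) for d in days]

    soc = np.array([g.soc_code or "" for g in config.groups], dtype=object)[gidx]
    return pd.DataFrame({
        "person_id": [f"{config.geography}-{config.sex[0]}-{i}" for i in range(n)],
        "sex": config.sex,
        "age_at_census": ages,
        "soc_code": soc,
        "geography": config.geography,
        "entry_date": entry,
        "exit_date": exit_dates,
        "died": died.astype(int),
    })


def records_from_frame(frame: pd.DataFrame) -> list[CohortRecord]:
    """Materialise dataclass rows from a cohort frame."""
    return [
        CohortRecord(
            person_id=str(r.person_id),
            sex=str(r.sex),
            age_at_census=float(r.age_at_census),
            soc_code=(str(r.soc_code) if str(r.soc_code).strip() else None),
            geography=str(r.geography),
            entry_date=_as_date(r.entry_date),
            exit_date=_as_date(r.exit_date),
            died=bool(int(r.died)),
        )
        for r in frame.itertuples(index=False)
    ]


def _as_date(x) -> dt.date:
    if isinstance(x, dt.date) and not isinstance(x, dt.datetime):
        return x
    return pd.Timestamp(x).date()


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write a cohort CSV (ISO-8601 dates, died as 0/1)."""
    out = frame.loc[:, COHORT_COLUMNS].copy()
    out["entry_date"] = out["entry_date"].map(lambda d: _as_date(d).isoformat())
    out["exit_date"] = out["exit_date"].map(lambda d: _as_date(d).isoformat())
    out["died"] = out["died"].astype(int)
    out.to_csv(path, index=False)


def read_cohort(path, follow_up_years: Optional[float] = None) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Malformed rows are reported with their file line number (header is
    line 1).  When *follow_up_years* is given, exit dates beyond entry +
    follow-up are rejected.
    """
    frame = pd.read_csv(path, dtype={"soc_code": str}, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    errors = []
    entry, exit_ = [], []
    for i, r in enumerate(frame.itertuples(index=False)):
        line = i + 2
        try:
            e = dt.date.fromisoformat(str(r.entry_date))
            x = dt.date.fromisoformat(str(r.exit_date))
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
            entry.append(None)
            exit_.append(None)
            continue
        entry.append(e)
        exit_.append(x)
        if not e < x:
            errors.append(f"line {line}: entry {e} not before exit {x}")
        elif follow_up_years is not None:
            max_days = follow_up_years * DAYS_PER_YEAR
            if (x - e).days > max_days:
                errors.append(
                    f"line {line}: follow-up {(x - e).days} days exceeds "
                    f"{follow_up_years} years"
                )
        try:
            parse_soc(str(r.soc_code), row=line)
        except ValueError as exc:
            errors.append(str(exc))
        if not (0 <= float(r.age_at_census) < 130):
            errors.append(f"line {line}: implausible age {r.age_at_census}")
    if errors:
        raise ValueError(f"{path}: invalid cohort rows:\n  " + "\n  ".join(errors))
    frame["entry_date"] = entry
    frame["exit_date"] = exit_
    frame["age_at_census"] = frame["age_at_census"].astype(float)
    frame["died"] = frame["died"].astype(int)
    return frame
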