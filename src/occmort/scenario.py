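"""Counterfactual expected-deaths scenarios between geographies.

The engine scales the occupation structure observed in a cohort sample up
to a national working-age population: group g receives

    P_g = (PY_g / sum_g PY_g) * W

persons, where PY_g is the sample person-years in group g and W the
national working-age population count for that sex.  Treating persons as
annual person-years at risk, expected deaths per year under a rate table
are D_g = rate_g * P_g / 100 000.  A counterfactual scenario swaps in
another geography's occupation-specific rates and reports the per-group
and total change in expected deaths per year, with 95% intervals from
Monte Carlo draws of every rate from its normal approximation.

Within one simulation draw the group changes add up to the total change
exactly, so the reported totals are internally consistent.  When the
counterfactual table is value-identical to the baseline the draws are
shared and the excess is exactly zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .montecarlo import DEFAULT_N_SIM, _with_se

__all__ = ["SyntheticPopulation", "ScenarioResult", "build_population",
           "expected_deaths", "run_scenario"]


@dataclass(frozen=True)
class SyntheticPopulation:
    """National working-age population allocated to occupation groups."""

    persons: pd.Series  # group_id -> persons (annual person-years at risk)
    geography: str = ""
    sex: str = ""

    @property
    def total(self) -> float:
        return float(self.persons.sum())


def build_population(
    sample_py: pd.Series | dict,
    working_age_population: float,
    geography: str = "",
    sex: str = "",
) -> SyntheticPopulation:
    """Proportionally allocate a national count across occupation groups.

    ``sample_py`` maps group id (including the no-occupation group) to the
    person-years observed for that group in the cohort sample.
    """
    py = pd.Series(sample_py, dtype=float)
    if (py < 0).any():
        raise ValueError("negative sample person-years")
    if py.sum() <= 0:
        raise ValueError("sample person-years sum to zero")
    if working_age_population <= 0:
        raise ValueError("working-age population must be positive")
    persons = py / py.sum() * float(working_age_population)
    return SyntheticPopulation(persons=persons, geography=geography, sex=sex)


def expected_deaths(pop: SyntheticPopulation, rates: pd.DataFrame) -> pd.Series:
    """Expected deaths per year per group: D_g = rate_g * P_g / 100 000.

    Groups with people but no available rate (suppressed cells) are
    excluded with a warning, mirroring the situation where no rate could
    be estimated for a small part of the population.
    """
    rate_by_group = rates.set_index("group_id")["rate"]
    missing = [g for g in pop.persons.index
               if g not in rate_by_group.index and pop.persons[g] > 0]
    if missing:
        warnings.warn(
            f"no rate for groups {missing}; excluded from expected deaths",
            stacklevel=2,
        )
    shared = [g for g in pop.persons.index if g in rate_by_group.index]
    return pop.persons[shared] * rate_by_group[shared] / 1e5


@dataclass(frozen=True)
class ScenarioResult:
    """Per-group and total expected/excess deaths under a rate swap.

    ``table`` has one row per group: persons, both rates, the rate
    difference with Monte Carlo CI and p value, expected deaths under each
    table, and the change in expected deaths with CI.  ``total_*`` summarise
    the whole population; per draw the total equals the sum of the groups.
    """

    table: pd.DataFrame
    total_baseline: float
    total_counterfactual: float
    total_change: float
    total_change_ci: tuple[float, float]
    n_sim: int
    seed: Optional[int]


def run_scenario(
    pop: SyntheticPopulation,
    rates_baseline: pd.DataFrame,
    rates_counterfactual: pd.DataFrame,
    n_sim: int = DEFAULT_N_SIM,
    seed: Optional[int] = None,
) -> ScenarioResult:
    """Expected change in deaths if counterfactual rates replaced baseline.

    Rate tables need ``group_id``, ``label``, ``rate`` and ``se`` (or a CI
    to reconstruct it).  Groups lacking a rate in either table are dropped
    from both arms so the contrast is like-for-like.  Baseline and
    counterfactual draws are independent, except that a value-identical
    counterfactual table reuses the baseline draws, making the
    self-scenario excess exactly zero.
    """
    base = _with_se(rates_baseline).set_index("group_id")
    cf = _with_se(rates_counterfactual).set_index("group_id")
    groups = [g for g in pop.persons.index
              if g in base.index and g in cf.index]
    dropped = [g for g in pop.persons.index if g not in groups]
    if dropped:
        warnings.warn(
            f"groups {dropped} lack a rate in one of the tables; dropped "
            "from both arms of the comparison",
            stacklevel=2,
        )
    if not groups:
        raise ValueError("no group has rates in both tables")

    P = pop.persons[groups].to_numpy(dtype=float)
    rb = base.loc[groups, "rate"].to_numpy(dtype=float)
    sb = base.loc[groups, "se"].to_numpy(dtype=float)
    rc = cf.loc[groups, "rate"].to_numpy(dtype=float)
    sc = cf.loc[groups, "se"].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    draws_b = rb + sb * rng.standard_normal((n_sim, len(groups)))
    identical = np.array_equal(rb, rc) and np.array_equal(sb, sc)
    if identical:
        draws_c = draws_b
    else:
        draws_c = rc + sc * rng.standard_normal((n_sim, len(groups)))

    rate_diff = draws_c - draws_b              # per 100 000 PY, per draw
    delta = rate_diff * P / 1e5                # deaths/year change, per draw
    delta_total = delta.sum(axis=1)

    q = [0.025, 0.975]
    d_lo, d_hi = np.quantile(rate_diff, q, axis=0)
    c_lo, c_hi = np.quantile(delta, q, axis=0)
    t_lo, t_hi = np.quantile(delta_total, q)
    share_pos = (rate_diff > 0).mean(axis=0)
    share_neg = (rate_diff < 0).mean(axis=0)
    p = np.maximum(1.0 / n_sim, 2.0 * np.minimum(share_pos, share_neg))

    D_base = rb * P / 1e5
    D_cf = rc * P / 1e5
    table = pd.DataFrame({
        "group_id": groups,
        "label": base.loc[groups, "label"].to_numpy(),
        "persons": P,
        "rate_baseline": rb,
        "rate_counterfactual": rc,
        "rate_diff": rate_diff.mean(axis=0),
        "rate_diff_ci_low": d_lo,
        "rate_diff_ci_high": d_hi,
        "p_value": np.minimum(p, 1.0),
        "expected_baseline": D_base,
        "expected_counterfactual": D_cf,
        "change": delta.mean(axis=0),
        "change_ci_low": c_lo,
        "change_ci_high": c_hi,
    })
    return ScenarioResult(
        table=table,
        total_baseline=float(D_base.sum()),
        total_counterfactual=float(D_cf.sum()),
        total_change=float(delta_total.mean()),
        total_change_ci=(float(t_lo), float(t_hi)),
        n_sim=n_sim,
        seed=seed,
    )
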