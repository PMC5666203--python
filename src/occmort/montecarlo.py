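"""Monte Carlo inference for differences between age-standardised rates.

When two rates come from separate safe settings (different countries, or
different census cohorts), no joint model is available, but each published
rate carries a mean and a standard error.  The procedure simulates many
(default 10 000) independent normal draws for each rate, differences them
draw by draw, and reads the 95% interval off the empirical 2.5% and 97.5%
quantiles of the simulated differences; the two-sided p value is twice the
smaller tail share, floored at 1/n_sim.  Rates are modelled as normal (not
Poisson) because published tables expose only the rate and its interval,
never the underlying death counts; negative draws are therefore possible
and deliberately not truncated.

Standard errors can be reconstructed from a printed 95% interval as
(high - low) / (2 * 1.959964).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .rates import Z95

__all__ = ["RateSummary", "RateDifference", "se_from_ci", "mc_difference",
           "compare_tables"]

log = logging.getLogger(__name__)

DEFAULT_N_SIM = 10_000


@dataclass(frozen=True)
class RateSummary:
    """A standardised rate reduced to its mean and standard error."""

    label: str
    rate: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.label}: se must be positive")

    @classmethod
    def from_ci(cls, label: str, rate: float, ci_low: float,
                ci_high: float) -> "RateSummary":
        return cls(label=label, rate=rate, se=se_from_ci(ci_low, ci_high))


@dataclass(frozen=True)
class RateDifference:
    """Simulated contrast of two rates (B minus A), per 100 000 PY."""

    label: str
    diff: float
    ci_low: float
    ci_high: float
    p_value: float
    n_sim: int
    seed: Optional[int] = None


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Standard error implied by a symmetric normal 95% interval."""
    if not ci_high > ci_low:
        raise ValueError(f"interval ({ci_low}, {ci_high}) has no width")
    return (ci_high - ci_low) / (2 * Z95)


def mc_difference(
    a: RateSummary,
    b: RateSummary,
    n_sim: int = DEFAULT_N_SIM,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> RateDifference:
    """Simulate the difference B - A between two summarised rates.

    Draws ``n_sim`` independent pairs, one normal draw per rate, and
    summarises their differences.  The draw stream is attached to the
    summary with the lexicographically smaller label, so swapping the
    arguments (same seed) mirrors the result exactly.
    """
    if n_sim < 100:
        raise ValueError("n_sim < 100 makes the quantiles unstable")
    if rng is None:
        rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_sim)
    z2 = rng.standard_normal(n_sim)
    if b.label < a.label:
        z1, z2 = z2, z1
    x_a = a.rate + a.se * z1
    x_b = b.rate + b.se * z2
    diffs = x_b - x_a
    lo, hi = np.quantile(diffs, [0.025, 0.975])
    share_pos = float(np.mean(diffs > 0))
    share_neg = float(np.mean(diffs < 0))
    p = max(1.0 / n_sim, 2.0 * min(share_pos, share_neg))
    return RateDifference(
        label=f"{b.label} - {a.label}",
        diff=float(diffs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(min(p, 1.0)),
        n_sim=n_sim,
        seed=seed,
    )


def compare_tables(
    rates_a: pd.DataFrame,
    rates_b: pd.DataFrame,
    n_sim: int = DEFAULT_N_SIM,
    seed: Optional[int] = None,
    join_on: str = "group_id",
) -> pd.DataFrame:
    """Per-group Monte Carlo differences between two rate tables (B - A).

    Tables need columns ``group_id``, ``label``, ``rate`` and either ``se``
    or ``ci_low``/``ci_high``.  Groups present in only one table (for
    example suppressed at one timepoint) are skipped with a log entry.
    Each group gets an independent, deterministic substream of the master
    seed, so row order does not affect results.
    """
    a = _with_se(rates_a).set_index(join_on)
    b = _with_se(rates_b).set_index(join_on)
    shared = [g for g in a.index if g in set(b.index)]
    skipped = sorted(set(a.index).symmetric_difference(b.index))
    for g in skipped:
        log.info("group %r present in only one table; skipped", g)
    if not shared:
        raise ValueError("the two rate tables share no groups")

    ss = np.random.SeedSequence(seed)
    children = dict(zip(sorted(shared), ss.spawn(len(shared))))
    rows = []
    for gid in shared:
        ra, rb = a.loc[gid], b.loc[gid]
        res = mc_difference(
            RateSummary(str(ra["label"]), float(ra["rate"]), float(ra["se"])),
            RateSummary(str(rb["label"]), float(rb["rate"]), float(rb["se"])),
            n_sim=n_sim,
            rng=np.random.default_rng(children[gid]),
        )
        rows.append({
            join_on: gid,
            "label": ra["label"],
            "rate_a": float(ra["rate"]),
            "rate_b": float(rb["rate"]),
            "diff": res.diff,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "p_value": res.p_value,
        })
    return pd.DataFrame(rows)


def _with_se(rates: pd.DataFrame) -> pd.DataFrame:
    out = rates.copy()
    if "se" not in out.columns or out["se"].isna().any():
        out["se"] = [
            se_from_ci(lo, hi)
            for lo, hi in zip(out["ci_low"], out["ci_high"])
        ]
    return out
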