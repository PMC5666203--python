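"""End-to-end pipeline orchestration and publication-style table output.

``run_pipeline`` wires the stages together for one run: read (or simulate)
a cohort, tabulate deaths and person-years, collapse the grouping until
every published group clears the disclosure threshold, standardise, and
optionally compare against a second rate table and run a counterfactual
deaths scenario.  Every machine-readable artifact is a CSV under the
configured output directory; a run log records the package version, seed,
a hash of the configuration, and any warnings (weight renormalisations,
dropped groups) as machine-parsable lines.  All randomness flows from the
single configured seed, so a rerun reproduces the artifacts byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__, datasets
from .cohort import read_cohort
from .lexis import tabulate
from .montecarlo import DEFAULT_N_SIM, compare_tables
from .rates import StandardPopulation, standardised_rates, rank_table
from .scenario import build_population, run_scenario
from .soc import GroupingScheme, MIN_DEATHS, collapse_until_publishable

__all__ = ["RunConfig", "run_pipeline", "render_rate_table",
           "render_diff_table", "render_scenario_table"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``compare_with`` points at a second rate table CSV (columns group_id,
    label, rate, ci_low, ci_high) to difference against the run's own
    rates.  ``scenario`` holds ``counterfactual`` (rate table CSV) and
    ``working_age_population`` (the national count W) to run the rate-swap
    scenario on the run's own cohort.
    """

    cohort: str
    grouping: str | None = None          # CSV path; None = packaged, by sex
    sex: str = ""
    standard_population: str | None = None  # CSV path; None = ESP 2013
    age_basis: str = "attained"
    min_deaths: int = MIN_DEATHS
    n_sim: int = DEFAULT_N_SIM
    seed: int = 0
    output_dir: str = "occmort-out"
    follow_up_years: Optional[float] = None
    compare_with: Optional[str] = None
    scenario: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.n_sim < 100:
            raise ValueError("n_sim must be at least 100")
        if self.age_basis not in ("attained", "baseline"):
            raise ValueError(f"unknown age basis {self.age_basis!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
            .encode()
        ).hexdigest()[:16]


def _stage(name):
    """Decorator: re-raise stage failures with the stage name attached."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the pipeline; returns a name -> path map of written artifacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    messages: list[str] = []
    artifacts: dict[str, Path] = {}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        cohort = _stage("read_cohort")(read_cohort)(
            config.cohort, follow_up_years=config.follow_up_years)
        if config.grouping:
            scheme = GroupingScheme.from_csv(
                config.grouping, sex=config.sex, min_deaths=config.min_deaths)
        else:
            scheme = datasets.published_grouping(
                config.sex or str(cohort["sex"].iloc[0]),
                min_deaths=config.min_deaths)
        std = (StandardPopulation.from_csv(config.standard_population)
               if config.standard_population else datasets.esp2013())

        strata = _stage("tabulate")(tabulate)(
            cohort, scheme, age_basis=config.age_basis)
        deaths_by_group = strata.groupby("group_id")["deaths"].sum().to_dict()
        collapsed = _stage("collapse")(collapse_until_publishable)(
            deaths_by_group, scheme)
        if [g.group_id for g in collapsed.groups] != [g.group_id for g in scheme.groups]:
            messages.append("INFO collapse merged under-threshold groups")
            strata = _stage("tabulate")(tabulate)(
                cohort, collapsed, age_basis=config.age_basis)
        labels = {g.group_id: g.label for g in collapsed.groups}
        rates = _stage("standardise")(standardised_rates)(
            strata, std, min_deaths=config.min_deaths, labels=labels)

        strata_path = outdir / "strata.csv"
        strata.to_csv(strata_path, index=False)
        artifacts["strata"] = strata_path
        rates_path = outdir / "rates.csv"
        rates.to_csv(rates_path, index=False)
        artifacts["rates"] = rates_path

        if config.compare_with:
            other = pd.read_csv(config.compare_with, dtype={"group_id": str})
            pub = rates[~rates["suppressed"]]
            diffs = _stage("compare")(compare_tables)(
                pub, other, n_sim=config.n_sim, seed=config.seed)
            diffs_path = outdir / "diffs.csv"
            diffs.to_csv(diffs_path, index=False)
            artifacts["diffs"] = diffs_path

        if config.scenario:
            cf = pd.read_csv(config.scenario["counterfactual"],
                             dtype={"group_id": str})
            W = float(config.scenario["working_age_population"])
            pop = build_population(
                strata.groupby("group_id")["person_years"].sum(), W)
            pub = rates[~rates["suppressed"]]
            res = _stage("scenario")(run_scenario)(
                pop, pub, cf, n_sim=config.n_sim, seed=config.seed)
            scen_path = outdir / "scenario.csv"
            res.table.to_csv(scen_path, index=False)
            artifacts["scenario"] = scen_path
            messages.append(
                f"INFO scenario total change {res.total_change:.1f} "
                f"({res.total_change_ci[0]:.1f} to {res.total_change_ci[1]:.1f})"
            )

        for w in caught:
            messages.append(f"WARNING {w.message}")

    logpath = outdir / "run.log"
    with open(logpath, "w") as fh:
        fh.write(f"occmort {__version__}\n")
        fh.write(f"seed {config.seed}\n")
        fh.write(f"config sha256:{config.digest()}\n")
        for m in messages:
            fh.write(m + "\n")
    artifacts["log"] = logpath
    for m in messages:
        log.info("%s", m)
    return artifacts


# ------------------------------------------------------------- text tables

def _fmt_int(x) -> str:
    return f"{x:,.0f}".replace(",", " ")


def render_rate_table(rates: pd.DataFrame, title: str = "") -> str:
    """Ranked publication-style listing of a rates table.

    Suppressed groups are left out of the body and counted in the footer;
    rates display as integers per 100 000 person-years.
    """
    ranked = rank_table(rates)
    lines = [title] if title else []
    lines.append(f"{'Rank':>4}  {'SOC':<6} {'Label':<55} "
                 f"{'Person-years':>13}  Mortality rate (95% CI)")
    for r in ranked.itertuples(index=False):
        py = _fmt_int(r.person_years) if pd.notna(r.person_years) else ".."
        lines.append(f"{r.rank:>4}  {r.group_id:<6} {r.label[:55]:<55} "
                     f"{py:>13}  {r.display}")
    n_sup = int(rates["suppressed"].sum()) if "suppressed" in rates else 0
    if n_sup:
        lines.append(f"({n_sup} group(s) suppressed: fewer than 10 deaths)")
    if "max_min_ratio" in ranked.attrs:
        lines.append(f"max/min published rate ratio: "
                     f"{ranked.attrs['max_min_ratio']:.2f}")
    return "\n".join(lines)


def render_diff_table(diffs: pd.DataFrame, title: str = "") -> str:
    """Monte Carlo difference table in published column order."""
    lines = [title] if title else []
    lines.append(f"{'SOC':<6} {'Label':<55} {'Rate A':>7} {'Rate B':>7} "
                 f"{'Difference (95% CI)':>24}  p value")
    for r in diffs.itertuples(index=False):
        ci = f"{r.diff:.0f} ({r.ci_low:.0f} to {r.ci_high:.0f})"
        lines.append(f"{r.group_id:<6} {r.label[:55]:<55} {r.rate_a:>7.0f} "
                     f"{r.rate_b:>7.0f} {ci:>24}  {_fmt_p(r.p_value)}")
    return "\n".join(lines)


def render_scenario_table(result, title: str = "") -> str:
    """Expected-change-in-deaths table with the totals row."""
    lines = [title] if title else []
    lines.append(f"{'SOC':<6} {'Label':<55} "
                 f"{'Rate difference (95% CI)':>26}  {'p':>6}  "
                 f"Expected change in deaths (95% CI)")
    for r in result.table.itertuples(index=False):
        rd = f"{r.rate_diff:.0f} ({r.rate_diff_ci_low:.0f} to {r.rate_diff_ci_high:.0f})"
        ch = f"{r.change:.1f} ({r.change_ci_low:.1f} to {r.change_ci_high:.1f})"
        lines.append(f"{r.group_id:<6} {r.label[:55]:<55} {rd:>26}  "
                     f"{_fmt_p(r.p_value):>6}  {ch}")
    lo, hi = result.total_change_ci
    lines.append(f"{'Total':<62} {'':>26}  {'':>6}  "
                 f"{result.total_change:.1f} ({lo:.1f} to {hi:.1f})")
    return "\n".join(lines)


def _fmt_p(p: float) -> str:
    return f"{p:.3f}" if p < 0.01 else f"{p:.2f}"
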