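"""Time-weighted average exposure engine.

The model is the classic microenvironment (ME) decomposition of daily
exposure: a person's 24-h average exposure is

    E = sum_i C_i * T_i

where ``C_i`` is the particle number concentration in the i-th ME (pt/cm^3)
and ``T_i`` the fraction of the day spent there.  Both are uncertain and are
sampled — concentrations from moment-matched lognormals, time fractions
from moment-matched betas — by Latin hypercube over all 2N parameters of a
scenario, independently within and across MEs.  Each iteration yields a
partial exposure per ME, cumulative sums over the in-transit / indoor /
outdoor categories, and their total.

Time fractions are *not* renormalised to sum to one per iteration by
default: the study tables' printed totals equal the sum of the per-ME mean
products, which holds only without renormalisation.  A ``renormalize_time``
flag imposes a strict 24-h budget for users who want it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lhs import lhs_uniform, sample_from
from .moments import MomentSpec, Support, fit_beta, fit_lognormal

__all__ = [
    "CATEGORIES",
    "MicroenvironmentTable",
    "TimeProfile",
    "Scenario",
    "ExposureDraws",
    "simulate",
    "aggregate",
    "summarize",
    "run_study",
    "ScenarioResult",
    "derive_scenario_seed",
]

CATEGORIES = ("in_transit", "indoor", "outdoor")

#: validation band for the sum of printed (rounded) daily fractions
FRACTION_SUM_TOL = (0.95, 1.05)


@dataclass(frozen=True)
class MicroenvironmentTable:
    """Per-ME, per-season concentration moments plus the category grouping.

    ``data`` columns: ``me_id, category, season, mean_pt_cm3, sd_pt_cm3,
    sampling_hours``.  Row order of first appearance of each ``me_id`` fixes
    the parameter order used for sampling.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "me_id",
            "category",
            "season",
            "mean_pt_cm3",
            "sd_pt_cm3",
            "sampling_hours",
        }
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if self.data.duplicated(["me_id", "season"]).any():
            raise ValueError("duplicate (me_id, season) rows")
        if (self.data["mean_pt_cm3"] < 0).any():
            raise ValueError("negative concentration mean")
        if (self.data["sd_pt_cm3"] < 0).any():
            raise ValueError("negative concentration sd")
        bad = set(self.data["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")

    @property
    def me_ids(self) -> tuple[str, ...]:
        """MEs in fixed (first-appearance) row order."""
        return tuple(dict.fromkeys(self.data["me_id"]))

    @property
    def seasons(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.data["season"]))

    @property
    def grouping(self) -> dict[str, str]:
        """ME -> category map."""
        return dict(zip(self.data["me_id"], self.data["category"]))

    def season_moments(self, season: str) -> dict[str, MomentSpec]:
        sub = self.data[self.data["season"] == season]
        if sub.empty:
            raise KeyError(f"season {season!r} not in table")
        return {
            row.me_id: MomentSpec(
                mean=float(row.mean_pt_cm3),
                sd=float(row.sd_pt_cm3),
                support=Support.positive_real,
            )
            for row in sub.itertuples()
        }


@dataclass(frozen=True)
class TimeProfile:
    """Daily time-fraction moments per ME for one subpopulation profile."""

    profile_id: str
    data: pd.DataFrame  # columns: me_id, mean_fraction, sd_fraction
    validate_sum: bool = True  # sensitivity probes deliberately break the budget

    def __post_init__(self) -> None:
        required = {"me_id", "mean_fraction", "sd_fraction"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        m = self.data["mean_fraction"]
        if ((m < 0) | (m > 1)).any():
            raise ValueError("mean_fraction outside [0, 1]")
        if (self.data["sd_fraction"] < 0).any():
            raise ValueError("negative sd_fraction")
        total = float(m.sum())
        lo, hi = FRACTION_SUM_TOL
        if self.validate_sum and not lo <= total <= hi:
            raise ValueError(
                f"profile {self.profile_id!r}: fractions sum to {total:.3f}, "
                f"outside [{lo}, {hi}]"
            )

    def moments(self) -> dict[str, MomentSpec]:
        return {
            row.me_id: MomentSpec(
                mean=float(row.mean_fraction),
                sd=float(row.sd_fraction),
                support=Support.unit_interval,
            )
            for row in self.data.itertuples()
        }


@dataclass(frozen=True)
class Scenario:
    """One (profile, season) simulation request."""

    profile_id: str
    season: str
    n_iterations: int = 2000
    seed: int = 0
    renormalize_time: bool = False
    infeasible_policy: str = "error"


@dataclass(frozen=True)
class ExposureDraws:
    """Per-iteration partial, cumulative and total exposures (pt/cm^3)."""

    partial: pd.DataFrame  # n_iterations x N, columns = me_ids
    cumulative: pd.DataFrame  # columns = categories
    total: pd.Series
    scenario: Scenario
    grouping: Mapping[str, str]


@dataclass(frozen=True)
class ScenarioResult:
    draws: ExposureDraws
    summary: pd.DataFrame


def _sampled_matrix(
    specs: Mapping[str, MomentSpec],
    uniforms,
    me_ids: Sequence[str],
    prefix: str,
    infeasible_policy: str,
) -> np.ndarray:
    cols = []
    for me in me_ids:
        spec = specs[me]
        if spec.support == Support.unit_interval:
            dist = fit_beta(spec, infeasible_policy=infeasible_policy)
        else:
            dist = fit_lognormal(spec)
        cols.append(sample_from(dist, uniforms.column(f"{prefix}:{me}")))
    return np.column_stack(cols)


def simulate(
    scenario: Scenario, conc: MicroenvironmentTable, time: TimeProfile
) -> ExposureDraws:
    """Run one Latin-hypercube exposure simulation.

    Samples the N time fractions and N concentrations of the scenario
    (2N LHS columns, time parameters first, MEs in table row order), forms
    ``partial[it, i] = T_i[it] * C_i[it]`` and sums per iteration.
    """
    me_ids = conc.me_ids
    tmoms = time.moments()
    missing = set(me_ids) - set(tmoms)
    if missing:
        raise ValueError(
            f"profile {time.profile_id!r} lacks MEs: {sorted(missing)}"
        )
    cmoms = conc.season_moments(scenario.season)
    param_ids = [f"time:{me}" for me in me_ids] + [f"conc:{me}" for me in me_ids]
    uniforms = lhs_uniform(
        scenario.n_iterations, len(param_ids), scenario.seed, param_ids
    )
    T = _sampled_matrix(tmoms, uniforms, me_ids, "time", scenario.infeasible_policy)
    C = _sampled_matrix(cmoms, uniforms, me_ids, "conc", scenario.infeasible_policy)
    if scenario.renormalize_time:
        T = T / T.sum(axis=1, keepdims=True)
    partial = pd.DataFrame(T * C, columns=list(me_ids))
    total = partial.sum(axis=1)
    total.name = "total"
    draws = ExposureDraws(
        partial=partial,
        cumulative=pd.DataFrame(index=partial.index),
        total=total,
        scenario=scenario,
        grouping=conc.grouping,
    )
    return aggregate(draws, conc.grouping)


def aggregate(draws: ExposureDraws, grouping: Mapping[str, str]) -> ExposureDraws:
    """Per-iteration cumulative sums over a ME -> category grouping."""
    unassigned = set(draws.partial.columns) - set(grouping)
    if unassigned:
        raise ValueError(f"MEs without a category: {sorted(unassigned)}")
    cumulative = pd.DataFrame(index=draws.partial.index)
    for cat in dict.fromkeys(grouping.values()):
        members = [me for me in draws.partial.columns if grouping[me] == cat]
        cumulative[cat] = draws.partial[members].sum(axis=1)
    return ExposureDraws(
        partial=draws.partial,
        cumulative=cumulative,
        total=draws.total,
        scenario=draws.scenario,
        grouping=dict(grouping),
    )


def summarize(draws: ExposureDraws) -> pd.DataFrame:
    """Descriptive statistics per ME and cumulative group.

    Columns: mean, mean_pct (share of mean total, %), sd (n-1 denominator),
    min, p5, median, p95, max; percentiles by linear interpolation between
    order statistics.  One row per ME, then one per cumulative category,
    then ``total``.
    """
    if len(draws.total) < 2:
        raise ValueError("need at least 2 iterations to summarize")
    columns = {me: draws.partial[me] for me in draws.partial.columns}
    columns.update({cat: draws.cumulative[cat] for cat in draws.cumulative.columns})
    columns["total"] = draws.total
    mean_total = float(draws.total.mean())
    rows = {}
    for name, col in columns.items():
        v = col.to_numpy()
        rows[name] = {
            "mean": v.mean(),
            "mean_pct": 100.0 * v.mean() / mean_total,
            "sd": v.std(ddof=1),
            "min": v.min(),
            "p5": np.percentile(v, 5),
            "median": np.percentile(v, 50),
            "p95": np.percentile(v, 95),
            "max": v.max(),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def derive_scenario_seed(master_seed: int, index: int) -> int:
    """Deterministic 31-bit per-scenario seed from a master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_study(
    profiles: Iterable[TimeProfile],
    conc: MicroenvironmentTable,
    seasons: Sequence[str] | None = None,
    n_iterations: int = 2000,
    seed: int = 0,
    renormalize_time: bool = False,
    infeasible_policy: str = "error",
) -> dict[tuple[str, str], ScenarioResult]:
    """Simulate and summarize every (profile, season) combination.

    Per-scenario seeds are derived deterministically from the master seed in
    enumeration order, so the whole study is reproducible from one integer.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    if seasons is None:
        seasons = conc.seasons
    if not seasons:
        raise ValueError("need at least one season")
    results: dict[tuple[str, str], ScenarioResult] = {}
    for k, (profile, season) in enumerate(
        (p, s) for p in profiles for s in seasons
    ):
        scenario = Scenario(
            profile_id=profile.profile_id,
            season=season,
            n_iterations=n_iterations,
            seed=derive_scenario_seed(seed, k),
            renormalize_time=renormalize_time,
            infeasible_policy=infeasible_policy,
        )
        draws = simulate(scenario, conc, profile)
        results[(profile.profile_id, season)] = ScenarioResult(
            draws=draws, summary=summarize(draws)
        )
    return results
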