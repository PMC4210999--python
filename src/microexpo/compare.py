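"""Statistical contrasts between exposure distributions and sensitivity.

Two kinds of question are answered here.  First, whether simulated exposure
distributions differ — between seasons (Mann-Whitney U), across
microenvironments (Kruskal-Wallis), across factor-coded scenario designs
(factorial ANOVA with Helmert contrasts and Tukey HSD post-hoc), or whether
exposure tracks time use versus concentration (Spearman).  Second, which
inputs the exposure estimate is most sensitive to, via a nominal-range
(one-at-a-time) analysis.

The default grouping unit for hypothesis tests is scenario-level summary
means: testing on raw iteration draws is available but with thousands of
draws per scenario essentially any difference is "significant", so
draw-level reports are labelled as such.

Rank tests are delegated to scipy; the exact small-sample Mann-Whitney
p-value (pooled n <= 20) is enumerated here with average-rank tie handling,
which scipy's exact method does not provide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import (
    ExposureDraws,
    MicroenvironmentTable,
    Scenario,
    TimeProfile,
    simulate,
)
from .moments import MomentSpec, Support, fit_beta, fit_lognormal

__all__ = [
    "ComparisonReport",
    "SensitivityReport",
    "mann_whitney_u",
    "kruskal_wallis",
    "spearman",
    "factorial_anova",
    "nominal_range_sensitivity",
]

#: pooled sample size up to which the Mann-Whitney p-value is enumerated
EXACT_MWU_LIMIT = 20


@dataclass(frozen=True)
class ComparisonReport:
    """Outcome of one hypothesis test."""

    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    unit: str = "scenario_means"
    details: object = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.statistic):
            raise ValueError("statistic must be finite")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class SensitivityReport:
    """Nominal-range sensitivity: % change of mean total per input probe.

    ``table`` has one row per model input with its base mean, the low/high
    probe values, and the signed percent change of the mean total exposure
    when the input's mean is moved to each probe (all other inputs, the seed
    and the sampling plan held at base).
    """

    table: pd.DataFrame
    base_mean_total: float

    def ranked(self) -> pd.DataFrame:
        """Inputs ordered by influence (max |% change| over both probes)."""
        influence = self.table[["pct_change_low", "pct_change_high"]].abs().max(axis=1)
        return self.table.assign(influence=influence).sort_values(
            "influence", ascending=False
        )


def _exact_mwu_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact Mann-Whitney p by enumeration with average ranks."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n = len(a), len(pooled)
    mu = len(a) * len(b) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    unit: str = "scenario_means",
    group_names: tuple[str, str] = ("a", "b"),
) -> ComparisonReport:
    """Two-sided Mann-Whitney U rank-sum test.

    The reported statistic is U of the first sample (rank-sum convention
    ``U1 = R1 - n1(n1+1)/2``; the complementary value is ``n1*n2 - U1``).
    With pooled n <= 20 the p-value is an exact enumeration over all rank
    assignments, handling ties by average ranks; beyond that a normal
    approximation with tie correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # every rank assignment is tied; U sits at its null mean
        return ComparisonReport(
            test="mann_whitney_u", groups=group_names,
            statistic=a.size * b.size / 2.0, p_value=1.0, unit=unit,
        )
    u1 = float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")[0]
    )
    if a.size + b.size <= EXACT_MWU_LIMIT:
        p = _exact_mwu_p(a, b, u1)
    else:
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")[1]
        )
    return ComparisonReport(
        test="mann_whitney_u",
        groups=group_names,
        statistic=u1,
        p_value=p,
        unit=unit,
    )


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    unit: str = "scenario_means",
    group_names: tuple[str, ...] | None = None,
) -> ComparisonReport:
    """Kruskal-Wallis H test with tie correction, chi-square p (k-1 df).

    If every pooled observation is identical the H statistic is 0 by
    construction and the p-value is reported as 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    if group_names is None:
        group_names = tuple(f"g{i}" for i in range(len(arrays)))
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return ComparisonReport(
            test="kruskal_wallis", groups=group_names, statistic=0.0, p_value=1.0,
            unit=unit,
        )
    h, p = stats.kruskal(*arrays)
    return ComparisonReport(
        test="kruskal_wallis", groups=group_names, statistic=float(h),
        p_value=float(p), unit=unit,
    )


def spearman(
    x: Sequence[float], y: Sequence[float], unit: str = "scenario_means"
) -> ComparisonReport:
    """Spearman rank correlation (average ranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return ComparisonReport(
        test="spearman", groups=("x", "y"), statistic=float(rho),
        p_value=float(p), unit=unit,
    )


def factorial_anova(
    data: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    unit: str = "scenario_means",
) -> list[ComparisonReport]:
    """Factorial ANOVA over scenario means with Helmert-coded contrasts.

    ``data`` holds one row per scenario with the response (e.g. mean total
    exposure) and categorical factor columns (season, gender, ...).  The
    design must be balanced.  Returns one report per factor, each carrying
    a Tukey HSD pairwise post-hoc table in ``details``.  A response that is
    constant across all cells yields F = 0, p = 1 for every factor.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    factors = list(factors)
    if not factors:
        raise ValueError("need at least one factor")
    counts = data.groupby(factors, observed=True).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal cell counts")
    resp = data[response].to_numpy(dtype=float)
    reports = []
    if np.allclose(resp, resp[0]):
        for f in factors:
            reports.append(
                ComparisonReport(
                    test="factorial_anova", groups=(f,), statistic=0.0,
                    p_value=1.0, unit=unit,
                )
            )
        return reports
    terms = " + ".join(f"C({f}, Helmert)" for f in factors)
    model = smf.ols(f"{response} ~ {terms}", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    for f in factors:
        row = table.loc[f"C({f}, Helmert)"]
        tukey = pairwise_tukeyhsd(resp, data[f].astype(str).to_numpy())
        reports.append(
            ComparisonReport(
                test="factorial_anova",
                groups=(f,),
                statistic=float(row["F"]),
                p_value=float(row["PR(>F)"]),
                unit=unit,
                details=tukey.summary(),
            )
        )
    return reports


def _default_probes(spec: MomentSpec) -> tuple[float, float]:
    """p5-p95 of the moment-matched distribution for one input."""
    if spec.sd == 0:
        return spec.mean, spec.mean
    if spec.support == Support.unit_interval:
        dist = fit_beta(spec, infeasible_policy="clamp")
    else:
        dist = fit_lognormal(spec)
    lo, hi = dist.ppf(np.array([0.05, 0.95]))
    return float(lo), float(hi)


def nominal_range_sensitivity(
    scenario: Scenario,
    conc: MicroenvironmentTable,
    time: TimeProfile,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> SensitivityReport:
    """One-at-a-time sensitivity of the mean total exposure to each input.

    Every model input — the mean time fraction and the mean concentration
    of each microenvironment — is moved in turn to a low and a high probe
    value (default: the p5 and p95 of its moment-matched distribution,
    overridable through ``ranges`` keyed ``"time:ME"`` / ``"conc:ME"``)
    while its SD and every other input stay at base; the scenario is then
    re-simulated with the same seed.  Probe refits of time fractions use
    the clamp policy because an extreme probe mean with the base SD can
    violate the beta variance bound.  Because exposure is bilinear in the
    inputs, a zero-width probe reproduces the base run exactly.
    """
    base = simulate(scenario, conc, time)
    base_mean = float(base.total.mean())
    tmoms = time.moments()
    cmoms = conc.season_moments(scenario.season)
    probe_scenario = replace(scenario, infeasible_policy="clamp")
    rows = []
    for me in conc.me_ids:
        for kind, spec in (("time", tmoms[me]), ("conc", cmoms[me])):
            key = f"{kind}:{me}"
            if ranges is not None and key in ranges:
                lo, hi = ranges[key]
            else:
                lo, hi = _default_probes(spec)
            if not lo <= spec.mean <= hi:
                raise ValueError(
                    f"range ({lo}, {hi}) for {key} excludes base {spec.mean}"
                )
            changes = {}
            for label, probe in (("low", lo), ("high", hi)):
                if probe == spec.mean:
                    changes[label] = 0.0
                    continue
                if kind == "time":
                    new_time = _with_time_mean(time, me, probe)
                    draws = simulate(probe_scenario, conc, new_time)
                else:
                    new_conc = _with_conc_mean(conc, me, scenario.season, probe)
                    draws = simulate(probe_scenario, new_conc, time)
                changes[label] = 100.0 * (
                    float(draws.total.mean()) - base_mean
                ) / base_mean
            rows.append(
                {
                    "parameter": key,
                    "kind": kind,
                    "me_id": me,
                    "base": spec.mean,
                    "low": lo,
                    "high": hi,
                    "pct_change_low": changes["low"],
                    "pct_change_high": changes["high"],
                }
            )
    return SensitivityReport(table=pd.DataFrame(rows), base_mean_total=base_mean)


def _with_time_mean(time: TimeProfile, me: str, new_mean: float) -> TimeProfile:
    data = time.data.copy()
    data.loc[data["me_id"] == me, "mean_fraction"] = new_mean
    # probes deliberately break the 24-h budget; skip the sum validation
    return TimeProfile(
        profile_id=f"{time.profile_id}[{me}->{new_mean:g}]",
        data=data,
        validate_sum=False,
    )


def _with_conc_mean(
    conc: MicroenvironmentTable, me: str, season: str, new_mean: float
) -> MicroenvironmentTable:
    data = conc.data.copy()
    data["mean_pt_cm3"] = data["mean_pt_cm3"].astype(float)
    mask = (data["me_id"] == me) & (data["season"] == season)
    data.loc[mask, "mean_pt_cm3"] = new_mean
    return MicroenvironmentTable(data)
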