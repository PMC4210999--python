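"""Method-of-moments fitting of sampling distributions.

Study inputs arrive as printed (mean, SD) pairs: daily time fractions spent
in each microenvironment and particle number concentrations measured there.
Time fractions live on [0, 1] and are described by beta distributions;
concentrations are positive and described by lognormals.  Both families are
parameterised here so that their *analytic* first two moments reproduce the
given pair exactly, which makes the fit invertible and testable by a
round-trip identity.

Zero-spread inputs (SD = 0, or a boundary mean of exactly 0 or 1 for a
fraction) collapse to a point mass; these are represented as first-class
``degenerate`` distributions so downstream sampling needs no special cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "Support",
    "MomentSpec",
    "FittedDistribution",
    "InfeasibleMomentsError",
    "fit_beta",
    "fit_lognormal",
    "moments_of",
]

#: fraction of the beta SD upper bound used when clamping infeasible inputs
CLAMP_FACTOR = 0.95


class Support(str, Enum):
    """Support of a moment specification."""

    unit_interval = "unit_interval"
    positive_real = "positive_real"


class InfeasibleMomentsError(ValueError):
    """Raised when no distribution of the family matches the moments."""


@dataclass(frozen=True)
class MomentSpec:
    """A (mean, SD) pair with its support.

    Parameters
    ----------
    mean
        Mean of the quantity: a dimensionless fraction of the 24-h day in
        [0, 1] for time use, or a concentration in pt/cm^3.
    sd
        Standard deviation, same units, >= 0.
    support
        ``unit_interval`` for time fractions, ``positive_real`` for
        concentrations.
    """

    mean: float
    sd: float
    support: Support = Support.positive_real

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean) or not np.isfinite(self.sd):
            raise ValueError("mean and sd must be finite")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.support == Support.unit_interval:
            if not 0.0 <= self.mean <= 1.0:
                raise ValueError(
                    f"unit-interval mean must lie in [0, 1], got {self.mean}"
                )
        else:
            if self.mean < 0:
                raise ValueError(f"positive-real mean must be >= 0, got {self.mean}")
            if self.mean == 0 and self.sd > 0:
                raise ValueError("mean = 0 requires sd = 0")


@dataclass(frozen=True)
class FittedDistribution:
    """A beta, lognormal or degenerate distribution in natural parameters.

    Exactly the parameters of ``kind`` are meaningful: ``(alpha, beta_param)``
    for a beta, ``(mu, sigma)`` on the log scale for a lognormal, ``value``
    for a point mass.  ``clamped`` flags a beta whose input SD exceeded the
    feasible bound and was shrunk before fitting.
    """

    kind: Literal["beta", "lognormal", "degenerate"]
    alpha: float | None = None
    beta_param: float | None = None
    mu: float | None = None
    sigma: float | None = None
    value: float | None = None
    clamped: bool = field(default=False, compare=False)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF at probabilities ``u`` (vectorised)."""
        u = np.asarray(u, dtype=float)
        if np.any((u < 0) | (u >= 1)):
            raise ValueError("probabilities must lie in [0, 1)")
        if self.kind == "degenerate":
            return np.full_like(u, self.value)
        if self.kind == "beta":
            return stats.beta.ppf(u, self.alpha, self.beta_param)
        # scipy's lognorm: shape = sigma, scale = exp(mu)
        return stats.lognorm.ppf(u, self.sigma, scale=math.exp(self.mu))


def fit_beta(
    spec: MomentSpec, infeasible_policy: Literal["error", "clamp"] = "error"
) -> FittedDistribution:
    """Fit a beta distribution on [0, 1] by matching mean and SD.

    With ``m = mean`` and ``s = sd``, the moment equations give
    ``nu = m(1-m)/s^2 - 1``, ``alpha = m*nu``, ``beta = (1-m)*nu``, valid
    only while ``s^2 < m(1-m)``.  A zero SD, or a mean at either boundary,
    yields a point mass.  Printed SDs are rounded and occasionally violate
    the variance bound; ``infeasible_policy="clamp"`` then shrinks the SD to
    ``0.95 * sqrt(m(1-m))`` and refits, flagging the result, instead of
    silently altering inputs (the default raises).
    """
    if spec.support != Support.unit_interval:
        raise ValueError("fit_beta requires a unit_interval spec")
    m, s = spec.mean, spec.sd
    if s == 0.0 or m in (0.0, 1.0):
        return FittedDistribution(kind="degenerate", value=m)
    bound = m * (1.0 - m)
    clamped = False
    if s * s >= bound:
        if infeasible_policy == "error":
            raise InfeasibleMomentsError(
                f"sd^2 = {s * s:.6g} >= mean(1-mean) = {bound:.6g}; "
                "no beta distribution has these moments"
            )
        s = CLAMP_FACTOR * math.sqrt(bound)
        clamped = True
    nu = bound / (s * s) - 1.0
    return FittedDistribution(
        kind="beta", alpha=m * nu, beta_param=(1.0 - m) * nu, clamped=clamped
    )


def fit_lognormal(spec: MomentSpec) -> FittedDistribution:
    """Fit a lognormal by matching mean and SD.

    ``sigma^2 = ln(1 + (sd/mean)^2)`` and ``mu = ln(mean) - sigma^2/2``;
    every positive (mean, sd) pair is feasible.  SD = 0 yields a point mass
    at the mean.
    """
    if spec.support != Support.positive_real:
        raise ValueError("fit_lognormal requires a positive_real spec")
    m, s = spec.mean, spec.sd
    if s == 0.0:
        return FittedDistribution(kind="degenerate", value=m)
    sigma2 = math.log1p((s / m) ** 2)
    return FittedDistribution(
        kind="lognormal", mu=math.log(m) - sigma2 / 2.0, sigma=math.sqrt(sigma2)
    )


def moments_of(dist: FittedDistribution) -> MomentSpec:
    """Analytic mean and SD of a fitted distribution (inverse of the fits)."""
    if dist.kind == "degenerate":
        support = (
            Support.unit_interval
            if 0.0 <= dist.value <= 1.0
            else Support.positive_real
        )
        return MomentSpec(mean=dist.value, sd=0.0, support=support)
    if dist.kind == "beta":
        a, b = dist.alpha, dist.beta_param
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1.0))
        return MomentSpec(mean=mean, sd=math.sqrt(var), support=Support.unit_interval)
    mean = math.exp(dist.mu + dist.sigma**2 / 2.0)
    var = math.expm1(dist.sigma**2) * mean**2  # expm1 keeps tiny-sigma precision
    return MomentSpec(mean=mean, sd=math.sqrt(var), support=Support.positive_real)
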