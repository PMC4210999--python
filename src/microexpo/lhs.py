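"""Latin hypercube sampling with reproducible per-parameter substreams.

Each of ``n`` iterations receives exactly one uniform draw from each of the
``n`` equal-probability strata ``[i/n, (i+1)/n)`` of every parameter, with
the stratum order shuffled independently per parameter.  Compared with
simple random sampling this removes the between-stratum component of the
Monte Carlo variance of the sample mean, which is why a few thousand
iterations suffice for stable exposure means.

Substreams are derived from ``(master seed, column index)`` through numpy's
``SeedSequence`` so results are independent of dict/hash ordering; the
documented parameter order is time fractions first, then concentrations,
each in the fixed microenvironment row order of the study tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .moments import FittedDistribution

__all__ = ["SampleMatrix", "lhs_uniform", "sample_from"]


@dataclass(frozen=True)
class SampleMatrix:
    """An ``n_iterations x n_parameters`` grid of uniforms in [0, 1)."""

    values: np.ndarray
    parameter_ids: tuple[str, ...]
    seed: int
    n_iterations: int

    def column(self, parameter_id: str) -> np.ndarray:
        return self.values[:, self.parameter_ids.index(parameter_id)]


def _column_stream(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def lhs_uniform(
    n_iterations: int,
    n_parameters: int,
    seed: int,
    parameter_ids: Sequence[str] | None = None,
) -> SampleMatrix:
    """Stratified uniforms: one draw per stratum per column, shuffled.

    Identical ``(seed, n_iterations, n_parameters)`` reproduce the matrix
    bit for bit.
    """
    if n_iterations < 1 or n_parameters < 1:
        raise ValueError("n_iterations and n_parameters must be >= 1")
    if parameter_ids is None:
        parameter_ids = tuple(f"p{j}" for j in range(n_parameters))
    else:
        parameter_ids = tuple(parameter_ids)
        if len(parameter_ids) != n_parameters:
            raise ValueError("parameter_ids length must equal n_parameters")
    n = n_iterations
    values = np.empty((n, n_parameters))
    edges = np.arange(n) / n
    for j in range(n_parameters):
        rng = _column_stream(seed, j)
        within = rng.random(n) / n  # offset inside each stratum
        values[:, j] = rng.permutation(edges + within)
    return SampleMatrix(
        values=values, parameter_ids=parameter_ids, seed=seed, n_iterations=n
    )


def sample_from(dist: FittedDistribution, uniforms: np.ndarray) -> np.ndarray:
    """Inverse-CDF transform of a column of uniforms.

    Degenerate distributions return the constant regardless of the input
    (after validating it), so zero-SD study rows flow through the same path.
    """
    uniforms = np.asarray(uniforms, dtype=float)
    if np.any((uniforms < 0) | (uniforms >= 1)):
        raise ValueError("uniforms must lie in [0, 1)")
    return dist.ppf(uniforms)
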