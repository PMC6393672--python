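"""Step 1: multisensory benefits and Raab's probability-summation prediction.

The redundant signals effect is measured as the area between the
redundant-condition CDF and the faster of the unisensory CDFs,
estimated on matched quantile grids:

    benefit = sum_i [ min(A_i, V_i) - AV_i ] / N

Raab's race model predicts the redundant CDF parameter-free from the
unisensory CDFs by probability summation,
``P_AV = P_A + P_V - P_A * P_V``, under statistical independence and
context invariance.  The predicted benefit substitutes quantiles of
that CDF for the empirical AV quantiles.
"""

from __future__ import annotations

import numpy as np

from .distributions import (
    DEFAULT_N_QUANTILES,
    ContinuousCDF,
    QuantileSet,
    ecdf,
    invert_cdf,
    quantile_grid,
)

__all__ = [
    "empirical_benefit",
    "raab_cdf",
    "raab_predicted_quantiles",
    "predicted_benefit",
    "combine_unisensory_cdfs",
    "DENSE_GRID_POINTS",
]

#: Dense time-grid resolution used when combining unisensory CDFs.
DENSE_GRID_POINTS = 2001


def _check_grids(*sets: QuantileSet) -> None:
    first = sets[0]
    for other in sets[1:]:
        if not first.same_grid(other):
            raise ValueError("quantile sets must share the same probability grid")


def empirical_benefit(a: QuantileSet, v: QuantileSet, av: QuantileSet) -> float:
    """Quantile-area benefit of the redundant over the faster unisensory condition.

    Positive when redundant responses are faster than the quantile-wise
    minimum of the unisensory conditions; may be negative.
    """
    _check_grids(a, v, av)
    n = len(a)
    return float(np.sum(np.minimum(a.values, v.values) - av.values) / n)


def raab_cdf(p_a, p_v):
    """Probability summation of two detection probabilities.

    ``P_A + P_V - P_A * P_V`` — the CDF of the minimum of two
    independent latencies.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_v = np.asarray(p_v, dtype=float)
    if np.any((p_a < 0) | (p_a > 1)) or np.any((p_v < 0) | (p_v > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = p_a + p_v - p_a * p_v
    return out if out.ndim else float(out)


def combine_unisensory_cdfs(
    a_sample, v_sample, combine, n_grid: int = DENSE_GRID_POINTS
) -> ContinuousCDF:
    """Apply a pointwise combination rule to two empirical CDFs.

    Builds piecewise-linear empirical CDFs of both samples, evaluates
    ``combine(P_A(t), P_V(t))`` on a dense time grid spanning the union
    of supports, and returns the combined CDF.
    """
    a_sample = np.asarray(a_sample, dtype=float)
    v_sample = np.asarray(v_sample, dtype=float)
    if a_sample.size < 2 or v_sample.size < 2:
        raise ValueError("both unisensory samples need at least 2 observations")
    cdf_a = ecdf(a_sample)
    cdf_v = ecdf(v_sample)
    lo = min(a_sample.min(), v_sample.min())
    hi = max(a_sample.max(), v_sample.max())
    grid = np.linspace(lo, hi, n_grid)
    combined = np.asarray(combine(cdf_a(grid), cdf_v(grid)), dtype=float)
    return ContinuousCDF(support=grid, cdf=combined)


def raab_predicted_quantiles(
    a_sample, v_sample, n: int = DEFAULT_N_QUANTILES
) -> QuantileSet:
    """Quantiles of the race-model (probability summation) predicted CDF."""
    cdf = combine_unisensory_cdfs(a_sample, v_sample, raab_cdf)
    return invert_cdf(cdf, quantile_grid(n))


def predicted_benefit(a: QuantileSet, v: QuantileSet, predicted_av: QuantileSet) -> float:
    """Benefit implied by a predicted redundant-condition quantile set.

    Same area estimator as :func:`empirical_benefit`, with the
    model-predicted AV quantiles substituted for the empirical ones.
    For probability summation this is nonnegative by construction.
    """
    return empirical_benefit(a, v, predicted_av)
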