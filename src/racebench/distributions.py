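"""Empirical CDFs and fixed-grid quantile down-sampling.

All distribution-level analyses in this package operate on ranked
quantiles extracted from piecewise-linear empirical CDFs.  The
probability convention is symmetric: the sorted sample point ``x_(j)``
is placed at cumulative probability ``(j - 0.5) / n``, and quantiles are
taken on the grid ``p_i = (i - 0.5) / N``.  Outside the sample extremes
the CDF is clamped (0 below the minimum, 1 above the maximum) — no tail
mass is extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuantileSet",
    "ContinuousCDF",
    "ecdf",
    "downsample_quantiles",
    "invert_cdf",
    "DEFAULT_N_QUANTILES",
]

#: Number of quantile points used package-wide for distribution comparisons.
DEFAULT_N_QUANTILES = 50


def quantile_grid(n: int) -> np.ndarray:
    """Return the probability grid ``(i - 0.5) / n`` for ``i = 1..n``."""
    if n < 1:
        raise ValueError(f"need at least one quantile point, got {n}")
    return (np.arange(1, n + 1) - 0.5) / n


@dataclass(frozen=True)
class QuantileSet:
    """Ranked quantiles of an RT (or rate) distribution on a fixed grid.

    Attributes
    ----------
    probs : ndarray
        Strictly increasing probabilities in (0, 1).
    values : ndarray
        Nondecreasing quantile values (seconds, or 1/s in rate space).
    n_source : int
        Size of the sample the quantiles were extracted from.
    """

    probs: np.ndarray
    values: np.ndarray
    n_source: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if probs.shape != values.shape or probs.ndim != 1:
            raise ValueError("probs and values must be 1-d arrays of equal length")
        if probs.size and (probs[0] <= 0.0 or probs[-1] >= 1.0 or np.any(np.diff(probs) <= 0)):
            raise ValueError("probs must be strictly increasing within (0, 1)")
        if np.any(np.diff(values) < -1e-12):
            raise ValueError("quantile values must be nondecreasing")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    def same_grid(self, other: "QuantileSet") -> bool:
        return len(self) == len(other) and np.allclose(self.probs, other.probs)


@dataclass(frozen=True)
class ContinuousCDF:
    """Piecewise-linear CDF on a finite support grid.

    ``support`` must be increasing and ``cdf`` nondecreasing in [0, 1].
    Evaluation clamps to 0 below the support and 1 above it.
    """

    support: np.ndarray
    cdf: np.ndarray
    clamp_low: float = field(default=0.0)
    clamp_high: float = field(default=1.0)

    def __post_init__(self) -> None:
        x = np.asarray(self.support, dtype=float)
        f = np.asarray(self.cdf, dtype=float)
        if x.shape != f.shape or x.ndim != 1 or x.size < 2:
            raise ValueError("support and cdf must be matching 1-d arrays, length >= 2")
        if np.any(np.diff(x) < 0):
            raise ValueError("support must be nondecreasing")
        if np.any(np.diff(f) < -1e-12) or f[0] < -1e-12 or f[-1] > 1 + 1e-12:
            raise ValueError("cdf must be nondecreasing within [0, 1]")
        object.__setattr__(self, "support", x)
        object.__setattr__(self, "cdf", f)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.support, self.cdf)
        out = np.where(t < self.support[0], self.clamp_low, out)
        out = np.where(t > self.support[-1], self.clamp_high, out)
        return out if out.ndim else float(out)


def ecdf(sample) -> ContinuousCDF:
    """Piecewise-linear empirical CDF through the nodes ``(x_(j), (j-0.5)/n)``.

    Parameters
    ----------
    sample : array-like of float
        At least two observations.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError(f"empirical CDF needs at least 2 observations, got {n}")
    return ContinuousCDF(support=x, cdf=quantile_grid(n))


def downsample_quantiles(sample, n: int = DEFAULT_N_QUANTILES) -> QuantileSet:
    """Down-sample observations to ``n`` ranked quantiles on the common grid.

    The quantile function is the linear-interpolation inverse of
    :func:`ecdf`, clamped at the sample extremes, evaluated at
    ``p_i = (i - 0.5) / n``.  With ``n`` equal to the sample size this
    reproduces the sorted sample exactly.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    if x.size < 2:
        raise ValueError(f"need at least 2 observations to down-sample, got {x.size}")
    probs = quantile_grid(n)
    nodes = quantile_grid(x.size)
    values = np.interp(probs, nodes, x)  # np.interp clamps outside node range
    return QuantileSet(probs=probs, values=values, n_source=x.size)


def invert_cdf(cdf: ContinuousCDF, probs) -> QuantileSet:
    """Invert a piecewise-linear CDF: smallest ``t`` with ``F(t) >= p``.

    Flat CDF segments are resolved to the smallest ``t``; probabilities
    outside the attained CDF range clamp to the support endpoint with a
    warning.
    """
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    x, f = cdf.support, cdf.cdf
    values = np.empty_like(probs)
    clamped = False
    # searchsorted 'left' gives the first node with F >= p, honouring the
    # smallest-t tie rule on flat segments.
    idx = np.searchsorted(f, probs, side="left")
    for k, (p, j) in enumerate(zip(probs, idx)):
        if j == 0:
            values[k] = x[0]
            clamped = clamped or f[0] > p
        elif j >= f.size:
            values[k] = x[-1]
            clamped = True
        elif f[j] == p:
            # exact hit: smallest t attaining p
            first = j
            while first > 0 and f[first - 1] == p:
                first -= 1
            values[k] = x[first]
        else:
            values[k] = x[j - 1] + (p - f[j - 1]) / (f[j] - f[j - 1]) * (x[j] - x[j - 1])
    if clamped:
        warnings.warn(
            "some probabilities fell outside the attained CDF range; "
            "quantiles clamped to the support endpoints",
            stacklevel=2,
        )
    order = np.argsort(probs, kind="stable")
    if np.any(np.diff(probs[order]) <= 0):
        raise ValueError("probabilities must be distinct")
    qs_probs = probs[order]
    qs_values = np.maximum.accumulate(values[order])
    return QuantileSet(probs=qs_probs, values=qs_values, n_source=x.size)
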