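"""Step 3: LATER fits and the context-variant race model.

The LATER model treats the reciprocal latency (rate, ``r = 1/RT``) as
normally distributed with mean ``mu`` and standard deviation ``sigma``;
fast responses correspond to high rates.  In the redundant condition a
race of two LATER units decides: the response is triggered by the unit
with the higher rate, so the redundant rate is the maximum of two
(generally correlated) Gaussians.

The context-variant race model has two free parameters beyond the
unisensory LATER fits:

``rho``
    correlation between the two units' rates, accounting for trial
    history (a negative value captures opposite switch/repetition
    effects in the two modalities);
``eta``
    additional accumulation noise in the redundant condition, added to
    both units' sigmas (``sigma_k' = sigma_k + eta``).  ``eta > 0``
    breaks context invariance and permits violations of Miller's bound.

Both parameters are estimated by maximum likelihood on the redundant
rate distribution using the closed-form density of the maximum of a
correlated bivariate normal.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator
from scipy.optimize import minimize

from .distributions import DEFAULT_N_QUANTILES, QuantileSet, quantile_grid
from .benefit import empirical_benefit

__all__ = [
    "LaterModel",
    "ContextVariantRaceModel",
    "fit_later",
    "fit_race",
    "bvn_cdf",
    "max_bvn_cdf",
    "max_bvn_pdf",
    "race_rt_cdf",
    "race_rt_quantiles",
    "model_benefit",
]

# Gauss-Legendre nodes/weights on [0, 1] for the tetrachoric integral.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(128)
_GL_NODES = 0.5 * (_GL_NODES + 1.0)
_GL_WEIGHTS = 0.5 * _GL_WEIGHTS


def bvn_cdf(a, b, rho: float):
    """Standard bivariate normal CDF ``P(X <= a, Y <= b)`` with correlation rho.

    Evaluated deterministically through the tetrachoric integral

        Phi2(a, b, rho) = Phi(a) Phi(b) + int_0^rho phi2(a, b, r) dr

    with fixed Gauss-Legendre quadrature, accurate to well below 1e-10
    for ``|rho| <= 0.99``.  ``rho = +/-1`` returns the comonotone /
    antithetic limits.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not np.isfinite(rho) or abs(rho) > 1:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho}")
    if rho == 1.0:
        out = norm.cdf(np.minimum(a, b))
        return out if out.ndim else float(out)
    if rho == -1.0:
        out = np.maximum(norm.cdf(a) + norm.cdf(b) - 1.0, 0.0)
        return out if out.ndim else float(out)
    base = norm.cdf(a) * norm.cdf(b)
    if rho == 0.0:
        return base if base.ndim else float(base)
    r = rho * _GL_NODES  # quadrature points along the correlation path
    w = abs(rho) * _GL_WEIGHTS * np.sign(rho)
    a_ = a[..., None]
    b_ = b[..., None]
    one_m_r2 = 1.0 - r * r
    dens = np.exp(-(a_ * a_ - 2.0 * r * a_ * b_ + b_ * b_) / (2.0 * one_m_r2)) / (
        2.0 * np.pi * np.sqrt(one_m_r2)
    )
    out = base + np.sum(w * dens, axis=-1)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


class LaterModel(BaseEstimator):
    """LATER unit: Gaussian rate (1/RT) distribution fit by moments.

    ``fit`` transforms RTs to rates and estimates ``mu_`` as the sample
    mean and ``sigma_`` as the square root of the unbiased (n-1)
    variance — the minimum-variance unbiased normal fit.
    """

    def fit(self, rts, y=None) -> "LaterModel":
        rts = np.asarray(rts, dtype=float).ravel()
        if rts.size < 3:
            raise ValueError(f"LATER fit needs at least 3 RTs, got {rts.size}")
        if np.any(rts <= 0):
            raise ValueError("all RTs must be positive")
        rates = 1.0 / rts
        sigma = float(np.std(rates, ddof=1))
        if sigma == 0.0:
            raise ValueError("degenerate LATER unit: zero rate variance")
        self.mu_ = float(np.mean(rates))
        self.sigma_ = sigma
        self.n_ = int(rates.size)
        return self

    @classmethod
    def from_params(cls, mu: float, sigma: float, n: int = 0) -> "LaterModel":
        """Construct an already-'fitted' unit from known parameters."""
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        model = cls()
        model.mu_ = float(mu)
        model.sigma_ = float(sigma)
        model.n_ = int(n)
        return model

    def _check_fitted(self) -> None:
        if not hasattr(self, "mu_"):
            raise ValueError("LaterModel is not fitted")

    def rate_pdf(self, r):
        self._check_fitted()
        return norm.pdf(r, loc=self.mu_, scale=self.sigma_)

    def rt_cdf(self, t):
        """P(RT <= t) = P(rate >= 1/t) for t > 0."""
        self._check_fitted()
        t = np.asarray(t, dtype=float)
        out = norm.sf(1.0 / t, loc=self.mu_, scale=self.sigma_)
        return out if out.ndim else float(out)

    def rt_quantiles(self, n: int = DEFAULT_N_QUANTILES) -> QuantileSet:
        self._check_fitted()
        probs = quantile_grid(n)
        # P(RT <= t) = p  <=>  1/t = isf(p) in rate space
        values = 1.0 / norm.isf(probs, loc=self.mu_, scale=self.sigma_)
        return QuantileSet(probs=probs, values=values, n_source=getattr(self, "n_", 0))


def fit_later(rts) -> LaterModel:
    """Fit a LATER unit to a vector of RTs (seconds)."""
    return LaterModel().fit(rts)


def _inflated_sigmas(fit_a: LaterModel, fit_v: LaterModel, eta: float) -> tuple[float, float]:
    s_a = fit_a.sigma_ + eta
    s_v = fit_v.sigma_ + eta
    if s_a <= 0 or s_v <= 0:
        raise ValueError("inflated sigmas must be positive")
    return s_a, s_v


def max_bvn_cdf(z, fit_a: LaterModel, fit_v: LaterModel, rho: float = 0.0, eta: float = 0.0):
    """CDF of the maximum of the two units' (correlated) rates.

    ``P(max(R_A, R_V) <= z)`` with means from the LATER fits, standard
    deviations inflated additively by ``eta``, and correlation ``rho``.
    """
    s_a, s_v = _inflated_sigmas(fit_a, fit_v, eta)
    z = np.asarray(z, dtype=float)
    return bvn_cdf((z - fit_a.mu_) / s_a, (z - fit_v.mu_) / s_v, rho)


def max_bvn_pdf(z, fit_a: LaterModel, fit_v: LaterModel, rho: float = 0.0, eta: float = 0.0):
    """Closed-form density of the maximum of a correlated bivariate normal.

    ``f(z) = phi_A(z) Phi(h_V(z)) + phi_V(z) Phi(h_A(z))`` where
    ``phi_k`` is the marginal density with the eta-inflated sigma and
    ``h_k`` the conditional standardisation given the other unit.
    Integrates to 1 for any parameter set.
    """
    s_a, s_v = _inflated_sigmas(fit_a, fit_v, eta)
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    z_a = (z - fit_a.mu_) / s_a
    z_v = (z - fit_v.mu_) / s_v
    if abs(rho) >= 1.0:
        if abs(rho) > 1.0:
            raise ValueError(f"correlation must lie in [-1, 1], got {rho}")
        # degenerate limits: conditional CDF becomes an indicator
        cond_v = (np.sign(rho) * z_a <= z_v) if rho > 0 else (-z_a <= z_v)
        cond_a = (np.sign(rho) * z_v <= z_a) if rho > 0 else (-z_v <= z_a)
        out = norm.pdf(z_a) / s_a * cond_v + norm.pdf(z_v) / s_v * cond_a
    else:
        denom = np.sqrt(1.0 - rho * rho)
        out = norm.pdf(z_a) / s_a * norm.cdf((z_v - rho * z_a) / denom) + norm.pdf(
            z_v
        ) / s_v * norm.cdf((z_a - rho * z_v) / denom)
    return out if out.ndim else float(out)


class ContextVariantRaceModel(BaseEstimator):
    """Race of two LATER units with free correlation ``rho`` and noise ``eta``.

    Parameters
    ----------
    later_a, later_v : LaterModel
        Fitted unisensory units constraining the race.
    rho_bounds : tuple of float
        Box bounds for the correlation (kept inside (-1, 1) so the
        likelihood stays finite).
    eta_max : float
        Upper bound for the additive noise, in rate units (1/s).
    n_starts : int
        Multi-start grid resolution per parameter (n_starts**2 starting
        points for the local optimiser).
    tol : float
        Optimiser convergence tolerance.

    Attributes
    ----------
    rho_, eta_ : float
        Maximum-likelihood estimates.
    loglik_ : float
        Log-likelihood at the optimum.
    converged_ : bool
        True if at least one start converged.
    n_ : int
        Number of redundant RTs used.
    neg_rate_mass_ : float
        Largest P(rate <= 0) across the two inflated units — the mass
        the untruncated Gaussian likelihood ignores (negligible at
        typical parameter scales; a warning is issued above 1e-4).
    """

    def __init__(
        self,
        later_a: LaterModel | None = None,
        later_v: LaterModel | None = None,
        rho_bounds: tuple[float, float] = (-0.99, 0.99),
        eta_max: float = 2.0,
        n_starts: int = 3,
        tol: float = 1e-8,
    ):
        self.later_a = later_a
        self.later_v = later_v
        self.rho_bounds = rho_bounds
        self.eta_max = eta_max
        self.n_starts = n_starts
        self.tol = tol

    def _neg_loglik(self, params: Sequence[float], rates: np.ndarray) -> float:
        rho, eta = params
        dens = max_bvn_pdf(rates, self.later_a, self.later_v, rho=rho, eta=eta)
        dens = np.asarray(dens)
        if np.any(dens <= 0) or not np.all(np.isfinite(dens)):
            return 1e12  # finite penalty keeps numerical gradients defined
        return -float(np.sum(np.log(dens)))

    def fit(self, rts, y=None) -> "ContextVariantRaceModel":
        if self.later_a is None or self.later_v is None:
            raise ValueError("both unisensory LATER fits must be supplied")
        self.later_a._check_fitted()
        self.later_v._check_fitted()
        rts = np.asarray(rts, dtype=float).ravel()
        if rts.size < 10:
            raise ValueError(f"race fit needs at least 10 redundant RTs, got {rts.size}")
        if np.any(rts <= 0):
            raise ValueError("all RTs must be positive")
        rates = 1.0 / rts

        lo, hi = self.rho_bounds
        rho_starts = np.linspace(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo), self.n_starts)
        eta_starts = np.linspace(0.05, 0.5, self.n_starts) * self.eta_max
        bounds = [(lo, hi), (0.0, self.eta_max)]

        best = None
        start_values = []
        for r0 in rho_starts:
            for e0 in eta_starts:
                start_values.append(self._neg_loglik((r0, e0), rates))
                res = minimize(
                    self._neg_loglik,
                    x0=np.array([r0, e0]),
                    args=(rates,),
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"ftol": self.tol * 1e-4, "gtol": self.tol},
                )
                if best is None or res.fun < best.fun:
                    best = res
        self.converged_ = bool(best is not None and best.success and np.isfinite(best.fun))
        self.rho_ = float(best.x[0])
        self.eta_ = float(best.x[1])
        self.loglik_ = -float(best.fun)
        self.n_ = int(rates.size)
        self.start_logliks_ = [-v for v in start_values]
        s_a, s_v = _inflated_sigmas(self.later_a, self.later_v, self.eta_)
        self.neg_rate_mass_ = float(
            max(norm.cdf(-self.later_a.mu_ / s_a), norm.cdf(-self.later_v.mu_ / s_v))
        )
        if self.neg_rate_mass_ > 1e-4:
            warnings.warn(
                f"P(rate <= 0) = {self.neg_rate_mass_:.2e} is non-negligible; the "
                "untruncated Gaussian likelihood may be inaccurate",
                stacklevel=2,
            )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "rho_"):
            raise ValueError("ContextVariantRaceModel is not fitted")

    def rate_cdf(self, z):
        self._check_fitted()
        return max_bvn_cdf(z, self.later_a, self.later_v, rho=self.rho_, eta=self.eta_)

    def rate_pdf(self, z):
        self._check_fitted()
        return max_bvn_pdf(z, self.later_a, self.later_v, rho=self.rho_, eta=self.eta_)

    def rt_cdf(self, t):
        self._check_fitted()
        return race_rt_cdf(t, self.later_a, self.later_v, rho=self.rho_, eta=self.eta_)

    def rt_quantiles(self, n: int = DEFAULT_N_QUANTILES) -> QuantileSet:
        self._check_fitted()
        if not self.converged_:
            raise ValueError("race fit did not converge; quantiles unavailable")
        return race_rt_quantiles(self.later_a, self.later_v, rho=self.rho_, eta=self.eta_, n=n)

    def score(self, rts, y=None) -> float:
        """Mean log-likelihood of RTs under the fitted race (rate space)."""
        self._check_fitted()
        rates = 1.0 / np.asarray(rts, dtype=float).ravel()
        dens = np.asarray(self.rate_pdf(rates))
        return float(np.mean(np.log(dens)))


def fit_race(av_rts, fit_a: LaterModel, fit_v: LaterModel, **kwargs) -> ContextVariantRaceModel:
    """Maximum-likelihood (rho, eta) fit of the context-variant race model."""
    return ContextVariantRaceModel(later_a=fit_a, later_v=fit_v, **kwargs).fit(av_rts)


def race_rt_cdf(t, fit_a: LaterModel, fit_v: LaterModel, rho: float = 0.0, eta: float = 0.0):
    """Race-model RT CDF: ``P(RT <= t) = 1 - P(max rate <= 1/t)``."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("RTs must be positive")
    out = 1.0 - np.asarray(max_bvn_cdf(1.0 / t, fit_a, fit_v, rho=rho, eta=eta))
    return out if out.ndim else float(out)


def race_rt_quantiles(
    fit_a: LaterModel,
    fit_v: LaterModel,
    rho: float = 0.0,
    eta: float = 0.0,
    n: int = DEFAULT_N_QUANTILES,
    t_bracket: tuple[float, float] = (0.05, 1.5),
    tol: float = 1e-6,
) -> QuantileSet:
    """RT quantiles of the race model by monotone bisection.

    The RT CDF is strictly increasing, so each quantile is bracketed and
    bisected to ``tol`` seconds on ``t_bracket`` (widened automatically
    if a quantile falls outside).
    """
    probs = quantile_grid(n)
    lo, hi = t_bracket
    # widen the bracket until it encloses all requested probabilities
    for _ in range(60):
        if race_rt_cdf(lo, fit_a, fit_v, rho, eta) < probs[0]:
            break
        lo /= 2.0
    for _ in range(60):
        if race_rt_cdf(hi, fit_a, fit_v, rho, eta) > probs[-1]:
            break
        hi *= 2.0
    lo_v = np.full(n, lo)
    hi_v = np.full(n, hi)
    while np.max(hi_v - lo_v) > tol:
        mid = 0.5 * (lo_v + hi_v)
        below = np.asarray(race_rt_cdf(mid, fit_a, fit_v, rho, eta)) < probs
        lo_v = np.where(below, mid, lo_v)
        hi_v = np.where(below, hi_v, mid)
    values = 0.5 * (lo_v + hi_v)
    return QuantileSet(probs=probs, values=np.maximum.accumulate(values))


def model_benefit(a: QuantileSet, v: QuantileSet, model_av: QuantileSet) -> float:
    """Benefit implied by the fitted race model's redundant quantiles.

    Same quantile-area estimator as the empirical benefit, with the
    model-derived AV quantiles and the *empirical* unisensory quantiles.
    """
    return empirical_benefit(a, v, model_av)
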