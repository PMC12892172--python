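"""Huggins closed-population capture-recapture building blocks.

The Huggins model conditions on the ``M`` individuals captured at least
once, so per-occasion capture probability ``p`` is estimable without
modelling the never-captured animals' histories.  On-grid abundance is then
partitioned as ``N = M + f`` with ``M ~ Poisson(lambda * p_star)`` and
``f ~ Poisson(lambda * (1 - p_star))``, where ``lambda = Dbar * A`` links
expected density to the effective trapping area ``A`` (grid plus a boundary
strip of half a home-range diameter).

All log-likelihoods are evaluated in the log domain; impossible data yield
``-inf`` rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.special import expit, gammaln, xlog1py, xlogy


@dataclass
class CaptureParams:
    """Logit-scale capture-probability hierarchy (mean + crossed random effects).

    ``month`` is ``None`` at the long timescale, where month effects are
    excluded from the model.
    """

    mu_p: float = 0.0
    eta_g_p: Mapping = field(default_factory=dict)
    eta_y_p: Mapping = field(default_factory=dict)
    eta_m_p: Optional[Mapping] = None
    eps_p: Mapping = field(default_factory=dict)
    sigma_g_p: float = 0.0
    sigma_y_p: float = 0.0
    sigma_m_p: float = 0.0
    sigma_p: float = 0.0

    def __post_init__(self):
        for s in (self.sigma_g_p, self.sigma_y_p, self.sigma_m_p, self.sigma_p):
            if s < 0:
                raise ValueError("random-effect SDs must be non-negative")


def _lookup(table: Mapping, level, what: str) -> float:
    try:
        return table[level]
    except KeyError:
        raise ValueError(f"{what} level {level!r} not registered") from None


def capture_prob(params: CaptureParams, plot, year, month=None,
                 period_key=None) -> float:
    """Per-occasion capture probability for one plot-period.

    ``logit p = mu_p + eta_plot + eta_year [+ eta_month] + eps``; the month
    term is evaluated only when the hierarchy carries month effects (short
    timescale).  Unregistered levels raise.
    """
    lp = params.mu_p
    lp += _lookup(params.eta_g_p, plot, "plot effect")
    lp += _lookup(params.eta_y_p, year, "year effect")
    if params.eta_m_p is not None:
        lp += _lookup(params.eta_m_p, month, "month effect")
    if period_key is None:
        period_key = (plot, year, month)
    if params.eps_p:
        lp += _lookup(params.eps_p, period_key, "plot-period residual")
    return float(expit(lp))


def p_star(p, t):
    """Probability of at least one capture in ``t`` occasions: 1 - (1-p)^t."""
    p = np.asarray(p, float)
    t = np.asarray(t)
    if np.any(t < 1):
        raise ValueError("t must be >= 1")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    out = -np.expm1(t * np.log1p(-p, where=p < 1, out=np.full(np.shape(p), -np.inf)))
    return out if out.ndim else float(out)


def huggins_loglik(M, n, t, p):
    """Huggins conditional log-likelihood of the observed encounter histories.

    ``n log p + (M t - n) log(1-p) - M log p_star``; identically 0 for
    M = 0 (no captured individuals, nothing to condition on).  ``p`` of 0
    (or 1 with non-saturated histories) yields ``-inf``.
    """
    M = np.asarray(M)
    n = np.asarray(n)
    t = np.asarray(t)
    p = np.asarray(p, float)
    if np.any((M < 0) | (n < M) | (n > M * t)):
        raise ValueError("requires 0 <= M <= n <= M*t")
    if np.any(t < 1):
        raise ValueError("t must be >= 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = 1.0 - (1.0 - p) ** t
        ll = xlogy(n, p) + xlog1py(M * t - n, -p) - xlogy(M, ps)
    ll = np.where(M == 0, 0.0, ll)
    ll = np.where(np.isnan(ll), -np.inf, ll)
    return ll if ll.ndim else float(ll)


def effective_area(L, d):
    """Effective trapping area in hectares: grid + boundary strip of d/2.

    ``A = (L^2 + 4 L (d/2) + pi (d/2)^2) * 1e-4`` with ``L`` and ``d`` in
    metres; strictly increasing and quadratic in ``d``.
    """
    L = np.asarray(L, float)
    d = np.asarray(d, float)
    if np.any(L <= 0):
        raise ValueError("L must be positive")
    if np.any(d < 0):
        raise ValueError("d must be non-negative")
    A = (L**2 + 4.0 * L * (0.5 * d) + np.pi * (0.5 * d) ** 2) * 1e-4
    return A if A.ndim else float(A)


def observed_capture_loglik(M, lam, pstar):
    """Poisson log-pmf of the captured count: ``M ~ Poisson(lambda * p_star)``."""
    M = np.asarray(M)
    lam = np.asarray(lam, float)
    pstar = np.asarray(pstar, float)
    if np.any(lam <= 0):
        raise ValueError("lambda must be positive")
    if np.any((pstar < 0) | (pstar > 1)):
        raise ValueError("pstar must lie in [0, 1]")
    rate = lam * pstar
    with np.errstate(divide="ignore"):
        ll = xlogy(M, rate) - rate - gammaln(M + 1)
    return ll if ll.ndim else float(ll)


def draw_uncaptured(M, lam, pstar, rng):
    """Posterior-predictive never-captured count and realized abundance.

    ``f ~ Poisson(lambda (1 - p_star))`` and ``N = M + f``.
    """
    M = np.asarray(M)
    lam = np.asarray(lam, float)
    pstar = np.asarray(pstar, float)
    if np.any(lam <= 0):
        raise ValueError("lambda must be positive")
    rate = lam * (1.0 - pstar)
    shape = np.broadcast_shapes(np.shape(M), np.shape(rate))
    f = rng.poisson(np.broadcast_to(rate, shape)) if shape else rng.poisson(rate)
    return f, M + f
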