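"""Single-season occupancy likelihood and the finite-population PSO.

Occupancy probability ``psi`` and per-check detection probability ``rho``
vary on the logit scale with a plot-selection covariate ``X`` plus crossed
plot/year/month random effects and a plot-period residual.  Because a known,
substantial fraction of the 0.0156-ha subplots in each 1-ha plot is
surveyed, the quantity of interest is the realized *proportion of subplots
occupied* (PSO), ``Psi = (s_star + u) / s``, where ``u`` is the latent
number of occupied-but-undetected subplots with

``u ~ Binomial(s - s_star, psi_C)``,

``psi_C`` being the probability a subplot is occupied conditional on no
detection there across ``k`` checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.special import expit, xlog1py, xlogy


@dataclass
class OccupancyParams:
    """One logit-scale hierarchy (used for both detection and occupancy).

    ``beta`` multiplies the binary plot-selection covariate ``X`` (0 random,
    1 non-random); ``eta_m`` is ``None`` at the long timescale.
    """

    mu: float = 0.0
    beta: float = 0.0
    eta_g: Mapping = field(default_factory=dict)
    eta_y: Mapping = field(default_factory=dict)
    eta_m: Optional[Mapping] = None
    eps: Mapping = field(default_factory=dict)
    sigma_g: float = 0.0
    sigma_y: float = 0.0
    sigma_m: float = 0.0
    sigma: float = 0.0

    def __post_init__(self):
        for s in (self.sigma_g, self.sigma_y, self.sigma_m, self.sigma):
            if s < 0:
                raise ValueError("random-effect SDs must be non-negative")

    def prob(self, plot, year, month=None, X=0, period_key=None) -> float:
        from .huggins import _lookup

        lp = self.mu + self.beta * X
        lp += _lookup(self.eta_g, plot, "plot effect")
        lp += _lookup(self.eta_y, year, "year effect")
        if self.eta_m is not None:
            lp += _lookup(self.eta_m, month, "month effect")
        if period_key is None:
            period_key = (plot, year, month)
        if self.eps:
            lp += _lookup(self.eps, period_key, "plot-period residual")
        return float(expit(lp))


def detection_prob(params: OccupancyParams, plot, year, month=None, X=0) -> float:
    """Per-check detection probability for an occupied subplot."""
    return params.prob(plot, year, month=month, X=X)


def occupancy_prob(params: OccupancyParams, plot, year, month=None, X=0) -> float:
    """Subplot occupancy probability."""
    return params.prob(plot, year, month=month, X=X)


def occupancy_loglik(s, s_star, d, k, psi, rho):
    """Observed-data log-likelihood of one plot-period's detection summary.

    ``s_star log psi + d log rho + (s_star k - d) log(1 - rho)
    + (s - s_star) log(1 - psi (1 - (1-rho)^k))``.

    Detections are pooled across the detected subplots (``s_star k`` total
    check trials).  Impossible data (e.g. detections with ``rho = 0``) give
    ``-inf``.
    """
    s = np.asarray(s)
    s_star = np.asarray(s_star)
    d = np.asarray(d)
    k = np.asarray(k)
    psi = np.asarray(psi, float)
    rho = np.asarray(rho, float)
    if np.any((s_star < 0) | (s_star > s)):
        raise ValueError("requires 0 <= s_star <= s")
    if np.any((d < s_star) | (d > s_star * k)):
        raise ValueError("requires s_star <= d <= s_star*k")
    if np.any(k < 1):
        raise ValueError("k must be >= 1")
    if np.any((psi < 0) | (psi > 1)) or np.any((rho < 0) | (rho > 1)):
        raise ValueError("psi and rho must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        p_any = psi * (1.0 - (1.0 - rho) ** k)  # unconditional detection prob
        ll = (
            xlogy(s_star, psi)
            + xlogy(d, rho)
            + xlog1py(s_star * k - d, -rho)
            + xlog1py(s - s_star, -p_any)
        )
    ll = np.where(np.isnan(ll), -np.inf, ll)
    return ll if ll.ndim else float(ll)


def psi_conditional(psi, rho, k):
    """Occupancy probability conditional on no detection in ``k`` checks.

    ``psi (1-rho)^k / (1 - psi (1 - (1-rho)^k))``; lies in [0, 1], is
    bounded above by ``psi`` unless ``psi`` is 0 or 1, and decreases in both
    ``rho`` and ``k``.  The degenerate ``psi = rho = 1`` case (no-detection
    impossible) returns 0 with a warning.
    """
    psi = np.asarray(psi, float)
    rho = np.asarray(rho, float)
    k = np.asarray(k)
    if np.any((psi < 0) | (psi > 1)) or np.any((rho < 0) | (rho > 1)):
        raise ValueError("psi and rho must lie in [0, 1]")
    if np.any(k < 1):
        raise ValueError("k must be >= 1")
    miss = (1.0 - rho) ** k
    num = psi * miss
    den = 1.0 - psi * (1.0 - miss)
    degenerate = den == 0.0
    if np.any(degenerate):
        warnings.warn(
            "psi = 1 with detection certain: conditional occupancy undefined, "
            "returning 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        out = np.where(degenerate, 0.0, num / np.where(degenerate, 1.0, den))
    return out if out.ndim else float(out)


def draw_pso(s, s_star, k, psi, rho, rng):
    """Draw the latent undetected count and the realized PSO.

    ``u ~ Binomial(s - s_star, psi_C)``; ``Psi = (s_star + u) / s``.
    """
    s = np.asarray(s)
    s_star = np.asarray(s_star)
    psiC = psi_conditional(psi, rho, k)
    u = rng.binomial(s - s_star, psiC)
    return u, (s_star + u) / s
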