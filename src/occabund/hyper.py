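"""The hyper model: log expected density regressed on sqrt(PSO), sqrt(rho).

``log Dbar = beta0 + beta1 sqrt(Psi) + beta2 sqrt(rho) + eps``, with
``eps ~ Normal(0, sigma_eps^2)``.  The square roots make the relative effect
of PSO and detection on density taper as either approaches 1 and stabilise
the variance of the probability-scale predictors; ``rho`` here is the
single-check detection probability, not its cumulative version.  Because of
the intercept, expected density stays positive even at Psi = rho = 0.

A ``transform="identity"`` switch preserves the untransformed-predictor
reading of the regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TRANSFORMS = ("sqrt", "identity")


def apply_transform(x, transform: str = "sqrt"):
    if transform not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}")
    x = np.asarray(x, float)
    out = np.sqrt(x) if transform == "sqrt" else x
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class HyperParams:
    """Hyper-model coefficients on the log-density scale."""

    beta0: float
    beta1: float
    beta2: float
    sigma_eps: float = 0.0

    def __post_init__(self):
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be non-negative")


def expected_log_density(hp: HyperParams, Psi, rho, eps=0.0,
                         transform: str = "sqrt"):
    """Linear predictor of log expected density plus residual.

    ``Psi`` and ``rho`` must lie in [0, 1]; the returned log-density
    exponentiates to a strictly positive density for any input.
    """
    Psi = np.asarray(Psi, float)
    rho = np.asarray(rho, float)
    if np.any((Psi < 0) | (Psi > 1)) or np.any((rho < 0) | (rho > 1)):
        raise ValueError("Psi and rho must lie in [0, 1]")
    out = (
        hp.beta0
        + hp.beta1 * apply_transform(Psi, transform)
        + hp.beta2 * apply_transform(rho, transform)
        + np.asarray(eps, float)
    )
    return out if np.ndim(out) else float(out)


def marginal_relative_effect(hp: HyperParams, Psi, rho, transform: str = "sqrt"):
    """Partial derivatives of log-density with respect to Psi and rho.

    Under the square-root transform these are ``beta1 / (2 sqrt(Psi))`` and
    ``beta2 / (2 sqrt(rho))`` -- unbounded at zero, hence zero inputs raise.
    Used for diagnostics and relationship plots.
    """
    Psi = np.asarray(Psi, float)
    rho = np.asarray(rho, float)
    if np.any((Psi <= 0) | (Psi > 1)) or np.any((rho <= 0) | (rho > 1)):
        raise ValueError("Psi and rho must lie in (0, 1]")
    if transform == "identity":
        g1 = np.broadcast_to(hp.beta1, Psi.shape).astype(float)
        g2 = np.broadcast_to(hp.beta2, rho.shape).astype(float)
    elif transform == "sqrt":
        g1 = hp.beta1 / (2.0 * np.sqrt(Psi))
        g2 = hp.beta2 / (2.0 * np.sqrt(rho))
    else:
        raise ValueError(f"transform must be one of {TRANSFORMS}")
    if g1.ndim == 0:
        return float(g1), float(g2)
    return g1, g2
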