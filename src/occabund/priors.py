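"""Prior specifications for the integrated model.

Somewhat informative defaults (normal distributions parameterised by mean
and *variance*; truncated normals additionally by lower/upper bound):

* hyper model: beta0 ~ N(-3, 1); beta1, beta2 ~ N(0, 4)
* intercepts: mu_p ~ N(-1, 1); mu_rho, mu_psi ~ N(0, 1)
* plot-selection coefficients: beta_rho, beta_psi ~ N(0, 0.25)
* every random-effect / residual SD (including the hyper-model sigma_eps):
  TruncNormal(0, 0.5625, [0, 1.5]) -- small SDs a priori more likely, with
  an ecological upper bound of 1.5 on the logit/log scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from scipy.stats import norm, truncnorm


@dataclass(frozen=True)
class NormalPrior:
    mean: float
    var: float

    def __post_init__(self):
        if self.var <= 0:
            raise ValueError("variance must be positive")

    @property
    def sd(self) -> float:
        return math.sqrt(self.var)

    def logpdf(self, x: float) -> float:
        z = (x - self.mean) / self.sd
        return -0.5 * z * z - math.log(self.sd) - 0.5 * math.log(2 * math.pi)


@dataclass(frozen=True)
class TruncNormalPrior:
    mean: float
    var: float
    low: float
    high: float

    def __post_init__(self):
        if self.var <= 0:
            raise ValueError("variance must be positive")
        if not self.low < self.high:
            raise ValueError("truncation requires low < high")

    @property
    def sd(self) -> float:
        return math.sqrt(self.var)

    @property
    def _lognorm(self) -> float:
        # cached: Phi(b) - Phi(a) via erf, no scipy dispatch overhead
        cached = object.__getattribute__(self, "__dict__").get("_lognorm_cache")
        if cached is None:
            a = (self.low - self.mean) / self.sd
            b = (self.high - self.mean) / self.sd
            phi = lambda z: 0.5 * (1.0 + math.erf(z / math.sqrt(2.0))) \
                if math.isfinite(z) else (1.0 if z > 0 else 0.0)
            cached = math.log(phi(b) - phi(a))
            object.__setattr__(self, "_lognorm_cache", cached)
        return cached

    def logpdf(self, x: float) -> float:
        if not (self.low <= x <= self.high):
            return -math.inf
        z = (x - self.mean) / self.sd
        return (-0.5 * z * z - math.log(self.sd) - 0.5 * math.log(2 * math.pi)
                - self._lognorm)

    def rvs(self, rng, size=None):
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=size,
                             random_state=rng)


_SIGMA = TruncNormalPrior(0.0, 0.5625, 0.0, 1.5)


@dataclass(frozen=True)
class PriorSpec:
    """Default priors for every top-level parameter of the joint model."""

    beta0: NormalPrior = NormalPrior(-3.0, 1.0)
    beta1: NormalPrior = NormalPrior(0.0, 4.0)
    beta2: NormalPrior = NormalPrior(0.0, 4.0)
    mu_p: NormalPrior = NormalPrior(-1.0, 1.0)
    mu_rho: NormalPrior = NormalPrior(0.0, 1.0)
    mu_psi: NormalPrior = NormalPrior(0.0, 1.0)
    beta_rho: NormalPrior = NormalPrior(0.0, 0.25)
    beta_psi: NormalPrior = NormalPrior(0.0, 0.25)
    sigma: TruncNormalPrior = _SIGMA

    def with_updates(self, **kwargs) -> "PriorSpec":
        return replace(self, **kwargs)

    def for_scalar(self, name: str):
        """Prior object for a named scalar parameter (sigmas share one)."""
        if name.startswith("sigma"):
            return self.sigma
        return getattr(self, name)
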