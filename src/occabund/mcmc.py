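"""MCMC containers, diagnostics, and a generic adaptive random-walk kernel.

Posterior draws are held as a dense ``(chains, draws, parameters)`` array
with parameter names; summaries follow the reporting convention of
posterior mean, SD and central 90% credible interval (5%/95% quantiles by
linear interpolation of order statistics), plus the split-chain
Gelman-Rubin statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``x`` has shape (chains, draws).  Each chain is split in half; with
    within-sequence variance W and between-sequence variance B,
    ``Rhat = sqrt(((n-1)/n * W + B/n) / W)``.  Chains that are constant
    everywhere return exactly 1.0.
    """
    x = np.asarray(x, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 chains of draws")
    n = x.shape[1] // 2
    if n < 5:
        raise ValueError("need at least 10 draws per chain to split")
    if np.all(x == x.flat[0]):  # constant everywhere: nothing to diagnose
        return 1.0
    halves = np.concatenate([x[:, :n], x[:, x.shape[1] - n:]], axis=0)
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclass
class PosteriorDraws:
    """Retained MCMC draws: (chain, iteration, parameter) plus names."""

    values: np.ndarray  # (C, D, P)
    names: list

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (chains, draws, params)")
        if self.values.shape[2] != len(self.names):
            raise ValueError("names length must match parameter axis")
        self._index = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        """(chains, draws) array for one named parameter."""
        return self.values[:, :, self._index[name]]

    def flat(self, name: str) -> np.ndarray:
        """All chains concatenated for one parameter."""
        return self.parameter(name).reshape(-1)

    def family(self, prefix: str) -> pd.DataFrame:
        """Flattened draws of every parameter named ``prefix[...]``."""
        cols = [n for n in self.names if n == prefix or n.startswith(prefix + "[")]
        return pd.DataFrame({c: self.flat(c) for c in cols})

    def rhat(self) -> pd.Series:
        return pd.Series(
            {n: split_rhat(self.parameter(n)) for n in self.names}, name="rhat"
        )

    def summary(self) -> pd.DataFrame:
        flat = self.values.reshape(-1, self.values.shape[2])
        q05, q95 = np.quantile(flat, [0.05, 0.95], axis=0)  # linear interpolation
        out = pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else 0.0,
                "q05": q05,
                "q95": q95,
            },
            index=pd.Index(self.names, name="parameter"),
        )
        out["rhat"] = self.rhat()
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, iteration, parameter, value) table."""
        C, D, P = self.values.shape
        chain = np.repeat(np.arange(C), D * P)
        it = np.tile(np.repeat(np.arange(D), P), C)
        par = np.tile(np.asarray(self.names, object), C * D)
        return pd.DataFrame(
            {"chain": chain, "iteration": it, "parameter": par,
             "value": self.values.reshape(-1)}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PosteriorDraws":
        names = list(pd.unique(df["parameter"]))
        C = df["chain"].nunique()
        D = df["iteration"].nunique()
        wide = df.pivot_table(index=["chain", "iteration"], columns="parameter",
                              values="value", sort=False)
        wide = wide[names]
        return cls(wide.to_numpy().reshape(C, D, len(names)), names)


def gelman_rubin(draws) -> pd.Series:
    """Per-parameter split-chain R-hat (~1 at convergence)."""
    if isinstance(draws, PosteriorDraws):
        return draws.rhat()
    x = np.asarray(draws, float)
    if x.ndim == 2:
        return pd.Series({"x": split_rhat(x)}, name="rhat")
    raise TypeError("expected PosteriorDraws or a (chains, draws) array")


def summarize(draws) -> pd.DataFrame:
    """Posterior mean, SD and central 90% credible interval per parameter."""
    if isinstance(draws, PosteriorDraws):
        return draws.summary()
    x = np.asarray(draws, float)
    if x.ndim == 2:
        return PosteriorDraws(x[:, :, None], ["x"]).summary()
    raise TypeError("expected PosteriorDraws or a (chains, draws) array")


def adaptive_metropolis(
    logpost,
    x0,
    n_iter: int,
    seed: int = 0,
    step: float = 1.0,
    target: float = 0.44,
    adapt_frac: float = 0.5,
):
    """Scalar adaptive random-walk Metropolis (generic kernel).

    The proposal SD is tuned by Robbins-Monro toward the ``target``
    acceptance rate during the first ``adapt_frac`` of iterations and frozen
    afterwards.  Returns the full chain including the adaptation phase.
    """
    rng = np.random.default_rng(seed)
    x = float(x0)
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("log-posterior not finite at the initial state")
    out = np.empty(n_iter)
    ls = np.log(step)
    n_adapt = int(adapt_frac * n_iter)
    for i in range(n_iter):
        prop = x + np.exp(ls) * rng.standard_normal()
        lp_prop = logpost(prop)
        acc = np.log(rng.random()) < lp_prop - lp
        if acc:
            x, lp = prop, lp_prop
        if i < n_adapt:
            ls += ((1.0 if acc else 0.0) - target) * (i + 1) ** -0.6
        out[i] = x
    return out
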