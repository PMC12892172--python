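"""Integrated density-occupancy model: Model and Results objects.

``IntegratedAbundanceModel`` binds collated capture and track-tube summary
tables (plus the plot registry) into one joint Bayesian model:

* a Huggins conditional likelihood and a Poisson observed-capture term for
  every live-trapped plot-period;
* a single-season occupancy likelihood with finite-population PSO for every
  tube-surveyed plot-period;
* the hyper model tying log expected density at paired plot-periods to
  sqrt(PSO) and sqrt(detection), which transfers density information to
  tube-only plot-periods.

``fit()`` runs the component-wise adaptive MCMC (``occabund.sampler``) and
returns an ``IntegratedFitResults`` carrying the posterior draws, summary
table, convergence diagnostics and prediction methods.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd

from . import data as dmod
from .data import LONG, SHORT, HomeRangeSpec, default_homerange
from .huggins import effective_area
from .hyper import HyperParams, apply_transform
from .mcmc import PosteriorDraws
from .priors import PriorSpec, TruncNormalPrior
from .sampler import Sampler, _norm_sum_logpdf

_SEED_JITTER = 0.05


@dataclass
class McmcConfig:
    """MCMC run configuration.

    Defaults follow the study's published configuration: three chains of
    30,000 unthinned iterations at the short timescale, 300,000 iterations
    thinned by 10 at the long timescale; the first ``burnin`` fraction of
    each chain is discarded (and used for proposal adaptation).
    """

    chains: int = 3
    iterations: int | None = None
    thin: int | None = None
    burnin: float = 0.5
    seed: int = 0

    def resolved(self, timescale: str) -> "McmcConfig":
        it = self.iterations if self.iterations is not None else (
            30_000 if timescale == SHORT else 300_000)
        th = self.thin if self.thin is not None else (1 if timescale == SHORT else 10)
        cfg = McmcConfig(self.chains, it, th, self.burnin, self.seed)
        n_burn = int(cfg.burnin * it)
        if cfg.chains < 1 or it <= n_burn or th < 1:
            raise ValueError("retained draws per chain must be positive")
        return cfg


class IntegratedAbundanceModel:
    """Joint model over capture summaries, occupancy summaries and registry.

    Parameters
    ----------
    captures, tubes : DataFrame
        Collated ``CaptureSummary`` / ``OccupancySummary`` tables.
    registry : DataFrame
        Plot registry with plot_id, subpopulation, selection_method.
    timescale : {"short", "long"}
        Month effects are included only at the short timescale.
    homerange : HomeRangeSpec, optional
        Mean/SE of the home-range diameter; defaults to the timescale's
        published values.  The diameter is a model parameter with a
        truncated-normal prior unless ``freeze_homerange``.
    transform : {"sqrt", "identity"}
        Predictor transform in the hyper model.
    """

    def __init__(self, captures, tubes, registry, timescale=SHORT,
                 priors: PriorSpec | None = None,
                 homerange: HomeRangeSpec | None = None,
                 transform: str = "sqrt",
                 freeze_homerange: bool = False):
        dmod._check_timescale(timescale)
        self.timescale = timescale
        self.priors = priors or PriorSpec()
        self.homerange = homerange or default_homerange(timescale)
        self.transform = transform
        self.freeze_homerange = freeze_homerange or self.homerange.sd_d == 0
        dmod.validate_capture_summary(captures, timescale)
        dmod.validate_occupancy_summary(tubes, timescale)
        self.captures = captures.reset_index(drop=True)
        self.tubes = dmod.attach_registry(tubes.reset_index(drop=True), registry)
        self.registry = registry.reset_index(drop=True)
        self._build()

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_csv(cls, capture_summary_csv, occupancy_summary_csv, plots_csv,
                 **kwargs):
        cap = pd.read_csv(capture_summary_csv, dtype={"plot_id": str})
        cap["month"] = cap["month"].astype("Int64") if "month" in cap else pd.NA
        occ = pd.read_csv(occupancy_summary_csv, dtype={"plot_id": str})
        occ["month"] = occ["month"].astype("Int64") if "month" in occ else pd.NA
        return cls(cap, occ, dmod.read_plots(plots_csv), **kwargs)

    @classmethod
    def from_raw(cls, captures_raw, tubes_raw, registry, timescale=SHORT,
                 **kwargs):
        cap = dmod.collate_captures(captures_raw, timescale)
        occ = dmod.collate_tubes(tubes_raw, timescale)
        return cls(cap, occ, registry, timescale=timescale, **kwargs)

    # -- assembly ----------------------------------------------------------

    def _key_cols(self):
        return ["plot_id", "year"] + (["month"] if self.timescale == SHORT else [])

    def _build(self):
        occ = self.tubes
        cap = self.captures
        keys = self._key_cols()

        # pair capture rows with the occupancy row at the same plot-period
        occ_pos = occ.reset_index().rename(columns={"index": "_occ_idx"})
        merged = cap.merge(occ_pos[keys + ["_occ_idx"]], on=keys, how="left")
        unmatched = merged["_occ_idx"].isna()
        if unmatched.any():
            warnings.warn(
                f"{int(unmatched.sum())} capture summaries have no matching "
                "occupancy summary and are dropped from the fit",
                stacklevel=2,
            )
            cap = cap.loc[~unmatched.to_numpy()].reset_index(drop=True)
            merged = merged.loc[~unmatched.to_numpy()].reset_index(drop=True)
            self.captures = cap

        plots = sorted(occ["plot_id"].unique())
        cap_plots = sorted(cap["plot_id"].unique())
        years = sorted(set(occ["year"]) | set(cap["year"]))
        months = sorted(occ["month"].dropna().unique()) if self.timescale == SHORT else []

        def codes(vals, levels):
            lut = {v: i for i, v in enumerate(levels)}
            return np.asarray([lut[v] for v in vals], dtype=int)

        d = SimpleNamespace()
        d.n_occ = len(occ)
        d.n_cap = len(cap)
        d.s = occ["s"].to_numpy(float)
        d.sstar = occ["s_star"].to_numpy(float)
        d.dd = occ["d"].to_numpy(float)
        d.k = occ["k"].to_numpy(float)
        d.Xf = occ["X"].to_numpy(float)
        d.g = codes(occ["plot_id"], plots)
        d.y = codes(occ["year"], years)
        d.m = codes(occ["month"], months) if self.timescale == SHORT else None
        d.M = cap["M"].to_numpy(float)
        d.n = cap["n"].to_numpy(float)
        d.t = cap["t"].to_numpy(float)
        d.gcap = codes(cap["plot_id"], cap_plots) if d.n_cap else np.zeros(0, int)
        d.ycap = codes(cap["year"], years) if d.n_cap else np.zeros(0, int)
        d.mcap = (codes(cap["month"], months)
                  if self.timescale == SHORT and d.n_cap else None)
        d.occ_idx = merged["_occ_idx"].to_numpy(int) if d.n_cap else np.zeros(0, int)
        d.s_p = d.s[d.occ_idx]
        d.sstar_p = d.sstar[d.occ_idx]
        d.k_p = d.k[d.occ_idx]
        d.smax = (d.s_p - d.sstar_p).astype(float)
        d.plots, d.cap_plots, d.years, d.months = plots, cap_plots, years, months
        # plot-level selection indicator (for beta/eta translation moves)
        x_by_plot = occ.groupby("plot_id")["X"].first()
        d.X_plot = np.asarray([int(x_by_plot.get(p, 0)) for p in plots])
        self._data = d

        self._scalar_names = [
            "beta0", "beta1", "beta2", "sigma_eps",
            "mu_p", "sigma_g_p", "sigma_y_p", "sigma_p",
            "mu_rho", "beta_rho", "sigma_g_rho", "sigma_y_rho", "sigma_rho",
            "mu_psi", "beta_psi", "sigma_g_psi", "sigma_y_psi", "sigma_psi",
        ]
        if self.timescale == SHORT:
            self._scalar_names += ["sigma_m_p", "sigma_m_rho", "sigma_m_psi"]
        if not self.freeze_homerange:
            self._scalar_names.append("d_hr")

        def period_labels(df):
            if self.timescale == SHORT:
                return [f"{p}|{yy}|{mm}" for p, yy, mm in
                        zip(df["plot_id"], df["year"], df["month"])]
            return [f"{p}|{yy}" for p, yy in zip(df["plot_id"], df["year"])]

        self._occ_labels = period_labels(occ)
        self._cap_labels = period_labels(cap)

        specs = []
        for suf, plot_lv, n_rows, row_labels in [
            ("rho", plots, d.n_occ, self._occ_labels),
            ("psi", plots, d.n_occ, self._occ_labels),
            ("p", cap_plots, d.n_cap, self._cap_labels),
        ]:
            specs.append((f"eta_g_{suf}", list(plot_lv), len(plot_lv)))
            specs.append((f"eta_y_{suf}", [str(v) for v in years], len(years)))
            if self.timescale == SHORT:
                specs.append((f"eta_m_{suf}", [str(v) for v in months], len(months)))
            specs.append((f"eps_{suf}", row_labels, n_rows))
        specs.append(("logD", self._cap_labels, d.n_cap))
        specs.append(("u", self._cap_labels, d.n_cap))
        self._vector_specs = specs

        hr = self.homerange
        self._d_prior = TruncNormalPrior(hr.mean_d, max(hr.sd_d, 1e-6) ** 2,
                                         0.0, math.inf)

    def _tr(self, x):
        return apply_transform(x, self.transform)

    def _area(self, d_hr):
        return effective_area(self.homerange.L, d_hr)

    def _scalar_targets(self, sampler: Sampler):
        """Scalar name -> (prior, row-total target) for Metropolis updates."""
        out = {}
        occ_side = sampler._rt_occ_side
        cap = sampler._rt_cap
        pair = sampler._rt_pair
        targets = {
            "beta0": pair, "beta1": pair, "beta2": pair, "sigma_eps": pair,
            "mu_p": cap, "mu_rho": occ_side, "beta_rho": occ_side,
            "mu_psi": occ_side, "beta_psi": occ_side, "d_hr": cap,
        }
        for name in self._scalar_names:
            if name == "d_hr":
                out[name] = (self._d_prior, targets[name])
            elif name.startswith("sigma_") and name != "sigma_eps":
                sig = name
                vec = "eta_" + name[len("sigma_"):] if name.count("_") == 2 else \
                    "eps_" + name[len("sigma_"):]
                out[name] = (self.priors.sigma, _SigmaTarget(vec, sig))
            else:
                out[name] = (self.priors.for_scalar(name), targets[name])
        return out

    # -- joint posterior ---------------------------------------------------

    def log_posterior_components(self, state: dict) -> dict:
        """Named additive components of the joint log posterior."""
        smp = Sampler(self)
        st = state
        comp = {}
        lp = 0.0
        for name in self._scalar_names:
            pr = self._d_prior if name == "d_hr" else self.priors.for_scalar(name)
            lp += pr.logpdf(st[name])
        comp["scalar_priors"] = lp
        eff = 0.0
        for name, _labels, _size in self._vector_specs:
            if name in ("logD", "u"):
                continue
            parts = name.split("_")
            sig = "sigma_" + "_".join(parts[1:]) if parts[0] == "eta" else \
                "sigma_" + parts[1]
            eff += _norm_sum_logpdf(st[name], max(st[sig], 1e-4))
        comp["random_effects"] = eff
        psi = smp._side_probs(st, "psi")
        rho = smp._side_probs(st, "rho")
        comp["occupancy_loglik"] = float(np.sum(smp._occ_ll(psi, rho)))
        comp["capture_loglik"] = float(np.sum(smp._cap_ll(st)))
        comp["hyper_and_u"] = float(np.sum(smp._pair_extra(st, psi, rho)))
        return comp

    def joint_log_posterior(self, state: dict) -> float:
        """Scalar joint log posterior; ``-inf`` outside the support."""
        try:
            return float(sum(self.log_posterior_components(state).values()))
        except (ValueError, FloatingPointError):
            return -math.inf

    # -- initialization ----------------------------------------------------

    def initial_state(self, rng) -> dict:
        """Prior-mean state jittered by seed-controlled noise."""
        st = {}
        for name in self._scalar_names:
            if name == "d_hr":
                st[name] = self.homerange.mean_d * math.exp(
                    _SEED_JITTER * rng.standard_normal())
            elif name.startswith("sigma"):
                st[name] = float(np.clip(
                    0.3 * math.exp(0.2 * rng.standard_normal()), 0.05, 1.2))
            else:
                st[name] = (self.priors.for_scalar(name).mean
                            + 0.25 * rng.standard_normal())
        if self.freeze_homerange:
            st["d_hr"] = self.homerange.mean_d
        for name, _labels, size in self._vector_specs:
            if name in ("logD", "u"):
                continue
            st[name] = 0.05 * rng.standard_normal(size)
        d = self._data
        smp = Sampler(self)
        psi = smp._side_probs(st, "psi")
        rho = smp._side_probs(st, "rho")
        if d.n_cap:
            rho_p = rho[d.occ_idx]
            psi_p = psi[d.occ_idx]
            miss = (1.0 - rho_p) ** d.k_p
            psiC = psi_p * miss / (1.0 - psi_p * (1.0 - miss))
            st["u"] = rng.binomial(d.smax.astype(int), psiC).astype(float)
            Psi = (d.sstar_p + st["u"]) / d.s_p
            st["logD"] = (st["beta0"] + st["beta1"] * self._tr(Psi)
                          + st["beta2"] * self._tr(rho_p)
                          + 0.25 * rng.standard_normal(d.n_cap))
        else:
            st["u"] = np.zeros(0)
            st["logD"] = np.zeros(0)
        comps = self.log_posterior_components(st)
        bad = [k for k, v in comps.items() if not np.isfinite(v)]
        if bad:
            raise RuntimeError(
                f"initial log posterior not finite in component(s): {bad}")
        return st

    # -- fitting -----------------------------------------------------------

    def _param_names(self):
        names = list(self._scalar_names)
        for vec, labels, size in self._vector_specs:
            names += [f"{vec}[{lab}]" for lab in labels]
        names += [f"rho[{lab}]" for lab in self._occ_labels]
        names += [f"psi[{lab}]" for lab in self._occ_labels]
        names.append("lp__")
        return names

    def fit(self, config: McmcConfig | None = None, **kwargs) -> "IntegratedFitResults":
        """Run MCMC and return the fitted results.

        Keyword shortcuts (``chains=``, ``iterations=``, ``thin=``,
        ``burnin=``, ``seed=``) override ``config`` fields.
        """
        cfg = config or McmcConfig()
        if kwargs:
            cfg = McmcConfig(**{**cfg.__dict__, **kwargs})
        cfg = cfg.resolved(self.timescale)
        n_burn = int(cfg.burnin * cfg.iterations)
        n_keep = len(range(n_burn, cfg.iterations, cfg.thin))
        names = self._param_names()
        values = np.empty((cfg.chains, n_keep, len(names)))
        smp = Sampler(self)
        for chain in range(cfg.chains):
            rng = np.random.default_rng([cfg.seed, chain])
            st = self.initial_state(rng)
            slot = {"i": 0}

            def record(st, it, chain=chain, slot=slot):
                values[chain, slot["i"], :] = self._flatten(st, smp)
                slot["i"] += 1

            smp.run(st, cfg.iterations, n_burn, cfg.thin, rng, record)
        draws = PosteriorDraws(values, names)
        return IntegratedFitResults(self, draws, cfg)

    def _flatten(self, st, smp):
        parts = [np.asarray([st[n] for n in self._scalar_names])]
        for vec, _labels, _size in self._vector_specs:
            parts.append(np.asarray(st[vec], float))
        psi = smp._side_probs(st, "psi")
        rho = smp._side_probs(st, "rho")
        parts.append(rho)
        parts.append(psi)
        parts.append([self.joint_log_posterior(st)])
        return np.concatenate(parts)


class IntegratedFitResults:
    """Posterior draws plus diagnostics and prediction entry points."""

    def __init__(self, model: IntegratedAbundanceModel, draws: PosteriorDraws,
                 config: McmcConfig):
        self.model = model
        self.draws = draws
        self.config = config

    # -- diagnostics -------------------------------------------------------

    def rhat(self) -> pd.Series:
        """Split-chain Gelman-Rubin statistic for every model parameter
        (derived per-row probabilities and lp__ excluded)."""
        skip = ("rho[", "psi[", "lp__")
        names = [n for n in self.draws.names if not n.startswith(skip)]
        from .mcmc import split_rhat
        return pd.Series({n: split_rhat(self.draws.parameter(n)) for n in names},
                         name="rhat")

    @property
    def converged(self) -> bool:
        return bool((self.rhat() < 1.1).all())

    def summary(self, params=None) -> pd.DataFrame:
        """Posterior mean, SD, central 90% CrI and R-hat."""
        tab = self.draws.summary()
        if params is not None:
            tab = tab.loc[[p for p in params if p in tab.index]]
        return tab

    # -- views -------------------------------------------------------------

    def hyper_params(self) -> HyperParams:
        """Posterior-mean hyper-model coefficients."""
        m = self.draws
        return HyperParams(
            beta0=float(m.flat("beta0").mean()),
            beta1=float(m.flat("beta1").mean()),
            beta2=float(m.flat("beta2").mean()),
            sigma_eps=float(m.flat("sigma_eps").mean()),
        )

    def _label(self, plot_id, year, month=None):
        if self.model.timescale == SHORT:
            return f"{plot_id}|{year}|{month}"
        return f"{plot_id}|{year}"

    def density_draws(self, plot_id, year, month=None) -> np.ndarray:
        """Posterior draws of expected density for a paired plot-period."""
        return np.exp(self.draws.flat(f"logD[{self._label(plot_id, year, month)}]"))

    # -- prediction (delegates) --------------------------------------------

    def classify_cases(self):
        from .predict import classify_cases
        return classify_cases(self.model.captures, self.model.tubes,
                              self.model.registry, self.model.timescale)

    def predict_plot_density(self, plot_id, year, month=None, rng=None):
        from .predict import predict_plot_density
        return predict_plot_density(self, plot_id, year, month=month, rng=rng)

    def predict_abundance(self, frame, rng=None, correlated=False):
        from .predict import aggregate_population
        return aggregate_population(self, frame, rng=rng, correlated=correlated)

    def to_frame(self) -> pd.DataFrame:
        return self.draws.to_frame()


class _SigmaTarget:
    """Gaussian log-density of an effect vector given its SD (closure-free
    so the scalar update machinery can treat sigmas uniformly)."""

    def __init__(self, vec_name, sigma_name):
        self.vec = vec_name
        self.sigma = sigma_name

    def __call__(self, st):
        return _norm_sum_logpdf(st[self.vec], max(st[self.sigma], 1e-4))
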