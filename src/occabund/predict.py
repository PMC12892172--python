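"""Posterior abundance prediction at plot and subpopulation level.

Three data scenarios per plot-period:

* ``PAIRED`` -- live-trapping and tube data: the plot-period's own posterior
  expected-density draws are used directly;
* ``TUBES_ONLY`` -- tube data only: posterior PSO and detection draws feed
  the hyper model with a fresh log-normal residual per draw;
* ``UNSAMPLED`` -- no monitoring: a representative sampled plot-period
  (same selection method, subpopulation and period; falling back to any
  method with a warning) is resampled uniformly per draw.

Abundance at the 1-ha plot scale is Poisson with mean equal to the drawn
density; subpopulation totals sum plot abundances over every hectare of
habitat.  By default each unsampled hectare resamples its representative
independently per posterior draw (``correlated=True`` shares one
representative draw per subpopulation and posterior draw, widening the
intervals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SHORT

PAIRED = "PAIRED"
TUBES_ONLY = "TUBES_ONLY"
UNSAMPLED = "UNSAMPLED"

#: Study-system defaults: subpopulation -> habitat area in hectares.
DEFAULT_AREAS = {"Oscar": 411.0, "Edson": 474.0, "SSM": 105.0}


@dataclass
class SubpopulationFrame:
    """Habitat areas (ha) per subpopulation; 1-ha plots tile the area."""

    areas: dict = field(default_factory=lambda: dict(DEFAULT_AREAS))

    def area(self, subpopulation) -> float:
        try:
            return float(self.areas[subpopulation])
        except KeyError:
            raise ValueError(f"no area configured for {subpopulation!r}") from None


def classify_cases(captures, tubes, registry, timescale=SHORT) -> pd.DataFrame:
    """Deterministically assign a prediction case to every registry
    plot-period (periods observed anywhere in the data)."""
    keys = ["plot_id", "year"] + (["month"] if timescale == SHORT else [])
    period_cols = keys[1:]
    periods = (
        pd.concat([tubes[period_cols], captures[period_cols]])
        .drop_duplicates()
        .sort_values(period_cols)
    )
    grid = registry[["plot_id"]].merge(periods, how="cross")
    tube_keys = set(map(tuple, tubes[keys].itertuples(index=False)))
    cap_keys = set(map(tuple, captures[keys].itertuples(index=False)))
    only_cap = cap_keys - tube_keys
    if only_cap:
        warnings.warn(
            f"{len(only_cap)} plot-periods have capture data without tube "
            "data; treated as PAIRED with missing-tube flag",
            stacklevel=2,
        )

    def case(row):
        key = tuple(row)
        if key in cap_keys:
            return PAIRED
        if key in tube_keys:
            return TUBES_ONLY
        return UNSAMPLED

    grid = grid.copy()
    grid["case"] = [case(r) for r in grid[keys].itertuples(index=False)]
    grid["missing_tube"] = [tuple(r) in only_cap
                            for r in grid[keys].itertuples(index=False)]
    return grid


def _occ_row_density(results, occ_idx: int, rng) -> np.ndarray:
    """Hyper-model density draws for one tube-only occupancy row."""
    m = results.model
    lab = m._occ_labels[occ_idx]
    rho = results.draws.flat(f"rho[{lab}]")
    psi = results.draws.flat(f"psi[{lab}]")
    d = m._data
    s = d.s[occ_idx]
    sstar = d.sstar[occ_idx]
    k = d.k[occ_idx]
    miss = (1.0 - rho) ** k
    psiC = psi * miss / (1.0 - psi * (1.0 - miss))
    u = rng.binomial(int(s - sstar), psiC)
    Psi = (sstar + u) / s
    b0 = results.draws.flat("beta0")
    b1 = results.draws.flat("beta1")
    b2 = results.draws.flat("beta2")
    se = results.draws.flat("sigma_eps")
    eps_new = rng.standard_normal(rho.shape) * se
    return np.exp(b0 + b1 * m._tr(Psi) + b2 * m._tr(rho) + eps_new)


def _density_bank(results, rng) -> pd.DataFrame:
    """Per-draw density for every sampled plot-period, with metadata."""
    m = results.model
    occ = m.tubes
    keys = m._key_cols()
    cap_label = {
        tuple(r): m._cap_labels[j]
        for j, r in enumerate(m.captures[keys].itertuples(index=False))
    }
    rows = []
    for i in range(len(occ)):
        key = tuple(occ.iloc[i][keys])
        if key in cap_label:
            dens = np.exp(results.draws.flat(f"logD[{cap_label[key]}]"))
            case = PAIRED
        else:
            dens = _occ_row_density(results, i, rng)
            case = TUBES_ONLY
        rec = {"plot_id": occ.iloc[i]["plot_id"], "year": occ.iloc[i]["year"],
               "subpopulation": occ.iloc[i]["subpopulation"],
               "X": int(occ.iloc[i]["X"]), "case": case, "density": dens}
        if m.timescale == SHORT:
            rec["month"] = occ.iloc[i]["month"]
        rows.append(rec)
    return pd.DataFrame(rows)


def predict_plot_density(results, plot_id, year, month=None, rng=None) -> np.ndarray:
    """Per-draw expected density for one plot-period under its data case."""
    rng = rng or np.random.default_rng(0)
    m = results.model
    keys = m._key_cols()
    key = (plot_id, year, month) if m.timescale == SHORT else (plot_id, year)
    cap_keys = list(map(tuple, m.captures[keys].itertuples(index=False)))
    if key in cap_keys:
        return results.density_draws(plot_id, year, month)
    occ_keys = list(map(tuple, m.tubes[keys].itertuples(index=False)))
    if key in occ_keys:
        return _occ_row_density(results, occ_keys.index(key), rng)
    # UNSAMPLED: representative resampling
    bank = _density_bank(results, rng)
    sub = m.registry.set_index("plot_id")["subpopulation"].get(plot_id)
    period = {"year": year, **({"month": month} if m.timescale == SHORT else {})}
    return _representative_density(bank, sub, period, X=0, rng=rng)


def _representative_density(bank, subpopulation, period, X, rng) -> np.ndarray:
    sel = (bank["subpopulation"] == subpopulation)
    for col, val in period.items():
        sel &= bank[col] == val
    cands = bank[sel & (bank["X"] == X)]
    if cands.empty:
        cands = bank[sel]
        if cands.empty:
            raise ValueError(
                f"no representative plot-period for {subpopulation} {period}")
        warnings.warn(
            f"no representative with matching selection method for "
            f"{subpopulation} {period}; using any method",
            stacklevel=2,
        )
    dens = np.stack(cands["density"].to_list())  # (R, ndraw)
    pick = rng.integers(0, dens.shape[0], size=dens.shape[1])
    return dens[pick, np.arange(dens.shape[1])]


def plot_abundance(density_draws, rng) -> np.ndarray:
    """Per-draw plot abundance: ``N ~ Poisson(density * 1 ha)``."""
    density_draws = np.asarray(density_draws, float)
    if np.any(density_draws < 0):
        raise ValueError("density draws must be non-negative")
    return rng.poisson(density_draws)


def aggregate_population(results, frame: SubpopulationFrame | None = None,
                         rng=None, correlated: bool = False) -> pd.DataFrame:
    """Posterior subpopulation abundance per period (mean, SD, 90% CrI).

    Sampled plots contribute Poisson draws around their own density draws;
    the remaining ``area - n_sampled`` hectares each receive a
    representative density draw (uniform over representatives, independent
    per hectare unless ``correlated``), then Poisson abundance.
    """
    frame = frame or SubpopulationFrame()
    rng = rng or np.random.default_rng(0)
    m = results.model
    bank = _density_bank(results, rng)
    period_cols = ["year"] + (["month"] if m.timescale == SHORT else [])
    out = []
    for (sub, *period), g in bank.groupby(["subpopulation"] + period_cols):
        period_d = dict(zip(period_cols, period))
        area = frame.area(sub)
        n_sampled = len(g)
        if area < n_sampled:
            raise ValueError(
                f"subpopulation {sub} area {area} ha smaller than "
                f"{n_sampled} sampled plots")
        ndraw = len(g["density"].iloc[0])
        total = np.zeros(ndraw, dtype=np.int64)
        for dens in g["density"]:
            total += rng.poisson(dens)
        n_extra = int(round(area - n_sampled))
        if n_extra > 0:
            dens_mat = np.stack(g["density"].to_list())  # (R, ndraw)
            R = dens_mat.shape[0]
            if correlated:
                pick = rng.integers(0, R, size=ndraw)
                lam = dens_mat[pick, np.arange(ndraw)]
                total += rng.poisson(np.broadcast_to(lam, (n_extra, ndraw))).sum(axis=0)
            else:
                pick = rng.integers(0, R, size=(n_extra, ndraw))
                lam = dens_mat[pick, np.arange(ndraw)[None, :]]
                total += rng.poisson(lam).sum(axis=0)
        q05, q95 = np.quantile(total, [0.05, 0.95])
        out.append({"subpopulation": sub, **period_d,
                    "mean": float(total.mean()),
                    "sd": float(total.std(ddof=1)),
                    "q05": float(q05), "q95": float(q95)})
    return pd.DataFrame(out)


def monthly_growth_rate(totals: pd.DataFrame, value_col: str = "mean") -> float:
    """Average ratio of consecutive monthly posterior-mean totals.

    ``totals`` needs columns subpopulation, year, month and ``value_col``;
    ratios are taken within subpopulation-year runs of consecutive months
    and averaged.  Zero-total months are skipped with a warning.
    """
    ratios = []
    for (_sub, _yr), g in totals.groupby(["subpopulation", "year"]):
        g = g.sort_values("month")
        months = g["month"].to_numpy()
        vals = g[value_col].to_numpy(float)
        for i in range(len(g) - 1):
            if months[i + 1] != months[i] + 1:
                continue
            if vals[i] == 0:
                warnings.warn("zero-total month skipped in growth rate",
                              stacklevel=2)
                continue
            ratios.append(vals[i + 1] / vals[i])
    if not ratios:
        raise ValueError("need at least two consecutive months of totals")
    return float(np.mean(ratios))
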