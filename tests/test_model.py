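"""Joint posterior assembly, determinism, hierarchy evaluation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import binom, norm

import occabund as oa
from occabund.huggins import CaptureParams, capture_prob
from occabund.model import IntegratedAbundanceModel, McmcConfig
from occabund.occupancy import OccupancyParams


def _tiny_tables():
    occ = pd.DataFrame({
        "plot_id": ["P1", "P2"], "year": [2020, 2020],
        "month": pd.array([5, 5], dtype="Int64"),
        "s": [4, 4], "s_star": [2, 1], "d": [3, 1], "k": [2, 2],
    })
    cap = pd.DataFrame({
        "plot_id": ["P1"], "year": [2020],
        "month": pd.array([5], dtype="Int64"),
        "M": [2], "n": [3], "t": [6],
    })
    reg = pd.DataFrame({
        "plot_id": ["P1", "P2"], "subpopulation": ["A", "A"],
        "selection_method": ["nonrandom", "random"], "X": [1, 0],
    })
    return cap, occ, reg


class TestHierarchies:
    def test_capture_prob_linear_predictor(self):
        params = CaptureParams(mu_p=-1.0, eta_g_p={"P1": 0.4},
                               eta_y_p={2020: 0.3}, eta_m_p={5: 0.3},
                               eps_p={("P1", 2020, 5): 0.0})
        assert capture_prob(params, "P1", 2020, 5) == pytest.approx(0.5)
        base = CaptureParams(mu_p=-1.0, eta_g_p={"P1": 0.0},
                             eta_y_p={2020: 0.0}, eta_m_p={5: 0.0})
        assert capture_prob(base, "P1", 2020, 5) == pytest.approx(0.26894, abs=1e-5)

    def test_missing_level_raises(self):
        params = CaptureParams(mu_p=0.0, eta_g_p={"P1": 0.0}, eta_y_p={})
        with pytest.raises(ValueError, match="not registered"):
            capture_prob(params, "P1", 2021)

    def test_selection_covariate_enters_occupancy(self):
        params = OccupancyParams(mu=0.0, beta=0.59, eta_g={"P1": 0.0},
                                 eta_y={2020: 0.0}, eta_m={5: 0.0})
        assert params.prob("P1", 2020, 5, X=1) == pytest.approx(0.643365, abs=1e-5)
        assert params.prob("P1", 2020, 5, X=0) == pytest.approx(0.5)


class TestJointLogPosterior:
    def test_hand_summed_components(self):
        """The joint log posterior equals an independent recomputation of
        every term through the module-level likelihood functions."""
        cap, occ, reg = _tiny_tables()
        model = IntegratedAbundanceModel(cap, occ, reg, timescale="short")
        st = model.initial_state(np.random.default_rng(3))

        total = 0.0
        # scalar priors
        for name in model._scalar_names:
            pr = model._d_prior if name == "d_hr" else model.priors.for_scalar(name)
            total += pr.logpdf(st[name])
        # random-effect priors
        for vec, sig in [("eta_g_rho", "sigma_g_rho"), ("eta_y_rho", "sigma_y_rho"),
                         ("eta_m_rho", "sigma_m_rho"), ("eps_rho", "sigma_rho"),
                         ("eta_g_psi", "sigma_g_psi"), ("eta_y_psi", "sigma_y_psi"),
                         ("eta_m_psi", "sigma_m_psi"), ("eps_psi", "sigma_psi"),
                         ("eta_g_p", "sigma_g_p"), ("eta_y_p", "sigma_y_p"),
                         ("eta_m_p", "sigma_m_p"), ("eps_p", "sigma_p")]:
            total += float(norm.logpdf(st[vec], 0, st[sig]).sum())
        # occupancy terms, row by row
        probs = {}
        for i, row in occ.iterrows():
            X = reg.set_index("plot_id")["X"][row["plot_id"]]
            psi = float(np.clip(expit(
                st["mu_psi"] + st["beta_psi"] * X + st["eta_g_psi"][i]
                + st["eta_y_psi"][0] + st["eta_m_psi"][0] + st["eps_psi"][i]),
                1e-12, 1 - 1e-12))
            rho = float(np.clip(expit(
                st["mu_rho"] + st["beta_rho"] * X + st["eta_g_rho"][i]
                + st["eta_y_rho"][0] + st["eta_m_rho"][0] + st["eps_rho"][i]),
                1e-12, 1 - 1e-12))
            probs[row["plot_id"]] = (psi, rho)
            total += oa.occupancy_loglik(row["s"], row["s_star"], row["d"],
                                         row["k"], psi, rho)
        # capture terms for the paired plot-period
        p = float(np.clip(expit(st["mu_p"] + st["eta_g_p"][0] + st["eta_y_p"][0]
                                + st["eta_m_p"][0] + st["eps_p"][0]),
                          1e-12, 1 - 1e-12))
        M, n, t = 2, 3, 6
        total += oa.huggins_loglik(M, n, t, p)
        lam = math.exp(st["logD"][0]) * oa.effective_area(37.5, st["d_hr"])
        total += oa.observed_capture_loglik(M, lam, oa.p_star(p, t))
        # latent u and the hyper model
        psi1, rho1 = probs["P1"]
        psiC = oa.psi_conditional(psi1, rho1, 2)
        u = int(st["u"][0])
        total += float(binom.logpmf(u, 4 - 2, psiC))
        Psi = (2 + u) / 4
        mean = (st["beta0"] + st["beta1"] * math.sqrt(Psi)
                + st["beta2"] * math.sqrt(rho1))
        total += float(norm.logpdf(st["logD"][0], mean, st["sigma_eps"]))

        assert model.joint_log_posterior(st) == pytest.approx(total, abs=1e-8)

    def test_empty_dataset_reduces_to_priors(self):
        occ = pd.DataFrame(columns=["plot_id", "year", "month", "s", "s_star",
                                    "d", "k"])
        occ["month"] = occ["month"].astype("Int64")
        cap = pd.DataFrame(columns=["plot_id", "year", "month", "M", "n", "t"])
        cap["month"] = cap["month"].astype("Int64")
        reg = pd.DataFrame({"plot_id": ["P1"], "subpopulation": ["A"],
                            "selection_method": ["random"], "X": [0]})
        model = IntegratedAbundanceModel(cap, occ, reg, timescale="short")
        st = model.initial_state(np.random.default_rng(0))
        expected = sum(
            (model._d_prior if n == "d_hr" else model.priors.for_scalar(n))
            .logpdf(st[n]) for n in model._scalar_names)
        assert model.joint_log_posterior(st) == pytest.approx(expected)

    def test_long_timescale_has_no_month_effects(self):
        cap, occ, reg = _tiny_tables()
        occ = occ.assign(month=pd.array([pd.NA, pd.NA], dtype="Int64"))
        cap = cap.assign(month=pd.array([pd.NA], dtype="Int64"))
        model = IntegratedAbundanceModel(cap, occ, reg, timescale="long")
        assert "sigma_m_p" not in model._scalar_names
        assert not any(n.startswith("eta_m") for n, _, _ in model._vector_specs)
        assert model.homerange.mean_d == pytest.approx(20.19)


class TestFitMechanics:
    def test_same_seed_identical_draws(self):
        cap, occ, reg = _tiny_tables()
        model = IntegratedAbundanceModel(cap, occ, reg, timescale="short")
        r1 = model.fit(chains=2, iterations=200, seed=7)
        r2 = IntegratedAbundanceModel(cap, occ, reg, timescale="short").fit(
            chains=2, iterations=200, seed=7)
        np.testing.assert_array_equal(r1.draws.values, r2.draws.values)

    def test_unmatched_capture_rows_dropped_with_warning(self):
        cap, occ, reg = _tiny_tables()
        cap2 = pd.concat([cap, pd.DataFrame({
            "plot_id": ["P2"], "year": [2020],
            "month": pd.array([6], dtype="Int64"),
            "M": [1], "n": [1], "t": [6]})], ignore_index=True)
        with pytest.warns(UserWarning, match="no matching occupancy"):
            model = IntegratedAbundanceModel(cap2, occ, reg, timescale="short")
        assert len(model.captures) == 1

    def test_mcmc_config_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(iterations=100, burnin=1.0).resolved("short")

    def test_frozen_homerange_not_sampled(self):
        cap, occ, reg = _tiny_tables()
        model = IntegratedAbundanceModel(cap, occ, reg, timescale="short",
                                         freeze_homerange=True)
        assert "d_hr" not in model._scalar_names
        res = model.fit(chains=2, iterations=100, seed=0)
        assert "d_hr" not in res.draws.names
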