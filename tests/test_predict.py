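"""Abundance prediction: case classification, density draws, aggregation."""

import numpy as np
import pandas as pd
import pytest

import occabund as oa
from occabund.mcmc import PosteriorDraws
from occabund.model import IntegratedFitResults, McmcConfig
from occabund.predict import (
    PAIRED,
    TUBES_ONLY,
    UNSAMPLED,
    _occ_row_density,
    aggregate_population,
    classify_cases,
    monthly_growth_rate,
    plot_abundance,
)


class TestClassifyCases:
    def test_assignment_from_data_availability(self, desk_model):
        registry = pd.concat([
            desk_model.registry,
            pd.DataFrame({"plot_id": ["P999"], "subpopulation": ["Oscar"],
                          "selection_method": ["random"], "X": [0]}),
        ], ignore_index=True)
        cases = classify_cases(desk_model.captures, desk_model.tubes,
                               registry, "short")
        by_plot = cases.groupby("plot_id")["case"].unique()
        # core plots are trapped every period
        for p in desk_model.captures["plot_id"].unique():
            assert list(by_plot[p]) == [PAIRED]
        # registry plot absent from both tables
        assert list(by_plot["P999"]) == [UNSAMPLED]
        tubes_only = set(desk_model.tubes["plot_id"]) - set(
            desk_model.captures["plot_id"])
        for p in tubes_only:
            assert list(by_plot[p]) == [TUBES_ONLY]

    def test_capture_without_tubes_flagged(self, desk_model):
        cap2 = pd.concat([desk_model.captures, pd.DataFrame({
            "plot_id": ["P002"], "year": [2021],
            "month": pd.array([99], dtype="Int64"),
            "M": [0], "n": [0], "t": [6]})], ignore_index=True)
        with pytest.warns(UserWarning, match="missing-tube"):
            cases = classify_cases(cap2, desk_model.tubes,
                                   desk_model.registry, "short")
        row = cases[(cases["plot_id"] == "P002") & (cases["month"] == 99)]
        assert (row["case"] == PAIRED).all()
        assert row["missing_tube"].all()


class TestPlotDensity:
    def test_paired_passthrough_equals_stored_draws(self, desk_fit):
        plot = desk_fit.model.captures["plot_id"].iloc[0]
        year = desk_fit.model.captures["year"].iloc[0]
        month = desk_fit.model.captures["month"].iloc[0]
        via_predict = desk_fit.predict_plot_density(plot, year, month)
        np.testing.assert_allclose(via_predict,
                                   desk_fit.density_draws(plot, year, month))

    def test_tubes_only_prediction_positive_and_seeded(self, desk_fit):
        tubes_only = sorted(set(desk_fit.model.tubes["plot_id"])
                            - set(desk_fit.model.captures["plot_id"]))
        plot = tubes_only[0]
        row = desk_fit.model.tubes.query("plot_id == @plot").iloc[0]
        a = desk_fit.predict_plot_density(plot, row["year"], row["month"],
                                          rng=np.random.default_rng(9))
        b = desk_fit.predict_plot_density(plot, row["year"], row["month"],
                                          rng=np.random.default_rng(9))
        assert np.all(a > 0)
        np.testing.assert_array_equal(a, b)

    def test_fresh_residual_inflates_mean_by_lognormal_factor(self, desk_model):
        """Case-2 predictions exceed their zero-residual version in mean by
        exp(sigma_eps^2 / 2)."""
        se = 0.8
        ndraw = 120_000
        lab = desk_model._occ_labels[0]
        names = ["beta0", "beta1", "beta2", "sigma_eps",
                 f"rho[{lab}]", f"psi[{lab}]"]
        vals = np.tile(np.array([0.0, 1.0, 1.0, se, 0.999, 0.5]),
                       (1, ndraw, 1))
        res = IntegratedFitResults(desk_model, PosteriorDraws(vals, names),
                                   McmcConfig())
        dens = _occ_row_density(res, 0, np.random.default_rng(2))
        # rho ~ 1 forces u = 0, so the linear predictor is constant
        d0 = desk_model._data
        Psi = d0.sstar[0] / d0.s[0]
        lin = 1.0 * np.sqrt(Psi) + 1.0 * np.sqrt(0.999)
        ratio = dens.mean() / np.exp(lin)
        assert ratio == pytest.approx(np.exp(se**2 / 2), rel=0.02)


class TestPlotAbundance:
    def test_zero_density_gives_zero(self, rng):
        assert np.all(plot_abundance(np.zeros(100), rng) == 0)

    def test_poisson_moments(self, rng):
        draws = plot_abundance(np.full(10**5, 5.0), rng)
        assert draws.mean() == pytest.approx(5.0, abs=0.05)
        assert draws.var() == pytest.approx(5.0, rel=0.05)
        assert np.issubdtype(draws.dtype, np.integer)

    def test_negative_density_rejected(self, rng):
        with pytest.raises(ValueError):
            plot_abundance(np.array([-1.0]), rng)


class TestAggregation:
    def test_totals_match_expected_density_budget(self, desk_fit):
        """Posterior-mean totals equal (sampled + resampled hectares) times
        the mean plot density, within Monte Carlo error."""
        from occabund.predict import SubpopulationFrame, _density_bank

        rng = np.random.default_rng(5)
        areas = {s: 12.0 for s in
                 desk_fit.model.registry["subpopulation"].unique()}
        totals = aggregate_population(desk_fit, SubpopulationFrame(areas),
                                      rng=np.random.default_rng(5))
        bank = _density_bank(desk_fit, np.random.default_rng(5))
        period_cols = ["year", "month"]
        for _, row in totals.iterrows():
            g = bank[(bank["subpopulation"] == row["subpopulation"])
                     & (bank["year"] == row["year"])
                     & (bank["month"] == row["month"])]
            mean_dens = np.mean([d.mean() for d in g["density"]])
            expected = 12.0 * mean_dens
            # Poisson + resampling noise on the mean of ~3000 draws
            assert row["mean"] == pytest.approx(expected, rel=0.15)

    def test_area_smaller_than_sampled_plots_errors(self, desk_fit):
        from occabund.predict import SubpopulationFrame

        areas = {s: 1.0 for s in
                 desk_fit.model.registry["subpopulation"].unique()}
        with pytest.raises(ValueError, match="smaller"):
            aggregate_population(desk_fit, SubpopulationFrame(areas),
                                 rng=np.random.default_rng(0))

    def test_correlated_aggregation_widens_intervals(self, desk_fit):
        from occabund.predict import SubpopulationFrame

        areas = {s: 40.0 for s in
                 desk_fit.model.registry["subpopulation"].unique()}
        frame = SubpopulationFrame(areas)
        ind = aggregate_population(desk_fit, frame,
                                   rng=np.random.default_rng(1),
                                   correlated=False)
        cor = aggregate_population(desk_fit, frame,
                                   rng=np.random.default_rng(1),
                                   correlated=True)
        assert cor["sd"].mean() > ind["sd"].mean()


class TestGrowthRate:
    def _totals(self, means):
        return pd.DataFrame({
            "subpopulation": "A", "year": 2020,
            "month": range(4, 4 + len(means)), "mean": means,
        })

    def test_constant_series(self):
        assert monthly_growth_rate(self._totals([50, 50, 50])) == 1.0

    def test_doubling(self):
        assert monthly_growth_rate(self._totals([100, 200])) == 2.0

    def test_mean_of_consecutive_ratios(self):
        assert monthly_growth_rate(self._totals([100, 150, 225])) == \
            pytest.approx(1.5)

    def test_zero_month_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            rate = monthly_growth_rate(self._totals([0, 100, 150]))
        assert rate == pytest.approx(1.5)

    def test_single_month_errors(self):
        with pytest.raises(ValueError):
            monthly_growth_rate(self._totals([100]))
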