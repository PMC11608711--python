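"""Survival model fitting: closed forms, oracles, spline limits, anchoring."""

import numpy as np
import pytest
from lifelines import (
    LogLogisticFitter, LogNormalFitter, WeibullFitter,
)

from psmcea import RunConfig
from psmcea.fitting import (
    FitError, SurvivalFit, apply_hazard_ratio, extrapolate, fit_catalogue,
    fit_parametric, fit_royston_parmar, rp_knot_locations, select_model,
    survival_at, AnchoredCurve,
)
from psmcea.reconstruct import PseudoIPD


class TestParametricFits:
    def test_exponential_rate_closed_form(self):
        # MLE rate = events / total time; 4 events over 10 units -> 0.4
        ipd = PseudoIPD(times=[1.0, 2.0, 3.0, 4.0], events=[1, 1, 1, 1])
        fit = fit_parametric(ipd, "exponential", min_events=1)
        assert fit.params["rate"] == pytest.approx(0.4, rel=1e-6)
        assert fit.log_likelihood == pytest.approx(4 * np.log(0.4) - 0.4 * 10, rel=1e-9)

    def test_exponential_with_censoring(self):
        ipd = PseudoIPD(times=[1.0, 2.0, 3.0, 4.0], events=[1, 1, 0, 0])
        fit = fit_parametric(ipd, "exponential", min_events=1)
        assert fit.params["rate"] == pytest.approx(0.2, rel=1e-6)

    @pytest.mark.parametrize(
        "family, fitter_cls",
        [
            ("weibull", WeibullFitter),
            ("lognormal", LogNormalFitter),
            ("loglogistic", LogLogisticFitter),
        ],
    )
    def test_loglikelihood_matches_lifelines(self, weibull_sample, family, fitter_cls):
        ours = fit_parametric(weibull_sample, family)
        oracle = fitter_cls().fit(weibull_sample.times, weibull_sample.events)
        theirs = float(oracle.log_likelihood_)
        assert ours.log_likelihood >= theirs - 1e-4
        assert ours.log_likelihood == pytest.approx(theirs, abs=1e-3)

    def test_weibull_params_match_lifelines(self, weibull_sample):
        ours = fit_parametric(weibull_sample, "weibull")
        oracle = WeibullFitter().fit(weibull_sample.times, weibull_sample.events)
        assert ours.params["shape"] == pytest.approx(float(oracle.rho_), rel=1e-4)
        assert ours.params["scale"] == pytest.approx(float(oracle.lambda_), rel=1e-4)

    def test_survival_matches_lifelines(self, weibull_sample):
        ours = fit_parametric(weibull_sample, "weibull")
        oracle = WeibullFitter().fit(weibull_sample.times, weibull_sample.events)
        grid = np.linspace(0.1, 6.0, 40)
        np.testing.assert_allclose(
            survival_at(ours, grid),
            oracle.survival_function_at_times(grid).to_numpy(),
            atol=1e-4,
        )

    def test_aic_identity(self, weibull_sample):
        for fam in ("exponential", "weibull", "lognormal"):
            f = fit_parametric(weibull_sample, fam)
            assert f.aic == pytest.approx(2 * f.n_params - 2 * f.log_likelihood)

    def test_true_family_competitive_at_large_n(self):
        # 2000 uncensored Weibull times: the true family must be within
        # 2 AIC of the best candidate
        rng = np.random.default_rng(7)
        ipd = PseudoIPD(times=2.0 * rng.weibull(1.4, 2000), events=np.ones(2000))
        fits = [fit_parametric(ipd, fam)
                for fam in ("exponential", "weibull", "gamma",
                            "loglogistic", "lognormal", "gompertz")]
        best = min(f.aic for f in fits)
        weib = next(f for f in fits if f.family == "weibull")
        assert weib.aic <= best + 2.0

    def test_degenerate_data_rejected(self):
        allc = PseudoIPD(times=np.arange(1, 30, dtype=float), events=np.zeros(29))
        with pytest.raises(FitError, match="censored"):
            fit_parametric(allc, "weibull")
        few = PseudoIPD(times=np.arange(1, 30, dtype=float),
                        events=np.r_[np.ones(3), np.zeros(26)])
        with pytest.raises(FitError, match="too few"):
            fit_parametric(few, "weibull")

    def test_unknown_family(self, weibull_sample):
        with pytest.raises(ValueError, match="unknown family"):
            fit_parametric(weibull_sample, "pareto")

    def test_confint_brackets_estimate(self, weibull_sample):
        f = fit_parametric(weibull_sample, "weibull")
        lo, hi = f.confint("shape")
        assert lo < f.params["shape"] < hi
        assert lo > 0  # log-parameterized


class TestRoystonParmar:
    def test_zero_knot_hazard_equals_weibull(self, weibull_sample):
        weib = fit_parametric(weibull_sample, "weibull")
        rp = fit_royston_parmar(weibull_sample, 0, "hazard")
        assert abs(rp.log_likelihood - weib.log_likelihood) <= 1e-4
        grid = np.linspace(0.05, 8.0, 50)
        np.testing.assert_allclose(
            survival_at(rp, grid), survival_at(weib, grid), atol=1e-4
        )

    def test_zero_knot_odds_equals_loglogistic(self, weibull_sample):
        llog = fit_parametric(weibull_sample, "loglogistic")
        rp = fit_royston_parmar(weibull_sample, 0, "odds")
        assert abs(rp.log_likelihood - llog.log_likelihood) <= 1e-4

    @pytest.mark.parametrize("scale", ["hazard", "odds"])
    def test_likelihood_nondecreasing_in_knots(self, weibull_sample, scale):
        lls = [fit_royston_parmar(weibull_sample, m, scale).log_likelihood
               for m in (0, 1, 2)]
        for a, b in zip(lls, lls[1:]):
            assert b >= a - 1e-6

    def test_fitted_survival_is_monotone(self, weibull_sample):
        rp = fit_royston_parmar(weibull_sample, 2, "hazard")
        grid = np.linspace(0.0, 25.0, 500)
        s = survival_at(rp, grid)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))

    def test_knot_locations_on_event_quantiles(self, weibull_sample):
        x = np.log(weibull_sample.times[weibull_sample.events == 1])
        k = rp_knot_locations(weibull_sample, 1)
        assert k["boundary"] == (pytest.approx(x.min()), pytest.approx(x.max()))
        assert k["interior"][0] == pytest.approx(np.quantile(x, 0.5))
        with pytest.raises(ValueError):
            rp_knot_locations(weibull_sample, 5)

    def test_invalid_scale(self, weibull_sample):
        with pytest.raises(ValueError, match="scale"):
            fit_royston_parmar(weibull_sample, 1, "probit")


class TestCatalogueAndSelection:
    def test_catalogue_covers_families_and_splines(self, weibull_sample):
        fits = fit_catalogue(weibull_sample, rp_knots=(1,))
        labels = {f.label for f in fits}
        assert "weibull" in labels and "rp_hazard_1k" in labels and "rp_odds_1k" in labels

    def test_select_lowest_aic(self, weibull_sample):
        fits = [fit_parametric(weibull_sample, f)
                for f in ("exponential", "weibull", "lognormal")]
        table, chosen = select_model(fits)
        assert table["aic"].is_monotonic_increasing
        assert chosen.aic == min(f.aic for f in fits)

    def test_tie_broken_by_parsimony(self, weibull_sample):
        simple = fit_parametric(weibull_sample, "exponential")
        rich = fit_parametric(weibull_sample, "weibull")
        # force an exact AIC tie by padding the simple model's likelihood
        tied = SurvivalFit(
            family="exponential", params=simple.params, theta=simple.theta,
            param_names=simple.param_names,
            log_likelihood=rich.log_likelihood - (rich.n_params - 1),
            n_params=1, n=simple.n, n_events=simple.n_events, label="exponential",
        )
        assert tied.aic == pytest.approx(rich.aic)
        _, chosen = select_model([rich, tied])
        assert chosen.n_params == 1

    def test_override(self, weibull_sample):
        fits = fit_catalogue(weibull_sample, families=("weibull", "lognormal"),
                             rp_knots=(1, 2))
        _, chosen = select_model(fits, override="lognormal")
        assert chosen.family == "lognormal"
        _, chosen = select_model(fits, override="rp_odds,2")
        assert chosen.scale == "odds" and len(chosen.knots["interior"]) == 2
        with pytest.raises(ValueError, match="matches no"):
            select_model(fits, override="gompertz")


class TestAnchoringAndExtrapolation:
    def test_identity_hazard_ratio(self):
        base = np.array([1.0, 0.9, 0.5, 0.1])
        np.testing.assert_array_equal(apply_hazard_ratio(base, 1.0), base)

    def test_power_algebra(self):
        assert apply_hazard_ratio(np.array([0.8]), 0.63)[0] == pytest.approx(0.8**0.63)
        assert 0.8**0.63 == pytest.approx(0.8688, abs=1e-4)

    def test_protective_ratio_raises_survival(self):
        base = np.linspace(1.0, 0.05, 30)
        anchored = apply_hazard_ratio(base, 0.63)
        assert np.all(anchored >= base)
        assert np.all(np.diff(anchored) <= 0)

    def test_composition(self):
        base = np.linspace(1.0, 0.2, 10)
        ab = apply_hazard_ratio(apply_hazard_ratio(base, 0.7), 0.9)
        np.testing.assert_allclose(ab, apply_hazard_ratio(base, 0.63))

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(np.array([1.0, 0.5]), 0.0)
        with pytest.raises(ValueError):
            AnchoredCurve(base=np.array([1.0, 0.5]), hr=-1.0)

    def test_anchored_curve_validates_base(self):
        with pytest.raises(ValueError, match="non-increasing"):
            AnchoredCurve(base=np.array([0.5, 0.9]), hr=0.8)
        with pytest.raises(ValueError, match="outside"):
            AnchoredCurve(base=np.array([1.2, 0.5]), hr=0.8)

    def test_extrapolate_fit_shape(self, weibull_sample, config):
        f = fit_parametric(weibull_sample, "weibull")
        s = extrapolate(f, config)
        assert len(s) == 348
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 0) and np.all((s >= 0) & (s <= 1))

    def test_extrapolate_pads_short_vector(self, config):
        s = extrapolate(np.array([1.0, 0.5, 0.25]), config)
        assert len(s) == 348
        assert s[-1] == 0.25

    def test_extrapolate_truncates_long_vector(self):
        cfg = RunConfig(horizon_years=5.0)
        s = extrapolate(np.linspace(1.0, 0.0, 1000), cfg)
        assert len(s) == cfg.n_cycles == 87

    def test_survival_at_rejects_negative_time(self, weibull_sample):
        f = fit_parametric(weibull_sample, "weibull")
        with pytest.raises(ValueError):
            survival_at(f, [-1.0])
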