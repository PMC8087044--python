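"""Vital-rate estimators: Monte-Carlo recovery, closed-form oracles, AIC selection."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import rametipm as rp
from rametipm.errors import DegenerateDataError, SeparationError
from rametipm.vital_rates import (
    FlowerCountRegression,
    GrowthRegression,
    SizeLogisticRegression,
    TruncatedNormalFit,
    select_from_candidates,
)

SIZE_RANGE = (-6.04, 3.31)


def _within_2se(fit, truth: dict):
    for name, true_val in truth.items():
        est = fit.coefficients[name]
        se = fit.standard_errors[name]
        assert abs(est - true_val) < 2 * se, (name, est, true_val, se)


class TestSurvival:
    def test_recovers_generating_coefficients(self, big_dataset):
        fit = rp.fit_survival(big_dataset)
        _within_2se(fit, {"beta0_s": 2.790, "beta1_s": 0.731})
        assert fit.n == 5000
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 4)

    def test_null_slope_when_survival_independent_of_size(self):
        rng = np.random.default_rng(10)
        z = rng.uniform(*SIZE_RANGE, 4000)
        y = rng.binomial(1, 0.7, 4000)
        est = SizeLogisticRegression().fit(z, y)
        assert abs(est.coef_[1]) < 2 * est.bse_[1]

    def test_probability_at_mean_size_closed_form(self, ref_params):
        # inv-logit of the survival intercept is the predicted survival at z=0
        assert ref_params.survival_prob(0.0) == pytest.approx(expit(2.790), rel=1e-12)
        assert float(expit(2.790)) == pytest.approx(0.9421, abs=5e-5)

    def test_constant_response_rejected(self):
        with pytest.raises(SeparationError):
            SizeLogisticRegression().fit(np.linspace(0, 1, 50), np.ones(50))

    def test_complete_separation_rejected(self):
        z = np.linspace(-1, 1, 100)
        y = (z > 0).astype(float)
        with pytest.raises(SeparationError):
            SizeLogisticRegression().fit(z, y)

    def test_order_invariance_and_duplication_scaling(self, big_dataset):
        fit = rp.fit_survival(big_dataset)
        shuffled = rp.RametDataset(
            big_dataset.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        fit2 = rp.fit_survival(shuffled)
        for k in fit.coefficients:
            assert fit2.coefficients[k] == pytest.approx(fit.coefficients[k], abs=1e-8)
        doubled_df = pd.concat([big_dataset.data] * 2, ignore_index=True)
        doubled_df["ramet_id"] = [f"d{i}" for i in range(len(doubled_df))]
        fit3 = rp.fit_survival(rp.RametDataset(doubled_df))
        for k in fit.coefficients:
            assert fit3.coefficients[k] == pytest.approx(fit.coefficients[k], abs=1e-6)
            assert fit3.standard_errors[k] == pytest.approx(
                fit.standard_errors[k] / np.sqrt(2), rel=1e-4
            )


class TestGrowth:
    def test_recovers_generating_coefficients(self, ref_params):
        ds = rp.generate_population(ref_params, 5000, seed=2)
        fit = rp.fit_growth(ds)
        _within_2se(
            fit,
            {"beta0_g": 0.016, "beta1_g": 0.898, "sigma0_g": 0.5, "betasigma_g": -0.175},
        )
        assert fit.converged

    def test_homoskedastic_limit_matches_ols(self):
        rng = np.random.default_rng(20)
        z = rng.uniform(*SIZE_RANGE, 5000)
        y = 0.3 + 0.9 * z + rng.normal(0, 0.4, 5000)
        est = GrowthRegression(variance="exponential").fit(z, y)
        assert abs(est.sigma_slope_) < 2 * est.bse_[3]
        X = np.column_stack([np.ones_like(z), z])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(est.coef_, ols, atol=1e-4)

    def test_constant_variance_fit_is_exactly_ols(self):
        rng = np.random.default_rng(21)
        z = rng.uniform(-2, 2, 800)
        y = 0.1 + 0.8 * z + rng.normal(0, 0.3, 800)
        est = GrowthRegression(variance="constant").fit(z, y)
        X = np.column_stack([np.ones_like(z), z])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(est.coef_, ols, atol=1e-6)

    def test_zero_residual_variance_rejected(self):
        z = np.linspace(0, 1, 10)
        with pytest.raises(DegenerateDataError):
            GrowthRegression().fit(z, 2 * z)  # exact line

    def test_predict_sd_shape(self, ref_params):
        ds = rp.generate_population(ref_params, 2000, seed=22)
        df = ds.year_t_records
        df = df[df["survived"] == 1]
        est = GrowthRegression().fit(df["size_t"].to_numpy(), df["size_t1"].to_numpy())
        # SD must decrease with size when the exponent is negative
        assert est.sigma_slope_ < 0
        assert est.predict_sd([-2.0]) > est.predict_sd([2.0])


class TestFlowering:
    def test_recovers_generating_coefficients(self, ref_params):
        ds = rp.generate_population(ref_params, 5000, seed=3)
        fit = rp.fit_flowering(ds)
        _within_2se(fit, {"beta0_pr": 1.021, "beta1_pr": 1.103})
        # flowering is fit on all year-t ramets
        assert fit.n == len(ds.year_t_records)

    def test_probability_at_mean_size_closed_form(self, ref_params):
        assert ref_params.flowering_prob(0.0) == pytest.approx(0.735, abs=5e-4)

    def test_all_flowered_detected(self):
        df = rp.generate_population(rp.reference_parameterization(), 100, seed=0).data
        df["flowered"] = 1.0
        df["n_flowers"] = np.maximum(df["n_flowers"].fillna(0), 1.0)
        with pytest.raises(SeparationError):
            rp.fit_flowering(rp.RametDataset(df))


class TestFlowerCount:
    def test_recovers_mean_structure_on_untruncated_counts(self):
        """Poisson quasi-ML on NB(mean, var=2·mean) counts recovers the log-linear mean."""
        rng = np.random.default_rng(4)
        z = rng.uniform(*SIZE_RANGE, 5000)
        mu = np.exp(1.664 + 0.753 * z)
        y = rng.negative_binomial(mu / 1.0, 0.5)  # r = mu/(phi-1), p = 1/phi, phi = 2
        est = FlowerCountRegression().fit(z, y)
        assert abs(est.coef_[0] - 1.664) < 2 * est.bse_[0]
        assert abs(est.coef_[1] - 0.753) < 2 * est.bse_[1]
        assert 1.5 < est.dispersion_ < 2.5

    def test_predicted_count_at_mean_size_closed_form(self, ref_params):
        assert ref_params.flower_count_mean(0.0) == pytest.approx(5.28, abs=0.01)

    def test_equidispersed_poisson_limit(self):
        rng = np.random.default_rng(40)
        z = rng.uniform(-1, 2, 4000)
        y = rng.poisson(np.exp(1.0 + 0.5 * z))
        est = FlowerCountRegression().fit(z, y)
        # phi-hat is ~1 with Monte-Carlo noise of order sqrt(2/n)
        assert abs(est.dispersion_ - 1.0) < 3 * np.sqrt(2 / 4000)

    def test_dataset_fit_uses_flowering_ramets_only(self, big_dataset):
        fit = rp.fit_flower_count(big_dataset)
        assert fit.n == big_dataset.n_flowering
        assert fit.dispersion is not None

    def test_constant_counts_rejected(self):
        with pytest.raises(DegenerateDataError):
            FlowerCountRegression().fit(np.linspace(0, 1, 30), np.full(30, 5.0))


class TestRecruitSize:
    BOUNDS = (-6.84, 4.11)

    def test_recovers_truncated_normal_parameters(self):
        a = (self.BOUNDS[0] + 3.103) / 1.064
        b = (self.BOUNDS[1] + 3.103) / 1.064
        draws = stats.truncnorm.rvs(
            a, b, loc=-3.103, scale=1.064, size=2000, random_state=np.random.default_rng(5)
        )
        fit = rp.fit_recruit_size(draws, self.BOUNDS)
        assert abs(fit.coefficients["mu_rd"] + 3.103) < 0.08
        assert abs(fit.coefficients["sigma_rd"] - 1.064) < 0.06

    def test_wide_bounds_equal_untruncated_ml(self):
        rng = np.random.default_rng(50)
        x = rng.normal(-1.0, 0.8, 500)
        fit = rp.fit_recruit_size(x, (-100.0, 100.0))
        assert fit.coefficients["mu_rd"] == pytest.approx(float(np.mean(x)), abs=1e-6)
        assert fit.coefficients["sigma_rd"] == pytest.approx(float(np.std(x)), abs=1e-6)

    def test_identical_sizes_degenerate(self):
        fit = rp.fit_recruit_size([0.5, 0.5], (-10, 10))
        assert fit.degenerate

    def test_sizes_outside_bounds_named(self):
        with pytest.raises(DegenerateDataError, match="outside bounds"):
            rp.fit_recruit_size([0.0, 99.0], (-10, 10))


class TestRecruitmentRate:
    @pytest.mark.parametrize(
        "n_rec,flowers,expected", [(10, 1000, 0.01), (0, 500, 0.0), (10, 10, 1.0)]
    )
    def test_rate_arithmetic(self, n_rec, flowers, expected):
        assert rp.estimate_recruitment_rate(n_rec, flowers) == expected

    def test_zero_flowers_undefined(self):
        with pytest.raises(DegenerateDataError):
            rp.estimate_recruitment_rate(5, 0)


class TestModelSelection:
    def test_linear_truth_selects_linear(self, big_dataset):
        table = rp.select_by_aic(big_dataset, "survival")
        assert table.selected == "linear"

    def test_growth_selection_prefers_exponential_sd(self, big_dataset):
        table = rp.select_by_aic(big_dataset, "growth")
        assert table.selected == "linear+exponential_sd"

    def test_tie_breaks_toward_fewer_parameters(self):
        # two candidates with identical AIC = 204: simpler wins
        cands = [
            {"formula": "simple", "aic": -2 * -100 + 2 * 2, "n_params": 2, "error": None},
            {"formula": "complex", "aic": -2 * -99 + 2 * 3, "n_params": 3, "error": None},
        ]
        assert select_from_candidates(cands) == "simple"
        assert cands[0]["delta_aic"] == 0.0

    def test_constant_response_flagged(self, ref_params):
        df = rp.generate_population(ref_params, 200, seed=6).data
        df["survived"] = 1.0
        df["size_t1"] = df["size_t1"].fillna(df["size_t"])
        table = rp.select_by_aic(rp.RametDataset(df), "survival")
        assert table.selected is None
        assert all(c["error"] is not None for c in table.candidates)

    def test_linear_beats_intercept_under_true_slope(self, big_dataset):
        table = rp.select_by_aic(big_dataset, "flowering")
        aics = {c["formula"]: c["aic"] for c in table.candidates}
        assert aics["linear"] <= aics["intercept"]


class TestCoverage:
    """95% Wald intervals achieve nominal coverage over repeated simulation."""

    N = 1000
    REPS = 200

    def _coverage(self, simulate_and_fit, truth: dict):
        hits = {k: 0 for k in truth}
        ests = {k: [] for k in truth}
        rng = np.random.default_rng(123)
        for _ in range(self.REPS):
            fit = simulate_and_fit(rng)
            for k, v in truth.items():
                est, se = fit.coefficients[k], fit.standard_errors[k]
                ests[k].append(est)
                if abs(est - v) < 1.96 * se:
                    hits[k] += 1
        for k, v in truth.items():
            cov = hits[k] / self.REPS
            assert 0.90 <= cov <= 0.99, (k, cov)
            arr = np.asarray(ests[k])
            assert abs(arr.mean() - v) < 3 * arr.std() / np.sqrt(self.REPS), k

    def test_survival_coverage(self):
        truth = {"beta0_s": 2.790, "beta1_s": 0.731}

        def sim(rng):
            z = rng.uniform(*SIZE_RANGE, self.N)
            y = rng.binomial(1, expit(2.790 + 0.731 * z))
            est = SizeLogisticRegression().fit(z, y)
            return rp.VitalRateFit(
                "survival",
                dict(zip(truth, est.coef_)),
                dict(zip(truth, est.bse_)),
                est.llf_, est.aic_, est.n_,
            )

        self._coverage(sim, truth)

    def test_growth_coverage(self):
        truth = {
            "beta0_g": 0.016, "beta1_g": 0.898, "sigma0_g": 0.5, "betasigma_g": -0.175,
        }

        def sim(rng):
            z = rng.uniform(*SIZE_RANGE, self.N)
            y = rng.normal(0.016 + 0.898 * z, 0.5 * np.exp(-0.175 * z))
            est = GrowthRegression().fit(z, y)
            coefs = list(est.coef_) + [est.sigma0_, est.sigma_slope_]
            return rp.VitalRateFit(
                "growth", dict(zip(truth, coefs)), dict(zip(truth, est.bse_)),
                est.llf_, est.aic_, est.n_,
            )

        self._coverage(sim, truth)

    def test_flower_count_coverage(self):
        truth = {"beta0_rs": 1.664, "beta1_rs": 0.753}

        def sim(rng):
            z = rng.uniform(*SIZE_RANGE, self.N)
            mu = np.exp(1.664 + 0.753 * z)
            y = rng.negative_binomial(mu, 0.5)
            est = FlowerCountRegression().fit(z, y)
            return rp.VitalRateFit(
                "flower_count", dict(zip(truth, est.coef_)), dict(zip(truth, est.bse_)),
                est.llf_, est.aic_, est.n_, dispersion=est.dispersion_,
            )

        self._coverage(sim, truth)

    def test_recruit_size_coverage(self):
        truth = {"mu_rd": -3.103, "sigma_rd": 1.064}
        lo, hi = -6.84, 4.11
        a, b = (lo + 3.103) / 1.064, (hi + 3.103) / 1.064

        def sim(rng):
            x = stats.truncnorm.rvs(a, b, loc=-3.103, scale=1.064, size=self.N, random_state=rng)
            return rp.fit_recruit_size(x, (lo, hi))

        self._coverage(sim, truth)
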