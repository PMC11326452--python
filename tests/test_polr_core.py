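import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from polrboot.data_model import DesignMatrix, encode_design
from polrboot.polr_core import (
    FitResult,
    PolrParams,
    category_probabilities,
    empirical_cumulative_logits,
    fit_polr,
    intercept_only_nll,
    neg_log_likelihood,
    wald_table,
)
from tests.conftest import make_intercept_only_design


class TestCategoryProbabilities:
    def test_zero_slope_closed_form(self):
        # sigma(0) = 0.5, sigma(log 3) = 0.75 -> (0.5, 0.25, 0.25)
        params = PolrParams(np.array([0.0, np.log(3.0)]), np.zeros(2))
        p = category_probabilities(params, [0.0, 0.0])
        np.testing.assert_allclose(p, [0.5, 0.25, 0.25], atol=1e-4)

    def test_two_categories_reduce_to_binary_logistic(self):
        params = PolrParams(np.array([0.0]), np.array([1.0]))
        np.testing.assert_allclose(
            category_probabilities(params, [0.0]), [0.5, 0.5]
        )
        np.testing.assert_allclose(
            category_probabilities(params, [1.0]),
            [expit(-1.0), expit(1.0)],
        )

    @settings(derandomize=True, max_examples=100)
    @given(
        th1=st.floats(-5, 5),
        gap=st.floats(0.01, 5),
        beta=st.floats(-5, 5),
        x=st.floats(-3, 3),
    )
    def test_probabilities_sum_to_one(self, th1, gap, beta, x):
        params = PolrParams(np.array([th1, th1 + gap]), np.array([beta]))
        p = category_probabilities(params, [x])
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            PolrParams(np.array([1.0, 0.5]), np.zeros(1))


class TestNegLogLikelihood:
    def test_single_observation_closed_form(self):
        design = make_intercept_only_design([1, 0, 0])
        # category 1, theta_1 = 0 -> P = 0.5
        design.outcome_codes[:] = 1
        params = PolrParams(np.array([0.0, 1.0]), np.zeros(0))
        assert neg_log_likelihood(params, design) == pytest.approx(
            np.log(2), abs=1e-9
        )

    def test_additivity_over_identical_observations(self):
        d1 = make_intercept_only_design([0, 1, 0])
        d2 = make_intercept_only_design([0, 2, 0])
        params = PolrParams(np.array([-0.3, 0.9]), np.zeros(0))
        assert neg_log_likelihood(params, d2) == pytest.approx(
            2 * neg_log_likelihood(params, d1), rel=1e-14
        )

    def test_matches_brute_force_probability_product(self, toy_dataset):
        """NLL equals -log of the explicit product of per-record probabilities."""
        design = encode_design(toy_dataset)
        params = PolrParams(np.array([-0.4, 0.9]), np.array([0.7]))
        log_prod = 0.0
        for i in range(design.n_obs):
            p = category_probabilities(params, design.values[i])
            log_prod += np.log(p[design.outcome_codes[i] - 1])
        assert neg_log_likelihood(params, design) == pytest.approx(
            -log_prod, rel=1e-12
        )

    def test_extreme_tail_observation_stays_finite(self):
        """Deep-tail observations keep a finite NLL (log-space evaluation)."""
        design = make_intercept_only_design([1, 0, 0])
        params = PolrParams(np.array([-800.0, -700.0]), np.zeros(0))
        # P(Y=1) = sigma(-800) -> log P = -800 exactly to first order
        assert neg_log_likelihood(params, design) == pytest.approx(800.0)

    def test_zero_probability_returns_inf(self):
        design = make_intercept_only_design([1, 0, 0])
        params = PolrParams(np.array([-np.inf, 0.0]), np.zeros(0))
        assert neg_log_likelihood(params, design) == np.inf


class TestFitPolr:
    def test_intercept_only_reproduces_empirical_cumulative_logits(self):
        """Balanced counts (10,10,10) give cut-points (-log 2, +log 2) exactly."""
        design = make_intercept_only_design([10, 10, 10])
        fit = fit_polr(design)
        assert fit.converged
        np.testing.assert_allclose(
            fit.params.thresholds, [-np.log(2), np.log(2)], atol=1e-10
        )
        assert fit.neg_log_likelihood == pytest.approx(
            intercept_only_nll(design.outcome_codes, 3), abs=1e-10
        )

    def test_intercept_only_unbalanced(self):
        design = make_intercept_only_design([5, 12, 3])
        fit = fit_polr(design)
        expected = empirical_cumulative_logits(design.outcome_codes, 3)
        np.testing.assert_allclose(fit.params.thresholds, expected, atol=1e-8)

    def test_matches_exhaustive_grid_search(self, toy_dataset):
        """Optimum NLL agrees with a coarse-to-fine grid over (th1, gap, beta)."""
        design = encode_design(toy_dataset)
        fit = fit_polr(design)

        # grid NLL via the 2x3 contingency cells (x in {0,1} times category)
        counts = np.zeros((2, 3))
        for x, y in zip(design.values[:, 0].astype(int), design.outcome_codes):
            counts[x, y - 1] += 1

        def grid_nll(th1, gap, beta):
            th1, gap, beta = np.broadcast_arrays(th1, gap, beta)
            th2 = th1 + gap
            nll = np.zeros_like(th1, dtype=float)
            for x in (0, 1):
                c1 = expit(th1 - beta * x)
                c2 = expit(th2 - beta * x)
                probs = [c1, c2 - c1, 1 - c2]
                for j in range(3):
                    with np.errstate(divide="ignore"):
                        nll -= counts[x, j] * np.log(probs[j])
            return nll

        coarse = np.meshgrid(
            np.arange(-3, 1.5, 0.05),
            np.arange(0.05, 3, 0.05),
            np.arange(-1, 3.5, 0.05),
            indexing="ij",
        )
        vals = grid_nll(*coarse)
        best = np.unravel_index(np.argmin(vals), vals.shape)
        c = [g[best] for g in coarse]
        fine = np.meshgrid(
            c[0] + np.arange(-0.06, 0.06, 0.002),
            c[1] + np.arange(-0.06, 0.06, 0.002),
            c[2] + np.arange(-0.06, 0.06, 0.002),
            indexing="ij",
        )
        grid_min = float(np.min(grid_nll(*fine)))
        assert fit.neg_log_likelihood <= grid_min + 1e-9
        assert abs(fit.neg_log_likelihood - grid_min) < 1e-4

    def test_estimates_recover_truth_at_large_n(self):
        from polrboot.synthetic_data import make_toy_config, simulate_dataset

        config = make_toy_config(seed=11, n=5000)
        design = encode_design(simulate_dataset(config))
        fit = fit_polr(design)
        truth = config.true_params.as_vector()
        se = np.sqrt(np.diag(fit.covariance))
        assert np.all(np.abs(fit.params.as_vector() - truth) < 3 * se)

    def test_agrees_with_statsmodels(self, toy_dataset):
        """Independent cross-check: statsmodels' ordinal MLE on the same design."""
        import warnings

        from statsmodels.miscmodels.ordinal_model import OrderedModel

        design = encode_design(toy_dataset)
        fit = fit_polr(design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = OrderedModel(
                pd.Series(design.outcome_codes), design.values, distr="logit"
            ).fit(method="bfgs", maxiter=500, disp=0)
        sm_beta = sm_fit.params[: design.k]
        sm_theta = OrderedModel(
            pd.Series(design.outcome_codes), design.values, distr="logit"
        ).transform_threshold_params(sm_fit.params)[1:-1]
        np.testing.assert_allclose(fit.params.slopes, sm_beta, atol=1e-4)
        np.testing.assert_allclose(fit.params.thresholds, sm_theta, atol=1e-4)
        assert fit.neg_log_likelihood == pytest.approx(-sm_fit.llf, abs=1e-6)

    def test_nll_at_optimum_not_worse_than_initialization(self, toy_dataset):
        design = encode_design(toy_dataset)
        fit = fit_polr(design)
        init = PolrParams(
            empirical_cumulative_logits(design.outcome_codes, 3),
            np.zeros(design.k),
        )
        assert fit.neg_log_likelihood <= neg_log_likelihood(init, design) + 1e-12
        assert np.all(np.diff(fit.params.thresholds) > 0)

    def test_missing_outcome_category_rejected(self):
        design = make_intercept_only_design([5, 0, 5])
        with pytest.raises(ValueError, match="observed"):
            fit_polr(design)


class TestWaldTable:
    def _stub_fit(self, estimates, variances, labels):
        n_th = 2
        return FitResult(
            params=PolrParams(estimates[:n_th], estimates[n_th:]),
            neg_log_likelihood=1.0,
            covariance=np.diag(variances),
            converged=True,
            n_obs=30,
            n_params=len(estimates),
            term_labels=labels,
        )

    def test_zero_estimate_gives_unit_or_and_p_one(self):
        fit = self._stub_fit(
            np.array([-1.0, 1.0, 0.0]),
            np.array([0.25, 0.25, 4.0]),
            ["low|mid", "mid|high", "x=b"],
        )
        row = wald_table(fit).row("x=b")
        assert row["odds_ratio"] == 1.0
        assert row["z_value"] == 0.0
        assert row["p_value"] == 1.0

    def test_or_and_z_identities_hold_for_every_row(self, toy_dataset):
        fit = fit_polr(encode_design(toy_dataset))
        table = wald_table(fit).frame
        np.testing.assert_allclose(
            table["odds_ratio"], np.exp(table["estimate"]), rtol=1e-12
        )
        ok = table["std_error"] > 0
        np.testing.assert_allclose(
            table.loc[ok, "z_value"],
            table.loc[ok, "estimate"] / table.loc[ok, "std_error"],
            rtol=1e-12,
        )

    def test_threshold_rows_labelled_low_mid_style(self, toy_dataset):
        fit = fit_polr(encode_design(toy_dataset))
        terms = list(wald_table(fit).frame["term"])
        assert terms[-2:] == ["low|mid", "mid|high"]

    def test_non_converged_fit_refused(self):
        fit = self._stub_fit(
            np.array([-1.0, 1.0, 0.0]), np.ones(3), ["a|b", "b|c", "x"]
        )
        fit.converged = False
        with pytest.raises(RuntimeError, match="diagnostics"):
            wald_table(fit)

    def test_presentation_columns(self, toy_dataset):
        fit = fit_polr(encode_design(toy_dataset))
        frame = wald_table(fit).to_frame()
        assert list(frame.columns) == [
            "Variable",
            "Estimate",
            "Standard error",
            "z-value",
            "Significance",
            "Exp (B)",
        ]
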