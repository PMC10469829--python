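"""IRLS logistic fitting, weighting modes, jackknife, and summaries."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from svybias import (
    ModelSpec,
    compare_aic,
    fit_logit,
    jackknife_cluster_covariance,
    summarize_fit,
)
from svybias.logit import NotConvergedError, SingularDesignError


def _records(y, weights=None, exposure=None, cluster=None, stratum=None):
    n = len(y)
    return pd.DataFrame(
        {
            "y": y,
            "weight": weights if weights is not None else np.ones(n),
            "exposed": exposure if exposure is not None else ["no"] * n,
            "cluster_id": cluster if cluster is not None else np.zeros(n, int),
            "stratum": stratum if stratum is not None else ["rural"] * n,
        }
    )


def _grid_search_2d(y, x, span=3.0, steps=241):
    """Brute-force maximizer of the Bernoulli likelihood over (b0, b1)."""
    grid = np.linspace(-span, span, steps)
    best, arg = -np.inf, (None, None)
    for b0 in grid:
        eta = b0 + np.outer(grid, x)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = (y * np.log(mu) + (1 - y) * np.log(1 - mu)).sum(axis=1)
        k = int(np.argmax(ll))
        if ll[k] > best:
            best, arg = ll[k], (b0, grid[k])
    return arg


class TestClosedForms:
    def test_intercept_only_is_logit_of_sample_proportion(self):
        data = _records([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        fit = fit_logit(data, ModelSpec())
        assert fit.converged
        assert fit.params["intercept"] == pytest.approx(math.log(3 / 7), abs=1e-8)

    def test_saturated_two_by_two_matches_odds_ratio_and_grid_search(self):
        # exposed: 2/10 events, unexposed: 1/10
        y = np.r_[np.ones(2), np.zeros(8), np.ones(1), np.zeros(9)]
        x = np.r_[np.ones(10), np.zeros(10)]
        data = _records(y, exposure=np.where(x == 1, "yes", "no"))
        fit = fit_logit(data, ModelSpec(covariates={"exposed": ("no", "yes")}))
        expected = math.log((2 * 9) / (8 * 1))
        assert fit.params["exposed=yes"] == pytest.approx(expected, abs=1e-6)
        # independent oracle: 2-D likelihood grid search
        b0, b1 = _grid_search_2d(y, x)
        assert fit.params["intercept"] == pytest.approx(b0, abs=0.05)
        assert fit.params["exposed=yes"] == pytest.approx(b1, abs=0.05)

    def test_weighted_intercept_is_logit_of_weighted_proportion(self):
        data = _records([1, 0], weights=[3.0, 1.0])
        fit = fit_logit(data, ModelSpec(weighting="pseudo_likelihood"))
        assert fit.params["intercept"] == pytest.approx(math.log(3.0), abs=1e-8)


class TestLikelihoodProperties:
    def test_score_equation_identity(self, small_survey, default_spec):
        _, sample, _ = small_survey
        fit = fit_logit(sample, default_spec)
        assert abs(fit.fitted.sum() - sample["y"].sum()) < 1e-8
        assert fit.fitted.mean() == pytest.approx(sample["y"].mean(), abs=1e-8)

    def test_integer_weights_equal_replicated_records(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 30)
        x = rng.choice(["no", "yes"], 30)
        w = rng.integers(1, 5, 30)
        data = _records(y, weights=w.astype(float), exposure=x)
        rep = data.loc[data.index.repeat(w)].assign(weight=1.0)
        spec = ModelSpec(covariates={"exposed": ("no", "yes")})
        weighted = fit_logit(data, dataclasses.replace(spec, weighting="pseudo_likelihood"))
        replicated = fit_logit(rep, spec)
        assert np.allclose(
            weighted.params.to_numpy(), replicated.params.to_numpy(), atol=1e-6
        )

    def test_weight_scale_invariance(self, small_survey, weighted_spec):
        _, sample, _ = small_survey
        a = fit_logit(sample, weighted_spec)
        scaled = sample.assign(weight=sample["weight"] * 17.3)
        b = fit_logit(scaled, weighted_spec)
        assert np.allclose(a.params.to_numpy(), b.params.to_numpy(), atol=1e-8)

    def test_unit_weights_collapse_all_modes(self, small_survey, default_spec):
        _, sample, _ = small_survey
        unit = sample.assign(weight=1.0)
        fits = [
            fit_logit(unit, dataclasses.replace(default_spec, weighting=mode))
            for mode in ("unweighted", "pseudo_likelihood", "eq7_literal")
        ]
        for other in fits[1:]:
            assert np.allclose(
                fits[0].params.to_numpy(), other.params.to_numpy(), atol=1e-8
            )


class TestAgainstStatsmodels:
    """statsmodels GLM is the independent oracle, never the implementation."""

    def test_unweighted_coefficients_and_covariance(self, small_survey, default_spec):
        _, sample, _ = small_survey
        fit = fit_logit(sample, default_spec)
        X = sm.add_constant(
            np.column_stack(
                [
                    (sample["sex"] == "female").astype(float),
                    (sample["residence"] == "rural").astype(float),
                ]
            )
        )
        ref = sm.GLM(sample["y"].to_numpy(), X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
        assert np.allclose(
            fit.cov_params.to_numpy(), ref.cov_params(), rtol=1e-4, atol=1e-8
        )
        assert fit.aic == pytest.approx(ref.aic, rel=1e-8)

    def test_pseudo_likelihood_matches_frequency_weights(
        self, small_survey, weighted_spec
    ):
        _, sample, _ = small_survey
        fit = fit_logit(sample, weighted_spec)
        X = sm.add_constant(
            np.column_stack(
                [
                    (sample["sex"] == "female").astype(float),
                    (sample["residence"] == "rural").astype(float),
                ]
            )
        )
        ref = sm.GLM(
            sample["y"].to_numpy(),
            X,
            family=sm.families.Binomial(),
            freq_weights=sample["weight"].to_numpy(),
        ).fit()
        assert np.allclose(fit.params.to_numpy(), ref.params, atol=1e-6)

    def test_predictor_scaled_mode_matches_transformed_design(
        self, small_survey
    ):
        _, sample, _ = small_survey
        spec = ModelSpec(covariates={"sex": ("male", "female")}, weighting="eq7_literal")
        fit = fit_logit(sample, spec)
        w = sample["weight"].to_numpy()
        X = np.column_stack([np.ones(len(sample)), (sample["sex"] == "female") * w])
        ref = sm.GLM(sample["y"].to_numpy(), X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.params.to_numpy(), ref.params, atol=1e-6)


class TestJackknife:
    def test_identical_clusters_give_zero_spread(self):
        block = pd.DataFrame(
            {
                "y": [1, 0, 1, 0, 0, 0],
                "weight": 1.0,
                "exposed": ["yes", "yes", "no", "no", "yes", "no"],
                "stratum": "rural",
            }
        )
        data = pd.concat(
            [block.assign(cluster_id=k) for k in range(4)], ignore_index=True
        )
        spec = ModelSpec(covariates={"exposed": ("no", "yes")})
        fit = fit_logit(data, spec)
        cov = jackknife_cluster_covariance(data, spec, fit)
        assert np.allclose(cov.to_numpy(), 0.0, atol=1e-10)

    def test_two_cluster_hand_formula(self):
        rng = np.random.default_rng(8)
        data = _records(
            rng.integers(0, 2, 40),
            exposure=rng.choice(["no", "yes"], 40),
            cluster=np.repeat([0, 1], 20),
        )
        spec = ModelSpec(covariates={"exposed": ("no", "yes")})
        fit = fit_logit(data, spec)
        cov = jackknife_cluster_covariance(data, spec, fit)
        # oracle: two direct delete-one refits, weights rescaled by K/(K-1)=2
        expected = np.zeros((2, 2))
        for drop in (0, 1):
            keep = data[data["cluster_id"] != drop].assign(weight=2.0)
            b = fit_logit(
                keep, dataclasses.replace(spec, weighting="pseudo_likelihood")
            ).params.to_numpy()
            d = b - fit.params.to_numpy()
            expected += np.outer(d, d)
        expected *= 1 / 2
        assert np.allclose(cov.to_numpy(), expected, atol=1e-6)

    def test_single_cluster_stratum_rejected(self):
        data = _records(
            [1, 0, 1, 0],
            cluster=[0, 0, 1, 1],
            stratum=["rural", "rural", "urban", "urban"],
        )
        spec = ModelSpec()
        fit = fit_logit(data, spec)
        with pytest.raises(ValueError, match="collapse"):
            jackknife_cluster_covariance(data, spec, fit)


class TestSummaries:
    def test_unit_odds_ratio_at_zero_coefficient(self):
        data = _records([1, 1, 0, 0])
        summary = summarize_fit(fit_logit(data, ModelSpec()))
        row = summary.table.iloc[0]
        assert row["estimate"] == pytest.approx(0.0, abs=1e-8)
        assert row["aOR"] == pytest.approx(1.0, abs=1e-8)

    def test_intercept_only_aic_closed_form(self):
        data = _records([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        summary = summarize_fit(fit_logit(data, ModelSpec()))
        expected = 2 * 1 - 2 * (3 * math.log(0.3) + 7 * math.log(0.7))
        assert summary.aic == pytest.approx(expected, abs=1e-6)

    def test_weighted_mode_reports_no_aic(self, small_survey, weighted_spec):
        _, sample, _ = small_survey
        assert summarize_fit(fit_logit(sample, weighted_spec)).aic is None

    def test_aic_comparison_flags_smaller(self, small_survey, default_spec):
        _, sample, _ = small_survey
        full = fit_logit(sample, default_spec)
        reduced = fit_logit(sample, ModelSpec(covariates={"sex": ("male", "female")}))
        table = compare_aic(full=full, reduced=reduced)
        assert table["preferred"].sum() == 1
        best = table.loc[table["preferred"], "aic"].iloc[0]
        assert best == table["aic"].min()

    def test_jackknife_switches_reference_to_t(self, small_survey, weighted_spec):
        _, sample, _ = small_survey
        fit = fit_logit(sample, weighted_spec)
        assert summarize_fit(fit).reference == "normal"
        jackknife_cluster_covariance(sample, weighted_spec, fit)
        summary = summarize_fit(fit)
        assert summary.reference.startswith("t(")
        assert fit.jackknife_df == len(sample["cluster_id"].unique()) - 2


class TestValidation:
    def test_non_binary_outcome_rejected(self):
        data = _records([1, 0, 2])
        with pytest.raises(ValueError, match="binary"):
            fit_logit(data, ModelSpec())

    def test_missing_weight_column_rejected_for_weighted_modes(self):
        data = _records([1, 0, 1]).drop(columns="weight")
        with pytest.raises(ValueError, match="weight"):
            fit_logit(data, ModelSpec(weighting="pseudo_likelihood"))

    def test_collinear_design_named(self):
        data = _records([1, 0, 1, 0], exposure=["yes", "yes", "no", "no"])
        data["copy"] = data["exposed"]
        spec = ModelSpec(
            covariates={"exposed": ("no", "yes"), "copy": ("no", "yes")}
        )
        with pytest.raises(SingularDesignError, match="collinear"):
            fit_logit(data, spec)

    def test_absent_level_rejected(self):
        data = _records([1, 0, 1, 0], exposure=["no"] * 4)
        with pytest.raises(ValueError, match="absent"):
            fit_logit(data, ModelSpec(covariates={"exposed": ("no", "yes")}))

    def test_separation_flagged(self):
        data = _records([1, 1, 1, 0, 0, 0],
                        exposure=["yes", "yes", "yes", "no", "no", "no"])
        fit = fit_logit(data, ModelSpec(covariates={"exposed": ("no", "yes")}))
        assert fit.diagnostics.get("separation_suspected", False)

    def test_summary_refuses_nonconverged(self, small_survey, default_spec):
        _, sample, _ = small_survey
        fit = fit_logit(sample, default_spec)
        fit.converged = False
        with pytest.raises(NotConvergedError):
            summarize_fit(fit)
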