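"""Hierarchical EM, Laplace evidence, iBIC, and cross-validation machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foragefit.fitting import (
    FitResult,
    assign_folds,
    compare_models,
    crossval_cross_task,
    em_fit,
    fit_subject_mle,
    ibic,
    laplace_log_marginal,
    parameter_transform,
)
from foragefit.synthetic import CohortSpec, simulate_foraging
from foragefit.valuation import FREE_PARAMS


class TestParameterTransform:
    @pytest.mark.parametrize("variant", list(FREE_PARAMS))
    def test_round_trip_identity(self, variant):
        tf = parameter_transform(variant)
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(0, 2, tf.dim)
            x2 = tf.to_unconstrained(tf.to_natural(x))
            np.testing.assert_allclose(x2, x, atol=1e-10)

    def test_quasi_ordering_enforced(self):
        tf = parameter_transform("disc_quasi")
        for _ in range(50):
            params = tf.to_natural(np.random.default_rng(1).normal(0, 3, 4))
            assert params["beta"] > params["delta"] > 0
            assert 0 < params["omega"] < 1

    def test_parameter_counts_per_model(self):
        # every model has two subject-level parameters (including the noise
        # sigma) except constant-sensitivity (3) and quasi-hyperbolic (4)
        expected = {v: 2 for v in FREE_PARAMS}
        expected["disc_cs"], expected["disc_quasi"], expected["mvt"] = 3, 4, 1
        for variant, d in expected.items():
            assert parameter_transform(variant).dim == d

    def test_bounded_transforms(self):
        tf = parameter_transform("pre_del")
        assert tf.to_natural([-20.0, 0.0])["alpha"] > 1
        tf = parameter_transform("post_del")
        a = tf.to_natural([2.0, 0.0])["alpha"]
        assert 0 < a < 1


def _gaussian_toy_fit(y, obs_sd, prior_mean, prior_var):
    """Exact conjugate scenario: y_i ~ N(theta, obs_sd^2), theta ~ N(m, v)."""
    n = len(y)
    prec = n / obs_sd**2 + 1 / prior_var
    post_mean = (y.sum() / obs_sd**2 + prior_mean / prior_var) / prec
    ll = float(
        -0.5 * n * math.log(2 * math.pi * obs_sd**2)
        - 0.5 * np.sum((y - post_mean) ** 2) / obs_sd**2
    )
    return FitResult(
        variant="disc_exp",
        task="foraging",
        horizon="all_future",
        param_names=("theta",),
        group_mean=np.array([prior_mean]),
        group_var=np.array([prior_var]),
        subject_ids=["s1"],
        subject_params=np.array([[post_mean]]),
        subject_params_natural=[{"theta": post_mean}],
        hessians=np.array([[[prec]]]),
        subject_loglik=np.array([ll]),
        n_obs=n,
        n_subjects=1,
        converged=True,
    )


class TestEvidence:
    def test_laplace_exact_for_gaussian_model(self):
        rng = np.random.default_rng(0)
        y = rng.normal(1.3, 0.7, size=40)
        obs_sd, m, v = 0.7, 0.0, 2.0
        fit = _gaussian_toy_fit(y, obs_sd, m, v)
        approx = laplace_log_marginal(fit)
        # closed-form marginal: y ~ N(m 1, obs_sd^2 I + v 11^T)
        n = len(y)
        cov = obs_sd**2 * np.eye(n) + v * np.ones((n, n))
        diff = y - m
        sign, logdet = np.linalg.slogdet(cov)
        exact = float(
            -0.5 * (n * math.log(2 * math.pi) + logdet + diff @ np.linalg.solve(cov, diff))
        )
        assert approx == pytest.approx(exact, abs=1e-6)

    def test_laplace_additivity_under_duplication(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0.5, 1.0, size=25)
        fit1 = _gaussian_toy_fit(y, 1.0, 0.0, 1.5)
        one = laplace_log_marginal(fit1)
        fit2 = _gaussian_toy_fit(y, 1.0, 0.0, 1.5)
        for attr in ("subject_params", "hessians", "subject_loglik"):
            setattr(fit2, attr, np.concatenate([getattr(fit2, attr)] * 2))
        fit2.subject_ids = ["s1", "s2"]
        fit2.n_subjects = 2
        fit2.n_obs = 2 * fit1.n_obs
        assert laplace_log_marginal(fit2) == pytest.approx(2 * one, rel=1e-12)

    def test_ibic_penalty_arithmetic(self):
        fit = _gaussian_toy_fit(np.array([0.1, -0.2, 0.3]), 1.0, 0.0, 1.0)
        lm = laplace_log_marginal(fit)
        # k = 2 group parameters (one mean + one variance), n = 100
        val = ibic(fit, n=100)
        assert val == pytest.approx(-lm + 0.5 * 2 * math.log(100))
        assert 0.5 * 2 * math.log(100) == pytest.approx(4.6052, abs=1e-4)
        # one extra subject-level parameter costs (2/2) log n more penalty
        fit.param_names = ("theta", "unused")
        assert ibic(fit, n=100) - val == pytest.approx(math.log(100))

    def test_ibic_requires_observations(self):
        fit = _gaussian_toy_fit(np.array([0.0]), 1.0, 0.0, 1.0)
        laplace_log_marginal(fit)
        with pytest.raises(ValueError):
            ibic(fit, n=0)

    def test_ranking_invariant_to_criterion_scaling(self):
        rng = np.random.default_rng(2)
        fits = [
            _gaussian_toy_fit(rng.normal(0, s, 30), s, 0.0, 1.0) for s in (0.5, 1.0, 2.0)
        ]
        vals = np.array([ibic(f, n=30) for f in fits])
        assert list(np.argsort(vals)) == list(np.argsort(2 * vals))
        assert list(np.argsort(vals)) == list(np.argsort(-(-vals)))


class TestEMFit:
    def test_flat_prior_single_subject_matches_mle(self, small_foraging_cohort):
        ds = small_foraging_cohort[0]
        fit = em_fit([ds], "disc_exp", seed=0, prior_disabled=True, max_iter=3, n_starts=3)
        mle = fit_subject_mle(ds, "disc_exp", seed=0, n_starts=3)
        assert fit.subject_params_natural[0]["beta"] == pytest.approx(
            mle["beta"], rel=0.05
        )
        assert -fit.subject_loglik[0] == pytest.approx(mle["_nll"], abs=0.5)

    def test_duplicated_subject_leaves_group_mean_unchanged(self, small_foraging_cohort):
        ds = small_foraging_cohort[1]
        fit2 = em_fit([ds, ds], "disc_exp", seed=0, max_iter=8, n_starts=2)
        fit4 = em_fit([ds, ds, ds, ds], "disc_exp", seed=0, max_iter=8, n_starts=2)
        np.testing.assert_allclose(fit2.group_mean, fit4.group_mean, atol=0.05)

    def test_small_cohort_recovery_is_sane(self):
        gm = {"beta": 0.2, "sigma": 0.15}
        cohort = simulate_foraging(
            CohortSpec(task="foraging", experiment="scale", n_rats=4,
                       patches_per_condition=80, variant="disc_exp",
                       group_means=gm, seed=3)
        )
        fit = em_fit(cohort, "disc_exp", seed=0, n_starts=3, max_iter=15)
        nat = fit.group_mean_natural()
        assert 0.1 < nat["beta"] < 0.4
        assert 0.08 < nat["sigma"] < 0.3
        assert fit.n_obs == 4 * 160
        assert fit.n_group_params == 4

    def test_requires_two_subjects(self, small_foraging_cohort):
        with pytest.raises(ValueError):
            em_fit([small_foraging_cohort[0]], "disc_exp")

    def test_compare_models_identical_specs_tie(self, small_foraging_cohort):
        cohort = small_foraging_cohort[:2]
        df = compare_models(
            {"travel_time": cohort}, ["disc_exp", "disc_exp"], seed=0,
            n_starts=2, max_iter=6,
        )
        sub = df[df.experiment == "travel_time"]["ibic"].to_numpy()
        assert sub[0] == pytest.approx(sub[1], rel=1e-6)


class TestCrossValidation:
    def test_fold_assignment_balanced_disjoint(self, small_foraging_cohort):
        ds = small_foraging_cohort[0]
        folds = assign_folds(ds, 3)
        sizes = folds.value_counts()
        assert len(sizes) == 3 and sizes.max() - sizes.min() <= 2
        assert folds.index.equals(ds.observations.index)

    def test_single_fold_rejected(self, small_foraging_cohort):
        with pytest.raises(ValueError):
            assign_folds(small_foraging_cohort[0], 1)

    def test_cross_task_matched_parameters_favor_foraging_fit(
        self, small_foraging_cohort, small_itc_cohort
    ):
        # data generated with one shared discount function per rat: the
        # foraging-fit parameters should explain held-out foraging data
        # better than ITC-fit parameters (positive difference)
        res = crossval_cross_task(small_foraging_cohort[0], small_itc_cohort[0], seed=0)
        assert res["nll_diff_foraging"] > 0
        assert np.isfinite(res["nll_diff_itc"])

    def test_mismatched_rats_rejected(self, small_foraging_cohort, small_itc_cohort):
        with pytest.raises(ValueError):
            crossval_cross_task(
                small_foraging_cohort[0], small_itc_cohort[1], seed=0
            )

    def test_sigma_only_refit_respects_fixed_discounts(self, small_itc_cohort):
        ds = small_itc_cohort[0]
        fixed = {"delta": 0.004, "beta": 0.4, "omega": 0.35}
        out = fit_subject_mle(ds, "disc_quasi", fixed=fixed, seed=0, n_starts=2)
        for k, v in fixed.items():
            assert out[k] == pytest.approx(v)
        assert out["sigma"] > 0
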