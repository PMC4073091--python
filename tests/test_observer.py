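"""Bayesian observer likelihood, fitting, BIC selection, bootstrap, flatness."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import optimize

import selfprior as sp
from selfprior.errors import ConfigError, FitError, InputError
from selfprior.observer import (
    MODEL_PRESETS,
    _Design,
    bootstrap_cis,
    classify_flat,
    compare_models,
    compute_bic,
    count_free_params,
    data_levels,
    fit_model,
    get_model_spec,
    neg_log_likelihood,
    posterior_weight,
    predict_estimate,
)
from conftest import make_two_condition_dataset


# ---------------------------------------------------------------------------
# posterior weight and predicted report


class TestPosteriorWeight:
    @pytest.mark.parametrize(
        "prior_sd,evidence_sd,expected",
        [(1.0, 1.0, 0.5), (1.0, 2.0, 0.8), (2.0, 1.0, 0.2)],
    )
    def test_known_values(self, prior_sd, evidence_sd, expected):
        assert posterior_weight(prior_sd, evidence_sd) == pytest.approx(expected)

    def test_flat_prior_limit(self):
        assert posterior_weight(1e8, 1.0) < 1e-15

    def test_non_positive_sd_rejected(self):
        with pytest.raises(ValueError):
            posterior_weight(0.0, 1.0)
        with pytest.raises(ValueError):
            posterior_weight(1.0, -1.0)

    @given(
        sp_=st.floats(0.01, 1e6), se=st.floats(0.01, 1e6), factor=st.floats(1.001, 10.0)
    )
    def test_monotonicity_and_range(self, sp_, se, factor):
        w = posterior_weight(sp_, se)
        assert 0.0 < w < 1.0
        assert posterior_weight(sp_ * factor, se) < w  # wider prior -> less weight
        assert posterior_weight(sp_, se * factor) > w  # noisier evidence -> more weight


class TestPredictEstimate:
    def test_prior_dominates_in_tight_prior_limit(self):
        params = sp.ObserverParams(prior_sd_px=1e-6, evidence_sd_px=50.0,
                                   prior_mean_px=500.0)
        mean, _ = predict_estimate(params, true_stop=800.0)
        assert mean == pytest.approx(500.0, abs=1e-3)

    def test_evidence_dominates_in_flat_prior_limit(self):
        params = sp.ObserverParams(prior_sd_px=1e9, evidence_sd_px=20.0,
                                   prior_mean_px=500.0)
        mean, sd = predict_estimate(params, true_stop=800.0)
        assert mean == pytest.approx(800.0, abs=1e-3)
        assert sd == pytest.approx(20.0, rel=1e-6)

    def test_matches_gridded_posterior_argmax(self):
        # dense-grid Gaussian prior x likelihood posterior maximum oracle
        rng = np.random.default_rng(0)
        step = 0.01
        for _ in range(100):
            sp_sd = rng.uniform(5, 200)
            se_sd = rng.uniform(5, 200)
            prior_mean = rng.uniform(300, 700)
            truth = rng.uniform(300, 700)
            shift_p = rng.uniform(-20, 20)
            shift_e = rng.uniform(-20, 20)
            direction = rng.choice([-1, 1])
            params = sp.ObserverParams(
                prior_sd_px=sp_sd, evidence_sd_px=se_sd, prior_mean_px=prior_mean,
                prior_shift_px=shift_p, evidence_shift_px=shift_e,
            )
            mean, _ = predict_estimate(params, truth, direction)
            a = prior_mean + shift_p
            b = truth + direction * shift_e
            grid = np.arange(min(a, b) - 3 * max(sp_sd, se_sd),
                             max(a, b) + 3 * max(sp_sd, se_sd), step)
            log_post = -((grid - a) ** 2) / (2 * sp_sd**2) - ((grid - b) ** 2) / (2 * se_sd**2)
            assert mean == pytest.approx(grid[np.argmax(log_post)], abs=step)


# ---------------------------------------------------------------------------
# likelihood


def _one_trial(estimate, truth=500.0, target=500.0):
    return pd.DataFrame(
        {
            "condition": ["self"],
            "direction": [1],
            "feedback_level": ["none"],
            "target_x_px": [target],
            "true_stop_x_px": [truth],
            "estimate_x_px": [estimate],
        }
    )


class TestNegLogLikelihood:
    def test_standard_normal_at_mode(self):
        # predicted sd 1 requires (1-w)*sigma_e = 1; pick w=0.5, sigma_e=2
        params = {"prior_sd[self]": 2.0, "evidence_sd[self]": 2.0}
        nll = neg_log_likelihood(params, "exp1_full", _one_trial(estimate=500.0))
        assert nll == pytest.approx(0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_additivity_over_concatenation(self, two_condition_dataset):
        params = {
            "prior_sd[self]": 30.0, "prior_sd[agent]": 40.0,
            "evidence_sd[self]": 25.0, "evidence_sd[agent]": 30.0,
        }
        a = two_condition_dataset.iloc[:150]
        b = two_condition_dataset.iloc[150:]
        nll_all = neg_log_likelihood(params, "exp1_full", two_condition_dataset)
        nll_sum = neg_log_likelihood(params, "exp1_full", a) + neg_log_likelihood(
            params, "exp1_full", b
        )
        assert nll_all == pytest.approx(nll_sum, abs=1e-8)

    def test_generative_parameters_beat_perturbed(self):
        df = make_two_condition_dataset(n_per_condition=5000, seed=1)
        gen = {
            "prior_sd[self]": 24.0, "prior_sd[agent]": 40.0,
            "evidence_sd[self]": 25.0, "evidence_sd[agent]": 30.0,
        }
        worse = dict(gen, **{"prior_sd[self]": 48.0})
        assert neg_log_likelihood(gen, "exp1_full", df) < neg_log_likelihood(
            worse, "exp1_full", df
        )

    def test_analytic_gradient_matches_finite_differences(self, two_condition_dataset):
        design = _Design(get_model_spec("exp2_full_shift"), two_condition_dataset)
        theta = np.concatenate(
            [np.log([30.0, 40.0]), np.log([25.0, 28.0]), [5.0, -3.0], [2.0, 1.0]]
        )
        _, grad = design.nll_grad(theta)
        num = optimize.approx_fprime(theta, lambda t: design.nll_grad(t)[0], 1e-6)
        np.testing.assert_allclose(grad, num, rtol=1e-4, atol=1e-3)


# ---------------------------------------------------------------------------
# parameter counting and BIC


EXP1_LEVELS = {"condition": ["self", "agent"], "direction": [1], "feedback_level": ["none"]}
EXP2_LEVELS = {"condition": ["self", "agent"], "direction": [-1, 1], "feedback_level": ["none"]}


class TestFreeParamCounts:
    @pytest.mark.parametrize(
        "preset,levels,expected",
        [
            ("exp1_full", EXP1_LEVELS, 4),
            ("exp1_shared_evidence", EXP1_LEVELS, 3),
            ("exp1_shared_prior", EXP1_LEVELS, 3),
            ("exp2_full_shift", EXP2_LEVELS, 10),
            ("exp2_shared_evidence_direction", EXP2_LEVELS, 8),
        ],
    )
    def test_presets_reproduce_published_counts(self, preset, levels, expected):
        assert count_free_params(preset, levels) == expected

    def test_single_condition_collapses(self):
        levels = {"condition": ["self"], "direction": [1], "feedback_level": ["none"]}
        assert count_free_params("exp1_full", levels) == 2

    def test_missing_factor_rejected(self):
        with pytest.raises(ConfigError):
            count_free_params("exp1_full", {"condition": ["self"]})

    def test_fit_k_matches_count(self, two_condition_dataset):
        fit = fit_model(two_condition_dataset, "exp1_full", n_restarts=2)
        assert fit.k == count_free_params("exp1_full", data_levels(two_condition_dataset))


class TestBic:
    def test_known_values(self):
        assert compute_bic(0.0, 0, 1) == 0.0
        assert compute_bic(50.0, 4, 100) == pytest.approx(4 * math.log(100) + 100)
        assert compute_bic(50.0, 4, 100) == pytest.approx(118.42068, abs=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_bic(1.0, 1, 0)
        with pytest.raises(ValueError):
            compute_bic(1.0, -1, 10)

    def test_fit_result_bic_identity(self, two_condition_dataset):
        fit = fit_model(two_condition_dataset, "exp1_full", n_restarts=2)
        assert fit.bic == pytest.approx(
            fit.k * math.log(fit.n_trials) + 2 * fit.neg_log_lik, abs=1e-10
        )


# ---------------------------------------------------------------------------
# fitting


class TestFitModel:
    def test_recovers_equal_variance_weighting(self):
        df = make_two_condition_dataset(
            n_per_condition=2000, self_prior=30.0, self_evid=30.0,
            agent_prior=30.0, agent_evid=30.0, perf_sd=30.0, seed=2,
        )
        fit = fit_model(df, "exp1_full", random_state=0)
        assert fit.weight("self") == pytest.approx(0.5, abs=0.05)

    def test_flat_generative_prior_exceeds_threshold(self):
        df = make_two_condition_dataset(
            n_per_condition=2000, agent_prior=1e9, seed=3
        )
        fit = fit_model(df, "exp1_full", random_state=0)
        assert fit.prior_sd("agent") > sp.FLAT_PRIOR_THRESHOLD
        assert classify_flat(fit) == {"self": False, "agent": True}

    def test_degenerate_zero_variance_data_raises(self):
        df = _one_trial(500.0)
        df = pd.concat([df] * 30, ignore_index=True)
        with pytest.raises(FitError):
            fit_model(df, "exp1_full")

    def test_too_few_trials_raise(self, two_condition_dataset):
        with pytest.raises(FitError):
            fit_model(two_condition_dataset.head(3), "exp1_full")

    def test_regression_and_ml_weighting_agree(self):
        from selfprior.prep import fit_error_regression

        df = make_two_condition_dataset(n_per_condition=2000, seed=4)
        self_df = df[df["condition"] == "self"]
        fit = fit_model(df, "exp1_full", random_state=1)
        reg = fit_error_regression(self_df)
        assert fit.weight("self") == pytest.approx(reg.weighting, abs=0.03)

    def test_nll_never_worse_with_extra_parameters(self, two_condition_dataset):
        full = fit_model(two_condition_dataset, "exp1_full", random_state=0)
        shared = fit_model(two_condition_dataset, "exp1_shared_evidence", random_state=0)
        assert full.neg_log_lik <= shared.neg_log_lik + 1e-4

    def test_log_sd_and_raw_sd_coordinates_agree(self, two_condition_dataset):
        # reparameterisation invariance: optimising over raw SDs (independent
        # route) reaches the same NLL optimum as the log-SD fit
        fit = fit_model(two_condition_dataset, "exp1_full", random_state=0)
        design = _Design(get_model_spec("exp1_full"), two_condition_dataset)

        def nll_raw(sds):
            return design.nll(np.log(sds), floor=1e-12)

        res = optimize.minimize(
            nll_raw, np.array([30.0, 30.0, 30.0, 30.0]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
        )
        assert fit.neg_log_lik == pytest.approx(res.fun, abs=1e-6)

    def test_shift_sign_recovered_in_bidirectional_task(self):
        import dataclasses
        from selfprior.pipeline import exp2_stop_task

        task = dataclasses.replace(exp2_stop_task(), trials_per_block=1000)
        correct = 0
        n_sim = 100
        for i in range(n_sim):
            p = sp.ObserverParams(
                prior_sd_px=40.0, evidence_sd_px=30.0, performance_sd_px=40.0,
                evidence_shift_px=15.0,
            )
            sb = sp.simulate_stop_block(task, p, "self", seed=9000 + i)
            ab = sp.simulate_agent_replay(sb, task, p, seed=19000 + i)
            df = pd.concat([sb, ab], ignore_index=True)
            fit = fit_model(df, "exp2_shared_evidence_direction",
                            n_restarts=2, random_state=i)
            correct += fit.shift_evidence("self") > 0
        assert correct >= 0.95 * n_sim

    def test_sklearn_interface_and_predict(self, two_condition_dataset):
        est = sp.BayesianObserver(model_spec="exp1_full", n_restarts=2, random_state=0)
        assert est.get_params()["model_spec"] == "exp1_full"
        est.set_params(n_restarts=3)
        est.fit(two_condition_dataset)
        assert est.n_restarts_used_ == 3
        pred = est.predict(two_condition_dataset.head(7))
        assert pred.shape == (7,)
        assert np.all(np.isfinite(pred))


# ---------------------------------------------------------------------------
# model comparison


def _dummy_fit(bic):
    return sp.FitResult(
        model="m", params={}, neg_log_lik=0.0, n_trials=10, k=1,
        bic=bic, converged=True, n_restarts_used=1,
    )


class TestCompareModels:
    def test_identical_fits_are_indistinguishable(self):
        fits = {"p0": {"a": _dummy_fit(100.0), "b": _dummy_fit(100.0)}}
        rep = compare_models(fits)
        pair = rep["pairwise"]["a vs b"]
        assert pair["mean_delta_bic"] == 0.0
        assert pair["verdict"] == "indistinguishable"

    @pytest.mark.parametrize("delta,strong", [(5.9, False), (6.0, True), (6.1, True)])
    def test_strong_evidence_threshold_inclusive_at_six(self, delta, strong):
        fits = {"p0": {"a": _dummy_fit(100.0), "b": _dummy_fit(100.0 + delta)}}
        rep = compare_models(fits)
        assert rep["pairwise"]["a vs b"]["strong_evidence"] is strong

    def test_ragged_inputs_rejected(self):
        fits = {"p0": {"a": _dummy_fit(1.0), "b": _dummy_fit(2.0)},
                "p1": {"a": _dummy_fit(1.0)}}
        with pytest.raises(InputError):
            compare_models(fits)

    def test_full_model_wins_when_conditions_separated(self):
        # well-separated condition SDs: the full model should win in the
        # majority of synthetic participants
        wins = 0
        for i in range(10):
            df = make_two_condition_dataset(
                n_per_condition=200, self_prior=24.0, self_evid=18.0,
                agent_prior=40.0, agent_evid=36.0, seed=500 + i,
            )
            f_full = fit_model(df, "exp1_full", n_restarts=3, random_state=i)
            f_sh = fit_model(df, "exp1_shared_evidence", n_restarts=3, random_state=i)
            wins += f_full.bic < f_sh.bic
        assert wins > 5


# ---------------------------------------------------------------------------
# bootstrap and flat classification


class TestBootstrap:
    def test_deterministic_given_seed(self):
        df = make_two_condition_dataset(n_per_condition=80, seed=6)
        a = bootstrap_cis(df, "exp1_full", B=20, seed=3, n_restarts=2)
        b = bootstrap_cis(df, "exp1_full", B=20, seed=3, n_restarts=2)
        assert a == b

    def test_intervals_contain_point_estimate(self):
        df = make_two_condition_dataset(n_per_condition=80, seed=7)
        fit = fit_model(df, "exp1_full", n_restarts=2, random_state=0)
        cis = bootstrap_cis(df, "exp1_full", B=30, seed=1, base_fit=fit)
        for label, (lo, hi) in cis.items():
            assert lo <= fit.params[label] <= hi

    def test_default_bootstrap_settings(self):
        import inspect

        sig = inspect.signature(bootstrap_cis)
        assert sig.parameters["B"].default == 5000
        assert sig.parameters["alpha"].default == 0.05

    def test_b_below_two_rejected(self, two_condition_dataset):
        with pytest.raises(ConfigError):
            bootstrap_cis(two_condition_dataset, "exp1_full", B=1)


class TestClassifyFlat:
    def test_threshold_is_strict(self):
        fit = _dummy_fit(0.0)
        fit.params = {"prior_sd[self]": 1e7}
        assert classify_flat(fit) == {"self": False}
        fit.params = {"prior_sd[self]": 1e9}
        assert classify_flat(fit) == {"self": True}

    def test_flat_flag_implies_negligible_weight(self):
        # evaluating the weighting formula at the threshold: (1e3/1e7)^2 = 1e-8,
        # so any flagged prior contributes essentially no bias
        w_at_threshold = posterior_weight(sp.FLAT_PRIOR_THRESHOLD, 1e3)
        assert w_at_threshold == pytest.approx(1e-8, rel=1e-6)
        assert w_at_threshold < 1e-7


# ---------------------------------------------------------------------------
# model spec plumbing


def test_presets_registry_complete():
    assert set(MODEL_PRESETS) == {
        "exp1_full", "exp1_shared_evidence", "exp1_shared_prior",
        "exp2_full_shift", "exp2_shared_evidence_direction",
    }
    with pytest.raises(ConfigError):
        get_model_spec("nope")


def test_model_spec_validation():
    with pytest.raises(ConfigError):
        sp.ModelSpec("bad", tie_evidence_across={"phase"})
    with pytest.raises(ConfigError):
        sp.ModelSpec("bad", fix_prior_mean_at_target=False, include_shifts=False)
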