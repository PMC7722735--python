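import numpy as np
import pandas as pd
import pytest

from bayescoin.observer_models import (
    fit_model,
    model_k_free,
    predict_fitted,
    predict_m1_senses,
    predict_m2_prior_mean,
    predict_m3_previous_coin,
    predict_m4_bayes_task_params,
    predict_m5_bayes_learned_prior,
    predict_m6_two_priors_global,
    predict_m7_two_priors_per_participant,
    predict_m8_stress_on_slope,
    predict_m9_stress_on_prior_var,
    predict_m10_stress_on_likelihood_var,
)
from bayescoin.synthetic_data import ObserverSpec, cohort_frame, simulate_cohort, simulate_observer
from bayescoin.task_model import ConditionParams


def _mini_frame(coins, centroids=None, prior="p", lik="l", group="control", pid="p0"):
    n = len(coins)
    if centroids is None:
        centroids = coins
    return pd.DataFrame(
        {
            "participant_id": pid,
            "group": group,
            "block": 1,
            "trial": np.arange(1, n + 1),
            "prior_level": prior,
            "likelihood_level": lik,
            "coin_x": coins,
            "centroid_x": centroids,
            "response_x": centroids,
            "hit": np.nan,
        }
    )


class TestHeuristicPredictions:
    def test_m1_is_centroid(self, noiseless_bayes_session):
        from bayescoin.synthetic_data import session_frame

        frame = session_frame(noiseless_bayes_session)
        assert np.array_equal(predict_m1_senses(frame), frame["centroid_x"].to_numpy())

    def test_m2_is_constant_half(self):
        frame = _mini_frame(np.array([0.2, 0.9, 0.4]))
        assert np.array_equal(predict_m2_prior_mean(frame), np.full(3, 0.5))

    def test_m3_lags_coin_with_prior_mean_start(self):
        frame = _mini_frame(np.array([0.5, 0.4, 0.7]))
        assert np.allclose(predict_m3_previous_coin(frame), [0.5, 0.5, 0.4])

    def test_m3_constant_coins(self):
        frame = _mini_frame(np.full(5, 0.37))
        assert np.allclose(predict_m3_previous_coin(frame)[1:], 0.37)

    def test_m3_is_per_participant(self):
        a = _mini_frame(np.array([0.1, 0.2]), pid="a")
        b = _mini_frame(np.array([0.8, 0.9]), pid="b")
        preds = predict_m3_previous_coin(pd.concat([a, b], ignore_index=True))
        assert np.allclose(preds, [0.5, 0.1, 0.5, 0.8])


class TestBayesPredictions:
    def test_m4_condition_examples(self):
        # pl trial, centroid 0.6: w = 0.000625/(0.000625 + 0.0036/5)
        frame = _mini_frame(np.array([0.5]), np.array([0.6]), prior="p", lik="l")
        w = 0.000625 / (0.000625 + 0.00072)
        assert predict_m4_bayes_task_params(frame)[0] == pytest.approx(0.5 + w * 0.1)
        frame = _mini_frame(np.array([0.5]), np.array([0.6]), prior="p", lik="L")
        assert predict_m4_bayes_task_params(frame)[0] == pytest.approx(0.5121951219512195)

    def test_m4_centred_centroid_is_prior_mean(self):
        for prior, lik in (("p", "l"), ("P", "L")):
            frame = _mini_frame(np.array([0.4]), np.array([0.5]), prior=prior, lik=lik)
            assert predict_m4_bayes_task_params(frame)[0] == pytest.approx(0.5)

    def test_m5_running_variance_matches_explicit_loop(self, noiseless_bayes_session):
        from bayescoin.synthetic_data import session_frame

        frame = session_frame(noiseless_bayes_session)
        params = ConditionParams()
        preds = predict_m5_bayes_learned_prior(frame, params)
        # independent oracle: explicit per-trial loop over the session
        expected = np.empty(len(frame))
        for (pid, block), sub in frame.groupby(["participant_id", "block"]):
            sub = sub.sort_values("trial")
            seen = []
            for row_pos, (_, row) in enumerate(sub.iterrows()):
                v = params.prior_var_large if not seen else float(np.mean(seen))
                v = max(v, 1e-6)
                s2 = params.sensory_var(row["likelihood_level"])
                w = v / (v + s2)
                expected[frame.index.get_loc(row.name)] = (1 - w) * 0.5 + w * row["centroid_x"]
                seen.append((row["coin_x"] - 0.5) ** 2)
        assert np.allclose(preds, expected)

    def test_m5_variance_floor_on_degenerate_history(self):
        frame = _mini_frame(np.array([0.5, 0.6]), np.array([0.6, 0.6]))
        preds = predict_m5_bayes_learned_prior(frame)
        # after one coin exactly at the mean the floored variance makes
        # the prediction hug the prior mean
        w_floor = 1e-6 / (1e-6 + 0.00072)
        assert preds[1] == pytest.approx(0.5 + w_floor * 0.1)

    def test_m5_learned_variance_converges_to_imposed(self, noiseless_bayes_session):
        from bayescoin.synthetic_data import session_frame

        frame = session_frame(noiseless_bayes_session)
        m4 = predict_m4_bayes_task_params(frame)
        m5 = predict_m5_bayes_learned_prior(frame)
        # late in each block the learner's predictions approach model 4's
        late = frame.groupby("block")["trial"].rank() > 100
        assert np.mean(np.abs(m4[late.to_numpy()] - m5[late.to_numpy()])) < 0.01


class TestReductionLattice:
    def test_m6_with_imposed_variances_equals_m4(self, small_noisy_cohort):
        params = ConditionParams()
        m6 = predict_m6_two_priors_global(small_noisy_cohort, params.prior_var_small, params.prior_var_large)
        assert np.allclose(m6, predict_m4_bayes_task_params(small_noisy_cohort))

    def test_m7_with_equal_params_equals_m6(self, small_noisy_cohort):
        pv = {pid: (0.001, 0.008) for pid in small_noisy_cohort["participant_id"].unique()}
        m7 = predict_m7_two_priors_per_participant(small_noisy_cohort, pv)
        assert np.allclose(m7, predict_m6_two_priors_global(small_noisy_cohort, 0.001, 0.008))

    @pytest.mark.parametrize("fn", [predict_m8_stress_on_slope, predict_m9_stress_on_prior_var, predict_m10_stress_on_likelihood_var])
    def test_stress_models_reduce_to_m6_at_beta_zero(self, fn, small_noisy_cohort):
        preds = fn(small_noisy_cohort, 0.001, 0.008, 0.0)
        assert np.allclose(preds, predict_m6_two_priors_global(small_noisy_cohort, 0.001, 0.008))

    def test_stress_betas_move_stressed_predictions_toward_centroid(self, small_noisy_cohort):
        stressed = (small_noisy_cohort["group"] == "stressed").to_numpy()
        centroid = small_noisy_cohort["centroid_x"].to_numpy()
        base = predict_m6_two_priors_global(small_noisy_cohort, 0.001, 0.008)
        for preds in (
            predict_m8_stress_on_slope(small_noisy_cohort, 0.001, 0.008, 0.1),
            predict_m9_stress_on_prior_var(small_noisy_cohort, 0.001, 0.008, np.log(4.0)),
            predict_m10_stress_on_likelihood_var(small_noisy_cohort, 0.001, 0.008, np.log(0.25)),
        ):
            assert np.allclose(preds[~stressed], base[~stressed])
            moved = np.abs(preds[stressed] - centroid[stressed])
            assert (moved <= np.abs(base[stressed] - centroid[stressed]) + 1e-12).all()

    def test_bayes_predictions_lie_between_prior_mean_and_centroid(self, small_noisy_cohort):
        centroid = small_noisy_cohort["centroid_x"].to_numpy()
        lo = np.minimum(0.5, centroid) - 1e-12
        hi = np.maximum(0.5, centroid) + 1e-12
        for preds in (
            predict_m4_bayes_task_params(small_noisy_cohort),
            predict_m5_bayes_learned_prior(small_noisy_cohort),
            predict_m8_stress_on_slope(small_noisy_cohort, 0.001, 0.008, 0.4),
        ):
            assert ((preds >= lo) & (preds <= hi)).all()


class TestFitting:
    def test_k_free_counts_match_design(self):
        counts = [model_k_free(mid, 60) for mid in range(1, 11)]
        assert counts == [0, 0, 0, 0, 0, 2, 120, 3, 3, 3]

    def test_m6_recovers_generating_variances(self):
        gen_vars = {"p": 0.0009, "P": 0.012}
        sessions = simulate_cohort(
            3,
            3,
            ObserverSpec(subjective_prior_vars=gen_vars, response_noise_sd=0.0),
            seed=31,
            trials_per_block=60,
        )
        fit = fit_model(6, cohort_frame(sessions), seed=1)
        assert fit.params["v_p"] == pytest.approx(gen_vars["p"], rel=0.02)
        assert fit.params["v_P"] == pytest.approx(gen_vars["P"], rel=0.02)
        assert fit.sse < 1e-8

    def test_m8_clamp_events_logged(self, small_noisy_cohort):
        fit = fit_model(8, small_noisy_cohort, seed=1, n_starts=2)
        assert "clamp_events" in fit.diagnostics

    def test_fit_requires_responses(self, stimulus_session):
        from bayescoin.synthetic_data import session_frame

        with pytest.raises(ValueError, match="without responses"):
            fit_model(1, session_frame(stimulus_session))

    def test_fitted_model_serialises_to_json(self, small_noisy_cohort):
        import json

        fit = fit_model(6, small_noisy_cohort, seed=3, n_starts=2)
        payload = json.loads(fit.to_json())
        assert payload["model_id"] == 6
        assert payload["seed"] == 3
        assert payload["diagnostics"]["n_converged"] >= 1

    def test_predict_fitted_matches_training_predictions(self, small_noisy_cohort):
        for mid in (1, 4, 6):
            fit = fit_model(mid, small_noisy_cohort, seed=0, n_starts=2)
            assert np.allclose(predict_fitted(fit, small_noisy_cohort), fit.predictions)
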