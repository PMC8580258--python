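import math

import numpy as np
import pytest

from latentcause import (
    CATALOGUE,
    InternalModel,
    ObserverChoiceModel,
    ObserverParams,
    TaskParams,
    compare_models,
    fit_model,
    negative_log_likelihood,
    sample_session,
    simulate_responses,
    trials_to_frame,
)


@pytest.fixture(scope="module")
def a1_dataset():
    """2000 trials with responses simulated from the exact Bayesian observer."""
    tp = TaskParams(N_set=(6, 9))
    rng = np.random.default_rng(101)
    trials = sample_session(tp, 2000, rng)
    gen = ObserverParams(k=0.5, sigma_d=1.0, lapse=0.05)
    responses, d = simulate_responses(
        CATALOGUE["A1"], gen, trials, rng, model=InternalModel()
    )
    return trials, responses, d


class TestNegativeLogLikelihood:
    def test_near_perfect_prediction_gives_near_zero(self, a1_dataset):
        trials, _, d = a1_dataset
        sharp = ObserverParams(k=0.0, sigma_d=1e-6, lapse=0.0)
        responses = (d > 0).astype(int)
        nll = negative_log_likelihood("A1", sharp, trials, responses, d_values=d)
        assert 0 <= nll < 1e-3

    def test_pure_lapse_is_coin_flip_likelihood(self, a1_dataset):
        trials, responses, d = a1_dataset
        coin = ObserverParams(k=0.0, sigma_d=1.0, lapse=1.0)
        nll = negative_log_likelihood("A1", coin, trials, responses, d_values=d)
        assert nll == pytest.approx(len(trials) * math.log(2), rel=1e-12)

    def test_lapse_grid_minimum_at_generating_value(self):
        # pure-lapse data: the Bernoulli NLL over a lapse grid bottoms out
        # near the generating lapse probability
        rng = np.random.default_rng(7)
        tp = TaskParams(N_set=(6,))
        trials = sample_session(tp, 4000, rng)
        d = np.full(len(trials), 10.0)  # far above criterion
        lam_true = 0.4
        p = 0.5 * lam_true + (1 - lam_true)
        responses = (rng.uniform(size=len(trials)) < p).astype(int)
        grid = np.linspace(0.05, 0.95, 19)
        nlls = [
            negative_log_likelihood(
                "A1",
                ObserverParams(k=0.0, sigma_d=1.0, lapse=lam),
                trials,
                responses,
                d_values=d,
            )
            for lam in grid
        ]
        assert abs(grid[int(np.argmin(nlls))] - lam_true) <= 0.1

    def test_misaligned_responses_rejected(self, a1_dataset):
        trials, responses, _ = a1_dataset
        with pytest.raises(ValueError):
            negative_log_likelihood(
                "A1", ObserverParams(), trials, responses[:-1]
            )


class TestInformationCriteria:
    def test_aic_bic_arithmetic(self, a1_dataset):
        trials, responses, _ = a1_dataset
        model = ObserverChoiceModel("A1", trials, responses)
        res = model.fit(n_restarts=3, seed=0)
        assert res.aic == pytest.approx(2 * res.n_params - 2 * res.log_lik)
        assert res.bic == pytest.approx(
            res.n_params * math.log(len(trials)) - 2 * res.log_lik
        )
        assert res.log_lik <= 0

    def test_free_parameter_bookkeeping(self, a1_dataset):
        trials, responses, _ = a1_dataset
        # two set sizes present: A2 has 2 criteria + sigma_d + lapse
        assert ObserverChoiceModel("A1", trials, responses).layout.n_free == 3
        assert ObserverChoiceModel("A2", trials, responses).layout.n_free == 4
        assert ObserverChoiceModel("A1P", trials, responses).layout.n_free == 5
        assert ObserverChoiceModel("A3", trials, responses).layout.n_free == 6
        assert ObserverChoiceModel("H10", trials, responses).layout.n_free == 3

    def test_full_design_parameter_counts(self):
        # with all four set sizes the flexible-criterion Bayesian model has
        # 4 criteria + sigma_d + lapse = 6 free parameters
        tp = TaskParams()
        rng = np.random.default_rng(8)
        trials = sample_session(tp, 40, rng)
        responses = rng.integers(0, 2, 40)
        assert ObserverChoiceModel("A2", trials, responses).layout.n_free == 6
        assert ObserverChoiceModel("H11", trials, responses).layout.n_free == 5

    def test_summary_renders(self, a1_dataset):
        trials, responses, _ = a1_dataset
        res = ObserverChoiceModel("A1", trials, responses).fit(n_restarts=2, seed=1)
        text = res.summary()
        assert "A1" in text and "AIC" in text and "k" in text


class TestFitModel:
    def test_recovers_generating_parameters(self, a1_dataset):
        trials, responses, _ = a1_dataset
        res = fit_model("A1", trials, responses, n_restarts=6, seed=3)
        est = dict(zip(res.param_names, res.param_values))
        assert abs(est["k"] - 0.5) <= 0.3
        assert abs(est["sigma_d"] - 1.0) <= 0.3
        assert abs(est["lapse"] - 0.05) <= 0.05
        assert res.converged

    def test_from_dataframe_constructor(self, a1_dataset):
        trials, responses, _ = a1_dataset
        df = trials_to_frame(trials[:200])
        df["response"] = responses[:200]
        model = ObserverChoiceModel.from_dataframe("A1", df)
        assert len(model.trials) == 200

    def test_nested_flexible_criterion_model_dominates(self, a1_dataset):
        trials, responses, _ = a1_dataset
        r1 = fit_model("A1", trials, responses, n_restarts=4, seed=4)
        r2 = fit_model("A2", trials, responses, n_restarts=4, seed=4)
        assert r2.log_lik >= r1.log_lik - 1e-3


class TestCompareModels:
    def test_self_comparison_is_zero(self, a1_dataset):
        trials, responses, _ = a1_dataset
        res = fit_model("A1", trials, responses, n_restarts=2, seed=5)
        tab = compare_models([res], reference="A1")
        assert tab["delta_aic_vs_ref"].iloc[0] == 0.0

    def test_unused_parameter_penalty_arithmetic(self, a1_dataset):
        trials, responses, _ = a1_dataset
        res = fit_model("A1", trials, responses, n_restarts=2, seed=6)
        import dataclasses

        padded = dataclasses.replace(
            res,
            model_id="A1_padded",
            n_params=res.n_params + 1,
            aic=2 * (res.n_params + 1) - 2 * res.log_lik,
            bic=(res.n_params + 1) * math.log(res.n_trials) - 2 * res.log_lik,
        )
        tab = compare_models([res, padded], reference="A1")
        row = tab[tab.model_id == "A1_padded"].iloc[0]
        assert row["delta_aic_vs_ref"] == pytest.approx(2.0)
        assert row["delta_bic_vs_ref"] == pytest.approx(math.log(res.n_trials))

    def test_mixed_datasets_rejected(self, a1_dataset):
        trials, responses, _ = a1_dataset
        r1 = fit_model("A1", trials[:500], responses[:500], n_restarts=2, seed=7)
        r2 = fit_model("A1", trials[500:], responses[500:], n_restarts=2, seed=7)
        with pytest.raises(ValueError):
            compare_models([r1, r2])

    def test_bayes_data_not_better_fit_by_distance_heuristic(self, a1_dataset):
        trials, responses, _ = a1_dataset
        r_a1 = fit_model("A1", trials, responses, n_restarts=4, seed=8)
        r_h10 = fit_model("H10", trials, responses, n_restarts=4, seed=8)
        assert r_h10.aic - r_a1.aic > 0


class TestConsistency:
    def test_error_shrinks_with_sample_size(self):
        # MLE consistency: |k_hat - k| at n = 2000 not worse than at n = 300
        tp = TaskParams(N_set=(6,))
        gen = ObserverParams(k=0.5, sigma_d=1.0, lapse=0.05)
        errs = {}
        for n, seed in ((300, 21), (2000, 22)):
            err = []
            for rep in range(3):
                rng = np.random.default_rng(seed + rep)
                trials = sample_session(tp, n, rng)
                responses, _ = simulate_responses(
                    CATALOGUE["A1"], gen, trials, rng, model=InternalModel()
                )
                res = fit_model("A1", trials, responses, n_restarts=5, seed=rep)
                est = dict(zip(res.param_names, res.param_values))
                err.append(abs(est["k"] - 0.5))
            errs[n] = np.median(err)
        assert errs[2000] <= errs[300] + 0.05
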