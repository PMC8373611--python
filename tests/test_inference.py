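"""Fitting, prediction, evidence estimation and Bayes factors."""

import numpy as np
import pandas as pd
import pytest

from pragmalex import (
    MCMCSettings,
    ModelName,
    PriorSpec,
    bayes_factor,
    default_design,
    fit,
    marginal_likelihood,
    monte_carlo_evidence,
    posterior_predict,
    predict_for_trials,
    simulate_experiment,
)
from pragmalex._trials import trial_arrays
from pragmalex.inference import (
    ModelEvidence,
    log_likelihood_and_grad,
    log_likelihood_draws,
)


def test_fit_rejects_empty_table():
    empty = pd.DataFrame(
        columns=["child_id", "age", "experiment", "condition", "object_id", "correct"]
    )
    with pytest.raises(ValueError, match="empty"):
        fit(ModelName.INTEGRATION, empty, seed=0)


def test_prediction_stage_refuses_exp3(truth):
    table = simulate_experiment(default_design("exp3", 3), truth, seed=0)
    with pytest.raises(ValueError, match="out-of-sample"):
        fit(ModelName.INTEGRATION, table, seed=0, stage="prediction")


def test_prior_only_fit_matches_prior():
    """With no data the sampler must reproduce the prior (Bayes with no data)."""
    priors = PriorSpec()
    empty = pd.DataFrame(
        columns=["child_id", "age", "experiment", "condition", "object_id", "correct"]
    )
    post = fit(
        ModelName.INTEGRATION,
        empty,
        priors=priors,
        settings=MCMCSettings(n_warmup=200, n_draws=600, n_chains=4),
        seed=1,
        prior_only=True,
    )
    draws = post.params()
    for name in ("alpha_intercept", "rho_intercept", "theta_slope"):
        loc, scale = priors.coefficients[name]
        assert np.mean(draws[name]) == pytest.approx(loc, abs=0.3 * scale)
        assert np.std(draws[name]) == pytest.approx(scale, rel=0.3)


def test_likelihood_shared_between_fit_and_evidence(truth, exp12_posterior):
    """Evidence must average exactly the likelihood the sampler used."""
    table = simulate_experiment(default_design("exp3", 4), truth, seed=21)
    arrays = trial_arrays(table, truth.object_ids)
    layout = exp12_posterior.layout
    X = exp12_posterior.draws(1500, rng=3)
    ll = log_likelihood_draws(ModelName.INTEGRATION, arrays, X, layout)
    ll_grad, _ = log_likelihood_and_grad(ModelName.INTEGRATION, arrays, X, layout)
    assert np.allclose(ll, ll_grad, atol=1e-9)

    ev = monte_carlo_evidence(
        lambda draws: log_likelihood_draws(ModelName.INTEGRATION, arrays, draws, layout),
        lambda n, rng: X[:n],
        n_samples=1500,
        seed=0,
    )
    m = ll.max()
    expected = m + np.log(np.mean(np.exp(ll - m)))
    assert ev.log_marginal_likelihood == pytest.approx(expected, abs=1e-9)


def test_evidence_fixed_model_closed_form():
    """A parameter-free p=0.5 model on 3 trials has evidence 0.5^3 exactly."""
    ev = monte_carlo_evidence(
        lambda draws: np.full(draws.shape[0], 3 * np.log(0.5)),
        lambda n, rng: np.zeros((n, 0)),
        n_samples=1000,
        seed=0,
    )
    assert ev.log_marginal_likelihood == pytest.approx(3 * np.log(0.5), abs=1e-12)
    assert ev.standard_error == pytest.approx(0.0, abs=1e-12)


def test_evidence_beta_bernoulli_oracle():
    """Uniform prior on p, 1 success in 2 trials: ML = B(2,2) = 1/6."""

    def loglik(draws):
        p = draws[:, 0]
        return np.log(p) + np.log1p(-p)

    ev = monte_carlo_evidence(
        loglik, lambda n, rng: rng.random((n, 1)), n_samples=10_000, seed=7
    )
    # standard_error is on the log scale; delta method back to natural scale
    se_natural = ev.standard_error * np.exp(ev.log_marginal_likelihood)
    assert np.exp(ev.log_marginal_likelihood) == pytest.approx(
        1 / 6, abs=3 * se_natural
    )


def test_evidence_se_scales_with_sqrt_n():
    def loglik(draws):
        p = np.clip(draws[:, 0], 1e-9, 1 - 1e-9)
        return 3 * np.log(p)

    se_small = monte_carlo_evidence(
        loglik, lambda n, rng: rng.random((n, 1)), 2_000, seed=1
    ).standard_error
    se_big = monte_carlo_evidence(
        loglik, lambda n, rng: rng.random((n, 1)), 20_000, seed=1
    ).standard_error
    assert se_small / se_big == pytest.approx(np.sqrt(10), rel=0.35)


def test_evidence_requires_min_samples():
    with pytest.raises(ValueError):
        monte_carlo_evidence(lambda d: np.zeros(10), lambda n, r: np.zeros((n, 1)), 10)


def test_all_zero_likelihood_warns():
    with pytest.warns(RuntimeWarning):
        ev = monte_carlo_evidence(
            lambda draws: np.full(draws.shape[0], -np.inf),
            lambda n, rng: np.zeros((n, 1)),
            n_samples=1000,
        )
    assert np.isneginf(ev.log_marginal_likelihood)


def test_bayes_factor_identities():
    a = ModelEvidence(-10.0, 0.1, 1000)
    b = ModelEvidence(-10.0 - np.log(10), 0.1, 1000)
    assert bayes_factor(a, a).value == pytest.approx(1.0)
    bf = bayes_factor(a, b)
    assert bf.value == pytest.approx(10.0)
    assert bf.log10 == pytest.approx(1.0)
    with pytest.warns(RuntimeWarning):
        degenerate = bayes_factor(ModelEvidence(-np.inf, np.nan, 1000), a)
    assert degenerate.value == 0.0


def test_posterior_predict_lesion_properties(exp12_posterior):
    ages = [2.5, 3.5, 4.5]
    ncg = posterior_predict(ModelName.NO_COMMON_GROUND, exp12_posterior, ages, seed=0)
    wide = ncg.pivot_table(
        index=["age", "object_id"], columns="condition", values="predicted_mean"
    )
    assert np.allclose(wide["congruent"], wide["incongruent"], atol=1e-12)

    nsi = posterior_predict(
        ModelName.NO_SPEAKER_INFORMATIVENESS, exp12_posterior, ages, seed=0
    )
    by_obj = nsi.groupby(["age", "condition"])["predicted_mean"].nunique()
    assert (by_obj == 1).all()  # prior-only predictions ignore the object

    integ = posterior_predict(ModelName.INTEGRATION, exp12_posterior, ages, seed=0)
    cong = integ[integ["condition"] == "congruent"].groupby("age")["predicted_mean"].mean()
    assert cong.loc[2.5] < cong.loc[4.5]  # predictions increase with age

    assert len(integ) == len(ages) * 2 * 12
    assert (integ["predicted_hdi_low"] <= integ["predicted_mean"]).all()


def test_predict_for_trials_needs_phi(exp12_posterior, truth):
    table = simulate_experiment(default_design("exp3", 2), truth, seed=5)
    with pytest.raises(ValueError, match="phi"):
        predict_for_trials(ModelName.BIASED, exp12_posterior, table)


def test_marginal_likelihood_from_posterior_fills_phi(exp12_posterior, truth):
    """Biased-model evidence from an integration posterior draws phi from its prior."""
    table = simulate_experiment(default_design("exp3", 4), truth, seed=23)
    ev = marginal_likelihood(
        ModelName.BIASED, table, exp12_posterior, n_samples=2000, seed=0
    )
    assert np.isfinite(ev.log_marginal_likelihood)
    assert ev.standard_error > 0
    assert ev.model is ModelName.BIASED
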