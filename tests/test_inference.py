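import numpy as np
import pytest
import scipy.stats

from mihmm.cohort import build_cohort
from mihmm.inference import (
    MCMCChains,
    MCMCConfig,
    PriorSpec,
    crude_init,
    log_posterior,
    params_to_theta,
    run_mcmc,
    summarize,
    theta_to_params,
)
from mihmm.likelihood import CohortData, series_loglik
from mihmm.params import N_EMISSION, N_TRANSITIONS, PARAM_NAMES, ProgressionParams
from mihmm.simulate import SimConfig, simulate_cohort

from conftest import make_series

N_PARAMS = len(PARAM_NAMES)


def test_theta_round_trip(truth_params):
    theta = params_to_theta(truth_params)
    back = theta_to_params(theta)
    np.testing.assert_allclose(back.beta, truth_params.beta)
    np.testing.assert_allclose(back.e, truth_params.e, atol=1e-12)


def test_prior_support_excludes_half(truth_params):
    prior = PriorSpec.default()
    theta = params_to_theta(truth_params)
    assert np.isfinite(prior.logpdf(theta))
    bad = theta.copy()
    bad[-1] = 0.5  # logit(e4) >= logit(0.5)
    assert prior.logpdf(bad) == -np.inf


def test_death_prior_centered_on_population_rate():
    prior = PriorSpec.default(death_rate=0.0065)
    for l in (2, 4, 5):  # Well/NSTEMI/STEMI -> Dead intercepts
        assert prior.beta_mean[l, 0] == pytest.approx(np.log(0.0065))
        assert prior.beta_sd[l, 0] == pytest.approx(0.5)
    assert prior.beta_sd[0, 0] == 10.0
    assert prior.beta_sd[0, 1] == 2.0


def test_log_posterior_composition_on_toy_cohort(truth_params):
    """log posterior = hand-summed per-series likelihood + normal prior terms."""
    series = [
        make_series([(0, 0), (1, 1)], patient_id="a"),
        make_series([(0, 1), (1, None), (2, 2)], patient_id="b"),
        make_series([(0, 0)], patient_id="c", death_time=1.5),
    ]
    data = CohortData.from_series(series)
    prior = PriorSpec.default()
    theta = params_to_theta(truth_params)
    expected = sum(series_loglik(s, truth_params) for s in series)
    expected += scipy.stats.norm.logpdf(
        theta, loc=prior.mean_vector, scale=prior.sd_vector
    ).sum()
    assert log_posterior(theta, data, prior) == pytest.approx(expected, abs=1e-8)


def test_flat_prior_limit_differences_are_likelihood_differences(truth_params):
    series = [make_series([(0, 0), (1, 1), (2, 2)])]
    data = CohortData.from_series(series)
    flat = PriorSpec(
        beta_mean=np.zeros((N_TRANSITIONS, 4)),
        beta_sd=np.full((N_TRANSITIONS, 4), 1e7),
        e_logit_mean=np.zeros(N_EMISSION),
        e_logit_sd=np.full(N_EMISSION, 1e7),
    )
    t1 = params_to_theta(truth_params)
    other = truth_params.copy()
    other.beta = other.beta + 0.1
    t2 = params_to_theta(other)
    lp_diff = log_posterior(t1, data, flat) - log_posterior(t2, data, flat)
    ll_diff = series_loglik(series[0], truth_params) - series_loglik(series[0], other)
    assert lp_diff == pytest.approx(ll_diff, abs=1e-6)


def test_no_data_posterior_is_prior(truth_params):
    prior = PriorSpec.default()
    theta = params_to_theta(truth_params)
    assert log_posterior(theta, None, prior) == pytest.approx(prior.logpdf(theta))


def test_mcmc_is_deterministic_given_seed(small_cohort):
    series, _ = small_cohort
    data = CohortData.from_series(series[:40])
    prior = PriorSpec.default()
    cfg = MCMCConfig(seed=9, chains=2, iterations=200, burn_in=0.5)
    a = run_mcmc(data, prior, cfg)
    b = run_mcmc(data, prior, cfg)
    assert np.array_equal(a.draws, b.draws)
    assert np.array_equal(a.accept_rates, b.accept_rates)


def test_prior_only_run_recovers_prior_quantiles():
    """With no data the sampler must reproduce the prior itself."""
    prior = PriorSpec.default()
    cfg = MCMCConfig(seed=5, chains=2, iterations=6000, burn_in=0.5)
    chains = run_mcmc(None, prior, cfg)
    summary = summarize(chains, compute_ess=False)
    # q1.age prior is N(0, 2): check mean and the 95% band loosely (MCMC error)
    row = summary.table.loc["q1.age"]
    assert abs(row["mean"]) < 0.35
    assert row["q2.5"] == pytest.approx(-3.92, abs=0.8)
    assert row["q97.5"] == pytest.approx(3.92, abs=0.8)
    # death intercept prior N(log 0.0065, 0.5)
    row = summary.table.loc["q3.intercept"]
    assert row["mean"] == pytest.approx(np.log(0.0065), abs=0.15)
    assert row["sd"] == pytest.approx(0.5, rel=0.3)


def test_fixed_emission_mode_recovers_rate_without_misclassification():
    """Simulated with emissions at the zero boundary and fitted with the
    emission block off, the posterior q1 mean lands within 3 posterior sds
    of truth."""
    import mihmm.simulate as sim

    truth = sim.default_true_params()
    truth.e = np.zeros(4)
    cfg = SimConfig(n_patients=500, seed=77, params=truth, gap_probability=0.2)
    series, _ = build_cohort(sim.simulate_cohort(cfg), require_mi=False)
    data = CohortData.from_series(series)
    chains = run_mcmc(
        None if not series else data,
        PriorSpec.default(),
        MCMCConfig(seed=31, chains=1, iterations=1500, burn_in=0.5, fix_emissions=True),
    )
    summary = summarize(chains, compute_ess=False)
    row = summary.table.loc["q1.intercept"]
    assert abs(row["mean"] - truth.beta[0, 0]) < 3 * row["sd"]
    # emission columns are pinned at the boundary in the output
    assert (summary.table.loc[["e1", "e2", "e3", "e4"], "mean"] == 0).all()


def test_summarize_constant_chain():
    draws = np.zeros((1, 300, N_PARAMS))
    draws[:] = 0.25
    draws[:, :, 24:] = -3.0  # logit scale
    chains = MCMCChains(draws=draws, n_burn=100, accept_rates=np.ones((1, 7)), seed=0)
    tab = summarize(chains, compute_ess=False).table
    assert tab.loc["q1.intercept", "mean"] == 0.25
    assert tab.loc["q1.intercept", "q2.5"] == tab.loc["q1.intercept", "q97.5"] == 0.25
    assert tab.loc["e1", "mean"] == pytest.approx(1 / (1 + np.exp(3.0)))


def test_summarize_normal_quantiles():
    rng = np.random.default_rng(1)
    draws = rng.standard_normal((1, 100_000, N_PARAMS))
    chains = MCMCChains(draws=draws, n_burn=0, accept_rates=np.ones((1, 7)), seed=0)
    tab = summarize(chains, compute_ess=False).table
    assert tab.loc["q2.sex", "q2.5"] == pytest.approx(-1.96, abs=0.05)
    assert tab.loc["q2.sex", "q97.5"] == pytest.approx(1.96, abs=0.05)


def test_two_chain_pooling_equals_concatenation():
    rng = np.random.default_rng(2)
    draws = rng.standard_normal((2, 400, N_PARAMS))
    two = MCMCChains(draws=draws, n_burn=100, accept_rates=np.ones((2, 7)), seed=0)
    one = MCMCChains(
        draws=np.concatenate([draws[0:1, 100:], draws[1:2, 100:]], axis=1),
        n_burn=0,
        accept_rates=np.ones((1, 7)),
        seed=0,
    )
    pd_a = summarize(two, compute_ess=False).table
    pd_b = summarize(one, compute_ess=False).table
    np.testing.assert_allclose(pd_a["mean"], pd_b["mean"])
    np.testing.assert_allclose(pd_a["q2.5"], pd_b["q2.5"])


def test_summarize_requires_enough_draws():
    draws = np.zeros((1, 50, N_PARAMS))
    chains = MCMCChains(draws=draws, n_burn=0, accept_rates=np.ones((1, 7)), seed=0)
    with pytest.raises(ValueError):
        summarize(chains)


def test_crude_init_tracks_event_rates(small_cohort):
    series, _ = small_cohort
    data = CohortData.from_series(series)
    theta = crude_init(data, PriorSpec.default())
    # crude Well->NSTEMI rate should be within an order of magnitude of truth
    assert -4.5 < theta[0] < -1.0


def test_seed_is_mandatory():
    with pytest.raises(TypeError):
        MCMCConfig()  # type: ignore[call-arg]
    with pytest.raises(ValueError):
        MCMCConfig(seed=None)  # type: ignore[arg-type]
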