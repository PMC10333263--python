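"""Priors, likelihood, Metropolis-Hastings and convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from predband.inference import (
    MCMCConfig,
    PriorSpec,
    default_prior,
    effective_sample_size,
    log_likelihood,
    log_prior,
    metropolis_hastings,
    r_hat,
    run_training,
)
from predband.models import CASCADE_T_GRID, NOMINAL_CASCADE, get_model, get_protocol, simulate
from predband.synthetic import MeasurementSet, generate_measurements, make_training_scenario

SIGMA = 0.3


# --------------------------------------------------------------------------
# priors


def test_cascade_prior_clips_at_1e4():
    prior = default_prior(get_model("nominal"))
    assert log_prior({"a1": 2.0e4}, prior) == -np.inf
    assert np.isfinite(log_prior({"a1": 9.9e3}, prior))
    assert log_prior({"a1": -1.0}, prior) == -np.inf


def test_uniform_prior_constant_inside_bounds():
    prior = default_prior(get_model("oscillator"))
    lo, hi = prior.entries["m1"][1:]
    inside = [log_prior({"m1": v}, prior) for v in np.linspace(lo, hi, 7)]
    assert np.allclose(inside, inside[0])
    assert log_prior({"m1": hi * 1.01}, prior) == -np.inf


def test_lognormal_mode_matches_numeric_maximisation():
    """Un-clipped LogNormal(mu, sigma) has its mode at exp(mu - sigma^2)."""
    prior = PriorSpec({"p": ("lognormal", 1.0, 3.0, 1e300)})
    res = optimize.minimize_scalar(
        lambda lx: -prior.logpdf("p", np.exp(lx)), bounds=(-30, 10), method="bounded"
    )
    assert np.exp(res.x) == pytest.approx(np.exp(1.0 - 9.0), rel=1e-3)


def test_clipped_prior_density_integrates_to_one():
    prior = default_prior(get_model("nominal"))
    from scipy.integrate import quad

    val, _ = quad(
        lambda lx: np.exp(prior.logpdf("a1", np.exp(lx))) * np.exp(lx),
        -40, np.log(1e4), limit=200,
    )
    assert val == pytest.approx(1.0, rel=1e-6)


# --------------------------------------------------------------------------
# likelihood


def _single_measurement(value, n_replicates=1):
    rows = [("K4", 1.0, r, value) for r in range(1, n_replicates + 1)]
    return MeasurementSet(
        pd.DataFrame(rows, columns=["variable", "time", "replicate", "value"]),
        sigma_error=SIGMA,
        transform="softlog",
        provenance={"protocol": "s_train"},
    )


@pytest.fixture(scope="module")
def nominal_softlog_k4_at_1h():
    from predband.synthetic import softlog

    traj = simulate(
        get_model("nominal"), NOMINAL_CASCADE, get_protocol("s_train"), CASCADE_T_GRID
    )
    return softlog(traj.state("K4")[1])


def test_loglik_of_zero_residual_is_gaussian_constant(nominal_softlog_k4_at_1h):
    ms = _single_measurement(nominal_softlog_k4_at_1h)
    ll = log_likelihood(NOMINAL_CASCADE, ms, get_model("nominal"))
    assert ll == pytest.approx(-np.log(SIGMA * np.sqrt(2 * np.pi)), abs=1e-6)
    assert ll == pytest.approx(0.2848, abs=5e-4)


def test_loglik_one_sigma_residual_costs_half(nominal_softlog_k4_at_1h):
    ms0 = _single_measurement(nominal_softlog_k4_at_1h)
    ms1 = _single_measurement(nominal_softlog_k4_at_1h + SIGMA)
    model = get_model("nominal")
    ll0 = log_likelihood(NOMINAL_CASCADE, ms0, model)
    ll1 = log_likelihood(NOMINAL_CASCADE, ms1, model)
    assert ll0 - ll1 == pytest.approx(0.5, abs=1e-6)


def test_loglik_scales_with_replicate_count(nominal_softlog_k4_at_1h):
    model = get_model("nominal")
    ll1 = log_likelihood(NOMINAL_CASCADE, _single_measurement(nominal_softlog_k4_at_1h, 1), model)
    ll2 = log_likelihood(NOMINAL_CASCADE, _single_measurement(nominal_softlog_k4_at_1h, 2), model)
    assert ll2 == pytest.approx(2 * ll1, abs=1e-9)


def test_training_selection_ignores_other_variables():
    """Likelihood restricted to K4 is untouched by permuting K1..K3 data."""
    model, protocol, ms = make_training_scenario("cascade_train")
    ll = log_likelihood(model.nominal_array, ms, model, protocol, trained_variables=["K4"])
    shuffled = ms.records.copy()
    mask = shuffled.variable != "K4"
    shuffled.loc[mask, "value"] = (
        shuffled.loc[mask, "value"].sample(frac=1, random_state=0).to_numpy()
    )
    ms2 = MeasurementSet(shuffled, ms.sigma_error, ms.transform, ms.provenance)
    ll2 = log_likelihood(model.nominal_array, ms2, model, protocol, trained_variables=["K4"])
    assert ll == ll2


def test_replicate_labels_exchangeable():
    model, protocol, ms = make_training_scenario("cascade_train")
    ll = log_likelihood(model.nominal_array, ms, model, protocol)
    relabeled = ms.records.copy()
    relabeled["replicate"] = relabeled["replicate"].map({1: 3, 2: 1, 3: 2})
    ms2 = MeasurementSet(relabeled, ms.sigma_error, ms.transform, ms.provenance)
    assert log_likelihood(model.nominal_array, ms2, model, protocol) == ll


def test_python_and_compiled_likelihood_agree():
    """The jitted kernel used inside MCMC matches the reference path up to
    the dropped Gaussian normalisation constant."""
    from predband import _mcmc
    from predband.inference import _chain_inputs

    model, protocol, ms = make_training_scenario("cascade_train")
    prior = default_prior(model)
    inputs = _chain_inputs(model, protocol, ms, ["K2", "K4"], prior)
    rng = np.random.default_rng(0)
    for _ in range(5):
        free = np.abs(rng.normal(1.0, 0.5, model.n_free))
        full = model.full_params(free)
        kernel_ll = _mcmc._log_likelihood_kernel(
            inputs["model_id"], full, inputs["y0"], inputs["t_out"],
            inputs["seg_t0"], inputs["seg_t1"], inputs["seg_v"], inputs["sin_par"],
            1e-6, 1e-9, inputs["transform_id"], inputs["meas_var"],
            inputs["meas_tidx"], inputs["meas_val"], inputs["sigma_err"],
        )
        n_obs = len(inputs["meas_val"])
        const = -n_obs * np.log(SIGMA * np.sqrt(2 * np.pi))
        ref = log_likelihood(full, ms, model, protocol, trained_variables=["K2", "K4"])
        assert kernel_ll + const == pytest.approx(ref, abs=1e-6)


# --------------------------------------------------------------------------
# Metropolis-Hastings on analytic targets


def test_mh_samples_standard_normal():
    samples, acc = metropolis_hastings(
        lambda x: -0.5 * float(x @ x), init=[0.0], step_sd=1.0, n_steps=100_000, seed=1
    )
    assert 0.2 < acc < 0.9
    assert -0.05 <= samples.mean() <= 0.05
    assert 0.9 <= samples.var() <= 1.1


def test_mh_acceptance_approaches_one_for_tiny_steps():
    _, acc = metropolis_hastings(
        lambda x: -0.5 * float(x @ x), init=[0.3], step_sd=1e-6, n_steps=5_000, seed=2
    )
    assert acc > 0.999


def test_mh_recovers_correlated_gaussian_covariance():
    cov = np.array([[1.0, 0.8], [0.8, 1.0]])
    prec = np.linalg.inv(cov)
    samples, _ = metropolis_hastings(
        lambda x: -0.5 * float(x @ prec @ x), init=[0.0, 0.0],
        step_sd=0.7, n_steps=200_000, seed=3,
    )
    est = np.cov(samples.T)
    assert np.allclose(est, cov, rtol=0.1, atol=0.05)


def test_mh_conjugate_gaussian_posterior():
    """Gaussian prior x Gaussian likelihood: MH matches the closed-form
    posterior within 3 Monte-Carlo standard errors."""
    prior_mu, prior_sd = 0.0, 2.0
    data = np.array([1.2, 0.8, 1.5, 0.9, 1.1])
    lik_sd = 0.5
    post_var = 1.0 / (1.0 / prior_sd**2 + len(data) / lik_sd**2)
    post_mu = post_var * (prior_mu / prior_sd**2 + data.sum() / lik_sd**2)

    def log_target(x):
        th = x[0]
        return -0.5 * ((th - prior_mu) / prior_sd) ** 2 - 0.5 * np.sum(
            ((data - th) / lik_sd) ** 2
        )

    samples, _ = metropolis_hastings(
        log_target, init=[0.0], step_sd=0.5, n_steps=100_000, seed=4, burn_in=5_000
    )
    th = samples[:, 0]
    ess = effective_sample_size(th[None, :, None])
    se_mean = th.std() / np.sqrt(ess)
    assert abs(th.mean() - post_mu) < 3 * se_mean
    se_sd = th.std() / np.sqrt(2 * (ess - 1))
    assert abs(th.std() - np.sqrt(post_var)) < 3 * se_sd


def test_mh_requires_finite_start():
    with pytest.raises(ValueError):
        metropolis_hastings(lambda x: -np.inf, init=[0.0], step_sd=1.0, n_steps=10)


# --------------------------------------------------------------------------
# configuration arithmetic


def test_default_config_retains_10000_samples():
    config = MCMCConfig()
    assert config.n_chains == 8
    assert config.n_steps == 1_500_000
    assert config.burn_in == 250_000
    assert config.thin == 1000
    assert config.n_retained == 10_000


def test_scale_factor_preserves_retained_count():
    config = MCMCConfig(scale_factor=0.01)
    assert config.n_steps_eff == 15_000
    assert config.burn_in_eff == 2_500
    assert config.thin_eff == 10
    assert config.n_retained == 10_000


def test_config_validation():
    with pytest.raises(ValueError):
        MCMCConfig(burn_in=2_000_000)
    with pytest.raises(ValueError):
        MCMCConfig(scale_factor=0.0)
    with pytest.raises(ValueError):
        MCMCConfig(thin=0)


# --------------------------------------------------------------------------
# training driver


@pytest.fixture(scope="module")
def tiny_run():
    model, protocol, ms = make_training_scenario("cascade_train")
    config = MCMCConfig(n_chains=2, scale_factor=0.002, seed=9)
    return run_training(model, ms, ["K4"], config=config, protocol=protocol)


def test_training_output_layout(tiny_run):
    post = tiny_run
    assert post.param_names == get_model("nominal").free_names
    assert len(post.df) == post.config.n_retained
    assert set(post.df.chain.unique()) == {0, 1}
    assert np.all(post.values > 0)
    assert np.all(post.values <= 1e4)  # prior clip respected
    assert "log_posterior" in post.df.columns


def test_training_is_deterministic_given_seed():
    model, protocol, ms = make_training_scenario("cascade_train")
    config = MCMCConfig(n_chains=2, scale_factor=0.002, seed=9)
    a = run_training(model, ms, ["K4"], config=config, protocol=protocol)
    b = run_training(model, ms, ["K4"], config=config, protocol=protocol)
    pd.testing.assert_frame_equal(a.df, b.df)


def test_training_requires_variables():
    model, protocol, ms = make_training_scenario("cascade_train")
    with pytest.raises(ValueError):
        run_training(model, ms, [], protocol=protocol)


def test_posterior_csv_roundtrip(tmp_path, tiny_run):
    path = tmp_path / "post.csv"
    tiny_run.to_csv(path)
    from predband.inference import PosteriorSamples

    back = PosteriorSamples.from_csv(path)
    assert back.param_names == tiny_run.param_names
    assert back.model_name == "nominal"
    assert np.allclose(back.values, tiny_run.values)
    assert back.config.seed == tiny_run.config.seed


# --------------------------------------------------------------------------
# diagnostics


def test_rhat_near_one_for_iid_chains():
    rng = np.random.default_rng(0)
    chains = rng.normal(size=(4, 2000))
    assert 0.99 <= float(r_hat(chains)) <= 1.01


def test_rhat_detects_separated_chains():
    rng = np.random.default_rng(1)
    chains = rng.normal(size=(2, 1000))
    chains[1] += 10.0
    assert float(r_hat(chains)) > 1.5


def test_rhat_nan_for_constant_chains():
    chains = np.ones((2, 500))
    with pytest.warns(UserWarning, match="zero within-chain variance"):
        assert np.isnan(float(r_hat(chains)))


def test_ess_of_iid_samples_is_close_to_n():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(1, 4000, 1))
    ratio = float(effective_sample_size(x)) / 4000
    assert 0.8 <= ratio <= 1.2


def test_ess_of_ar1_matches_closed_form():
    """AR(1) with phi = 0.9 has ESS/N = (1 - phi)/(1 + phi) ~ 0.053."""
    phi, n = 0.9, 60_000
    rng = np.random.default_rng(3)
    x = np.empty(n)
    x[0] = rng.normal()
    innov = rng.normal(size=n) * np.sqrt(1 - phi**2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov[i]
    ratio = float(effective_sample_size(x[None, :, None])) / n
    expected = (1 - phi) / (1 + phi)
    assert ratio == pytest.approx(expected, rel=0.3)


def test_ess_needs_enough_draws():
    with pytest.raises(ValueError):
        effective_sample_size(np.random.default_rng(0).normal(size=50))
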