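"""Multilevel model internals, sampler behavior, and derived quantities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import approx_fprime

from lamina.bml import (
    BmlData,
    diagnostics,
    fit_bml,
    modulation_index,
    posterior_positive_prob,
    posterior_predictive_check,
    simulate_dataset,
)
from lamina.bml.model import StudentTMultilevel, cpc_to_cholesky
from lamina.bml.nuts import nuts_sample


# -- log posterior -----------------------------------------------------------


@pytest.mark.parametrize("likelihood", ["student_t", "normal"])
def test_logp_gradient_matches_finite_differences(likelihood, rng):
    y = simulate_dataset(rng, b=[0.2, 0.5, 0.8], R=4, S=5)
    m = StudentTMultilevel(y, likelihood=likelihood)
    theta = m.initial_value(rng) + 0.3 * rng.standard_normal(m.layout.size)
    _, g = m.logp_and_grad(theta)
    h = 1e-5
    for k in rng.choice(m.layout.size, size=40, replace=False):
        e = np.zeros(m.layout.size)
        e[k] = h
        num = (m.logp_and_grad(theta + e)[0] - m.logp_and_grad(theta - e)[0]) / (2 * h)
        assert g[k] == pytest.approx(num, rel=1e-4, abs=1e-6)


def test_student_t_likelihood_matches_scipy(rng):
    """The likelihood term agrees with scipy's Student-t density."""
    y = simulate_dataset(rng, b=[0.1, 0.4], R=3, S=3)
    m = StudentTMultilevel(y)
    theta = m.initial_value(rng)
    con = m.constrain(theta)
    mu = (con["b"][:, None, None] + con["xi"][:, None, :] + con["eta"][:, :, None]
          + con["gamma"][None, :, :])
    oracle_ll = stats.t.logpdf(y, df=float(con["nu"]), loc=mu, scale=float(con["sigma"])).sum()
    # subtract the analytic prior terms by comparing two sigma values
    lp, _ = m.logp_and_grad(theta)
    theta2 = theta.copy()
    theta2[m.layout.slices["log_sigma"]] += 0.1
    con2 = m.constrain(theta2)
    oracle_ll2 = stats.t.logpdf(y, df=float(con2["nu"]), loc=mu, scale=float(con2["sigma"])).sum()
    lp2, _ = m.logp_and_grad(theta2)
    prior_delta = (
        -np.log1p((con2["sigma"] / m.sigma_scale) ** 2) + np.log(con2["sigma"])
        + np.log1p((con["sigma"] / m.sigma_scale) ** 2) - np.log(con["sigma"])
    )
    assert (lp2 - lp) == pytest.approx((oracle_ll2 - oracle_ll) + prior_delta, abs=1e-8)


@given(st.lists(st.floats(-3, 3), min_size=3, max_size=3))
@settings(max_examples=30, deadline=None)
def test_cpc_cholesky_produces_valid_correlation(xs):
    L = cpc_to_cholesky(np.tanh(np.asarray(xs)), 3)
    R = L @ L.T
    assert np.allclose(np.diag(R), 1.0, atol=1e-12)
    assert np.all(np.linalg.eigvalsh(R) > -1e-12)
    assert np.all(np.abs(R) <= 1 + 1e-12)


def test_model_input_validation(rng):
    y = simulate_dataset(rng, b=[0.1, 0.2], R=3, S=3)
    with pytest.raises(ValueError, match="single subject"):
        StudentTMultilevel(y[:, :, :1])
    with pytest.raises(ValueError, match="2 conditions"):
        StudentTMultilevel(y[:1])
    with pytest.raises(ValueError, match="chains"):
        fit_bml(y, chains=1)


# -- sampler -----------------------------------------------------------------


def test_nuts_recovers_correlated_gaussian(rng):
    A = rng.standard_normal((4, 4))
    cov = A @ A.T + 4 * np.eye(4)
    prec = np.linalg.inv(cov)
    mean = np.array([1.0, -2.0, 0.5, 3.0])

    def lg(x):
        d = x - mean
        return float(-0.5 * d @ prec @ d), -prec @ d

    draws = np.concatenate([
        nuts_sample(lg, rng.standard_normal(4), 400, 1200, np.random.default_rng(i))[0]
        for i in range(2)
    ])
    assert np.allclose(draws.mean(axis=0), mean, atol=0.15)
    assert np.allclose(np.cov(draws.T), cov, atol=0.15 * np.abs(cov).max())


def test_diagnostics_iid_vs_disjoint_chains(rng):
    from lamina.bml import BmlPosterior

    iid = rng.standard_normal((4, 1000))
    disjoint = np.stack([np.full(1000, 10.0) + rng.standard_normal(1000) * 0.1,
                         np.full(1000, -10.0) + rng.standard_normal(1000) * 0.1])

    def mini_posterior(arr):
        return BmlPosterior(draws={"x": arr}, conditions=[], regions=[], subjects=[],
                            likelihood="normal", seed=0, n_warmup=0)

    d = diagnostics(mini_posterior(iid))
    assert d.rhat.iloc[0] < 1.01
    assert d.ess.iloc[0] == pytest.approx(4000, rel=0.2)  # i.i.d. ESS ~ draw count
    d2 = diagnostics(mini_posterior(disjoint))
    assert d2.rhat.iloc[0] > 1.5
    with pytest.raises(ValueError, match="2 chains"):
        diagnostics(mini_posterior(iid[:1]))


def test_normal_limit_agrees_with_student_t_at_large_nu(rng):
    """With Gaussian data, the Student-t and Gaussian fits of the same
    structure give matching population effects within Monte-Carlo error."""
    y = simulate_dataset(rng, b=[0.2, 0.6], R=5, S=6, nu=np.inf, sigma=0.1)
    post_t = fit_bml(y, chains=2, iterations=500, seed=1, check_convergence=False)
    post_n = fit_bml(y, chains=2, iterations=500, seed=2, likelihood="normal",
                     check_convergence=False)
    bt, bn = post_t.flat("b"), post_n.flat("b")
    for c in range(2):
        mc = np.sqrt(bt[:, c].var() / 200 + bn[:, c].var() / 200)
        assert abs(bt[:, c].mean() - bn[:, c].mean()) < 6 * mc + 0.01


# -- derived quantities ------------------------------------------------------


def test_modulation_index_values_and_bounds(rng):
    assert modulation_index(np.array([1.0]), np.array([0.5]))[0] == pytest.approx(1 / 3)
    assert modulation_index(np.array([1.0]), np.array([-1.0]))[0] == pytest.approx(1.0)
    assert modulation_index(np.array([-1.0]), np.array([1.0]))[0] == pytest.approx(-1.0)
    x = rng.standard_normal(500)
    assert np.allclose(modulation_index(x, x), 0.0)
    a, b = rng.standard_normal(500), rng.standard_normal(500)
    idx = modulation_index(a, b)
    assert np.all(np.abs(idx) <= 1.0)
    assert np.allclose(idx, -modulation_index(b, a))  # antisymmetry
    with pytest.raises(ValueError, match="draw counts"):
        modulation_index(np.zeros(3), np.zeros(4))
    with pytest.warns(UserWarning, match="C1 = C2 = 0"):
        out = modulation_index(np.zeros(1), np.zeros(1))
    assert out[0] == 0.0


def test_posterior_positive_prob(rng):
    assert posterior_positive_prob(np.ones(200)) == 1.0
    sym = np.concatenate([rng.standard_normal(5000), -rng.standard_normal(5000)])
    assert posterior_positive_prob(sym) == pytest.approx(0.5, abs=0.02)
    with pytest.raises(ValueError, match="100 draws"):
        posterior_positive_prob(np.ones(50))


def test_posterior_predictive_self_consistency_and_outlier(rng):
    y = simulate_dataset(rng, b=[0.2, 0.6], R=5, S=6, nu=30.0, sigma=0.1)
    post = fit_bml(y, chains=2, iterations=400, seed=5, check_convergence=False)
    ppc = posterior_predictive_check(post, y, n_replicates=150, seed=0)
    # observed per-condition means inside the central 95% of replicate means
    assert np.all(ppc.observed_mean_quantile > 0.025)
    assert np.all(ppc.observed_mean_quantile < 0.975)
    assert not ppc.outliers.any()
    # gross outlier is flagged and drags the df posterior down
    y_out = y.copy()
    y_out[0, 0, 0] = 100 * y.std()
    post_out = fit_bml(y_out, chains=2, iterations=400, seed=6, check_convergence=False)
    ppc_out = posterior_predictive_check(post_out, y_out, n_replicates=150, seed=0)
    assert ppc_out.outliers[0, 0, 0]
    assert np.median(post_out.flat("nu")) < np.median(post.flat("nu"))
    with pytest.raises(ValueError, match="positive number"):
        posterior_predictive_check(post, y, n_replicates=0)


def test_bml_data_round_trip(rng):
    y = simulate_dataset(rng, b=[0.1, 0.2], R=3, S=4)
    data = BmlData(y=y, conditions=["a", "b"], regions=["r1", "r2", "r3"],
                   subjects=[f"s{i}" for i in range(4)])
    df = data.to_frame()
    back = BmlData.from_frame(df)
    assert np.allclose(back.y, y)
    with pytest.raises(ValueError, match="incomplete"):
        BmlData.from_frame(df.iloc[:-1])
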