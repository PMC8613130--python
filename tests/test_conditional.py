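import dataclasses

import numpy as np
import pytest
from scipy import stats

from smcimpute.conditional import (NormalLevel1Model, NormalLevel2Model,
                                   Priors, cluster_loglik,
                                   gibbs_update_level1, gibbs_update_level2,
                                   init_level1_model, init_level2_model,
                                   loglik_rows)
from smcimpute.data import MultilevelDataset
from smcimpute.formula import parse_formula

from conftest import random_dataset


def _fixed_model(spec, dataset, beta, sigma2, T=None, u=None):
    k = spec.n_random
    T = np.empty((0, 0)) if T is None else np.atleast_2d(T)
    u = np.zeros((dataset.n_clusters, k)) if u is None else u
    return NormalLevel1Model(spec, np.asarray(beta, float), sigma2, T, u)


def test_standard_normal_mode_density():
    ds = MultilevelDataset({"y": np.array([0.7]), "x": np.array([0.7])},
                           np.zeros(1), {"y": 1, "x": 1})
    spec = parse_formula("y ~ 0 + x")
    model = _fixed_model(spec, ds, [1.0], 1.0)  # residual exactly 0
    assert loglik_rows(model, ds) == pytest.approx(-0.5 * np.log(2 * np.pi),
                                                   abs=1e-14)


def test_loglik_matches_scipy_normal_oracle():
    rng = np.random.default_rng(3)
    ds = random_dataset(rng, J=5, n=1)
    spec = parse_formula("y ~ x + z + (1 | cluster)")
    u = rng.standard_normal((5, 1))
    model = _fixed_model(spec, ds, [0.3, -0.2, 0.5], 0.8,
                         T=np.array([[0.2]]), u=u)
    mu = (0.3 - 0.2 * ds.values("x") + 0.5 * ds.values("z")
          + u[ds.codes, 0])
    oracle = stats.norm.logpdf(ds.values("y"), mu, np.sqrt(0.8)).sum()
    assert loglik_rows(model, ds) == pytest.approx(oracle, abs=1e-12)


def test_loglik_symmetric_in_residual_sign():
    spec = parse_formula("y ~ 0 + x")
    for r in (0.4, 1.7):
        vals = []
        for sign in (1, -1):
            ds = MultilevelDataset({"y": np.array([sign * r]),
                                    "x": np.array([0.0])},
                                   np.zeros(1), {"y": 1, "x": 1})
            vals.append(loglik_rows(_fixed_model(spec, ds, [1.0], 0.7), ds))
        assert vals[0] == pytest.approx(vals[1], abs=1e-14)


def test_loglik_additive_over_clusters():
    rng = np.random.default_rng(5)
    ds = random_dataset(rng, J=4, n=3)
    spec = parse_formula("y ~ x + (1 | cluster)")
    model = _fixed_model(spec, ds, [0.1, 0.2], 1.3, T=np.array([[0.3]]),
                         u=rng.standard_normal((4, 1)))
    total = loglik_rows(model, ds)
    parts = sum(loglik_rows(model, ds, clusters=[j]) for j in range(4))
    assert total == pytest.approx(parts, abs=1e-10)
    per_cluster = cluster_loglik(model, ds)
    assert per_cluster.sum() == pytest.approx(total, abs=1e-10)


def test_invalid_variance_and_shapes_rejected():
    spec = parse_formula("y ~ x")
    with pytest.raises(ValueError):
        NormalLevel1Model(spec, np.zeros(2), -1.0, np.empty((0, 0)),
                          np.zeros((1, 0)))
    with pytest.raises(ValueError):
        NormalLevel2Model(parse_formula("z ~ 1", level=2), np.zeros(1), 0.0)
    spec_r = parse_formula("y ~ x + (1 + x | cluster)")
    with pytest.raises(ValueError, match="symmetric"):
        NormalLevel1Model(spec_r, np.zeros(2), 1.0,
                          np.array([[1.0, 0.5], [0.0, 1.0]]), np.zeros((1, 2)))


def test_beta_conditional_matches_conjugate_normal():
    """With random effects absent, the beta draw is N(betahat, s2 (X'X)^-1)."""
    rng = np.random.default_rng(10)
    ds = random_dataset(rng, J=4, n=10)
    spec = parse_formula("y ~ x")
    X = np.column_stack([np.ones(40), ds.values("x")])
    y = ds.values("y")
    betahat = np.linalg.solve(X.T @ X, X.T @ y)
    sigma2 = 0.5
    cov = np.linalg.inv(X.T @ X) * sigma2
    model = _fixed_model(spec, ds, [0.0, 0.0], sigma2)
    draws = np.empty((4000, 2))
    for i in range(draws.shape[0]):
        draws[i] = gibbs_update_level1(model, ds, rng, update=("beta",)).beta
    se = np.sqrt(np.diag(cov) / draws.shape[0])
    np.testing.assert_allclose(draws.mean(axis=0), betahat, atol=4 * se.max())
    np.testing.assert_allclose(np.cov(draws.T), cov, rtol=0.15)


def test_sigma2_conditional_matches_inverse_gamma():
    rng = np.random.default_rng(11)
    ds = random_dataset(rng, J=4, n=10)
    spec = parse_formula("y ~ x")
    beta = np.array([0.2, -0.1])
    model = _fixed_model(spec, ds, beta, 1.0)
    pri = Priors()
    X = np.column_stack([np.ones(40), ds.values("x")])
    rss = float(((ds.values("y") - X @ beta) ** 2).sum())
    shape = pri.var_shape + 20.0
    rate = pri.var_rate + rss / 2.0
    exact_mean = rate / (shape - 1)
    draws = np.array([
        gibbs_update_level1(model, ds, rng, pri, update=("sigma2",)).sigma2
        for _ in range(4000)])
    exact_sd = rate / ((shape - 1) * np.sqrt(shape - 2))
    assert draws.mean() == pytest.approx(
        exact_mean, abs=4 * exact_sd / np.sqrt(len(draws)))


def test_joint_chain_matches_normal_inverse_gamma_posterior():
    """Alternating beta/sigma2 draws target the conjugate NIG posterior."""
    rng = np.random.default_rng(12)
    ds = random_dataset(rng, J=5, n=8)
    spec = parse_formula("y ~ x")
    X = np.column_stack([np.ones(40), ds.values("x")])
    y = ds.values("y")
    betahat = np.linalg.solve(X.T @ X, X.T @ y)
    rss = float(((y - X @ betahat) ** 2).sum())
    pri = Priors()
    # marginal posterior: sigma2 ~ IG(a + (N-p)/2, b + rss/2), E[beta] = betahat
    a = pri.var_shape + (40 - 2) / 2.0
    b = pri.var_rate + rss / 2.0
    model = _fixed_model(spec, ds, [0.0, 0.0], 1.0)
    betas, sig2s = [], []
    for t in range(6000):
        model = gibbs_update_level1(model, ds, rng, pri,
                                    update=("beta", "sigma2"))
        if t >= 500:
            betas.append(model.beta)
            sig2s.append(model.sigma2)
    betas = np.asarray(betas)
    np.testing.assert_allclose(betas.mean(axis=0), betahat, atol=0.06)
    assert np.mean(sig2s) == pytest.approx(b / (a - 1), rel=0.08)


def test_level2_zero_residual_concentrates_on_exact_solution():
    J = 12
    z = np.linspace(-1, 1, J)
    w = 0.5 + 2.0 * z  # exact linear relation, no noise
    ds = MultilevelDataset({"z": np.repeat(z, 2), "w": np.repeat(w, 2)},
                           np.repeat(np.arange(J), 2), {"z": 2, "w": 2})
    spec = parse_formula("w ~ z", level=2)
    model = init_level2_model(spec)
    rng = np.random.default_rng(4)
    for _ in range(300):
        model = gibbs_update_level2(model, ds, rng)
    assert model.sigma2 < 1e-3
    np.testing.assert_allclose(model.gamma, [0.5, 2.0], atol=0.01)


def test_level2_intercept_only_posterior_mean_is_grand_mean():
    rng = np.random.default_rng(6)
    J = 30
    w = rng.standard_normal(J)
    ds = MultilevelDataset({"w": np.repeat(w, 2)},
                           np.repeat(np.arange(J), 2), {"w": 2})
    spec = parse_formula("w ~ 1", level=2)
    model = init_level2_model(spec)
    draws = []
    for t in range(4000):
        model = gibbs_update_level2(model, ds, rng)
        if t >= 200:
            draws.append(model.gamma[0])
    se = w.std(ddof=1) / np.sqrt(J)
    assert np.mean(draws) == pytest.approx(w.mean(), abs=4 * se / np.sqrt(30))


def test_same_seed_bit_identical_updates():
    ds = random_dataset(np.random.default_rng(8), J=5, n=6)
    spec = parse_formula("y ~ x + z + (1 + x | cluster)")
    model = init_level1_model(spec, ds)
    out = []
    for _ in range(2):
        rng = np.random.default_rng(123)
        m = model
        for _ in range(5):
            m = gibbs_update_level1(m, ds, rng)
        out.append(m)
    np.testing.assert_array_equal(out[0].beta, out[1].beta)
    np.testing.assert_array_equal(out[0].T, out[1].T)
    np.testing.assert_array_equal(out[0].u, out[1].u)
    assert out[0].sigma2 == out[1].sigma2

    spec2 = parse_formula("z ~ 1", level=2)
    g = []
    for _ in range(2):
        rng = np.random.default_rng(9)
        m2 = init_level2_model(spec2)
        for _ in range(5):
            m2 = gibbs_update_level2(m2, ds, rng)
        g.append(m2)
    np.testing.assert_array_equal(g[0].gamma, g[1].gamma)
    assert g[0].sigma2 == g[1].sigma2


def test_parameter_recovery_from_simulated_mixed_model():
    """Posterior means recover generating values on a J=150, n=15 dataset."""
    rng = np.random.default_rng(42)
    J, n = 150, 15
    codes = np.repeat(np.arange(J), n)
    x = rng.standard_normal(J * n)
    z = np.repeat(rng.standard_normal(J), n)
    u0 = 0.4 * rng.standard_normal(J)
    u1 = 0.3 * rng.standard_normal(J)
    y = (0.5 + 0.8 * x - 0.4 * z + u0[codes] + u1[codes] * x
         + 0.7 * rng.standard_normal(J * n))
    ds = MultilevelDataset({"x": x, "z": z, "y": y}, codes,
                           {"x": 1, "z": 2, "y": 1})
    spec = parse_formula("y ~ x + z + (1 + x | cluster)")
    model = init_level1_model(spec, ds)
    betas, t11 = [], []
    for t in range(600):
        model = gibbs_update_level1(model, ds, rng)
        if t >= 200:
            betas.append(model.beta)
            t11.append(model.T[1, 1])
    bmean = np.mean(betas, axis=0)
    np.testing.assert_allclose(bmean, [0.5, 0.8, -0.4], atol=0.1)
    assert np.mean(t11) == pytest.approx(0.09, abs=0.05)


def test_degenerate_singleton_clusters_are_allowed():
    rng = np.random.default_rng(13)
    ds = random_dataset(rng, J=8, n=1)
    spec = parse_formula("y ~ x + (1 | cluster)")
    model = init_level1_model(spec, ds)
    for _ in range(20):
        model = gibbs_update_level1(model, ds, rng)
    assert np.isfinite(model.sigma2) and np.isfinite(model.T).all()
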