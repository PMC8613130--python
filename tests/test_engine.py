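import logging

import numpy as np
import pytest
from scipy import stats

import smcimpute.engine as engine
from smcimpute.conditional import NormalLevel1Model
from smcimpute.data import MultilevelDataset
from smcimpute.engine import (ImputationSet, SamplerControls, SamplerState,
                              SequenceSpec, SMCImputer, adapt_proposals,
                              default_sequence_order, initialize_missing,
                              mh_log_ratio, mh_step, rhat, run_smc)
from smcimpute.formula import parse_formula

from conftest import random_dataset


def _sequence(x_formula="x ~ z + (1 | cluster)",
              y_formula="y ~ x + z + x:z + (1 + x | cluster)"):
    return SequenceSpec((parse_formula(x_formula),), parse_formula(y_formula))


def _make_state(dataset, sequence=None, seed=0, **controls):
    sequence = sequence or _sequence()
    ctl = SamplerControls(**{"burn_in": 10, "n_between": 2, "m": 2, **controls})
    return SamplerState(dataset, sequence, ctl, np.random.default_rng(seed))


# -- sequence validity -------------------------------------------------------

def test_sequence_rejects_conditioning_on_later_variable(incomplete_dataset):
    bad = SequenceSpec(
        (parse_formula("z ~ x", level=2), parse_formula("x ~ z + (1|cluster)")),
        parse_formula("y ~ x + z"))
    with pytest.raises(ValueError, match="later in the sequence"):
        bad.validate(incomplete_dataset)


def test_sequence_rejects_outcome_as_covariate_predictor(incomplete_dataset):
    bad = SequenceSpec((parse_formula("x ~ y + z + (1|cluster)"),),
                       parse_formula("y ~ x + z"))
    with pytest.raises(ValueError, match="conditions on the"):
        bad.validate(incomplete_dataset)


def test_sequence_requires_model_for_incomplete_variable(incomplete_dataset):
    bad = SequenceSpec((), parse_formula("y ~ x + z"))
    with pytest.raises(ValueError, match="owns no conditional model"):
        bad.validate(incomplete_dataset)


def test_default_sequence_order(incomplete_dataset):
    # level-2 variables first, then ascending missingness
    ds = incomplete_dataset.copy()
    models = [parse_formula("x ~ z + (1|cluster)"),
              parse_formula("z ~ 1", level=2)]
    ordered = default_sequence_order(ds, models)
    assert [m.outcome for m in ordered] == ["z", "x"]


# -- initialization ----------------------------------------------------------

def test_initialize_missing_identity_when_complete(toy_dataset):
    rng = np.random.default_rng(0)
    out = initialize_missing(toy_dataset, rng)
    for v in toy_dataset.variables:
        np.testing.assert_array_equal(out.values(v), toy_dataset.values(v))


def test_initialize_missing_seeded_and_fills_all(incomplete_dataset):
    a = initialize_missing(incomplete_dataset, np.random.default_rng(5))
    b = initialize_missing(incomplete_dataset, np.random.default_rng(5))
    assert not np.isnan(a.values("x")).any()
    np.testing.assert_array_equal(a.values("x"), b.values("x"))
    obs = ~incomplete_dataset.mask("x")
    np.testing.assert_array_equal(a.values("x")[obs],
                                  incomplete_dataset.values("x")[obs])


def test_initialize_missing_all_missing_column_errors():
    ds = MultilevelDataset({"x": np.full(4, np.nan), "y": np.ones(4)},
                           np.repeat([0, 1], 2), {"x": 1, "y": 1})
    with pytest.raises(ValueError, match="no observed cells"):
        initialize_missing(ds, np.random.default_rng(0))


# -- MH ratio ----------------------------------------------------------------

def test_mh_log_ratio_zero_for_identity_proposal(incomplete_dataset):
    state = _make_state(incomplete_dataset)
    current = state.data.values("x")[incomplete_dataset.mask("x")
                                     & (state.data.codes == 0)]
    assert mh_log_ratio(state, 0, "x", current) == pytest.approx(0.0, abs=1e-12)


def test_mh_log_ratio_errors(incomplete_dataset):
    state = _make_state(incomplete_dataset)
    with pytest.raises(ValueError, match="not flagged incomplete"):
        mh_log_ratio(state, 0, "y", np.array([0.0]))
    complete = incomplete_dataset.copy()
    complete._mask["x"][:] = False
    complete._values["x"][np.isnan(complete._values["x"])] = 0.0
    seq = _sequence()
    st_ok = _make_state(incomplete_dataset)
    # cluster with no missing cells for x
    ds2 = incomplete_dataset.copy()
    ds2._mask["x"][4:] = False
    ds2._values["x"][6] = 0.1
    state2 = SamplerState(ds2, seq, SamplerControls(burn_in=5, n_between=2, m=2),
                          np.random.default_rng(0))
    with pytest.raises(ValueError, match="no missing cells"):
        mh_log_ratio(state2, 1, "x", np.array([0.0]))


def test_mh_log_ratio_reduces_to_own_model_when_variable_unused():
    """If q predicts nothing later and is not the outcome, the ratio is its
    own conditional model's log-density difference."""
    rng = np.random.default_rng(3)
    ds = random_dataset(rng, J=3, n=4, missing_frac=0.3)
    seq = SequenceSpec((parse_formula("x ~ z + (1 | cluster)"),),
                       parse_formula("y ~ z"))
    state = _make_state(ds, seq)
    from smcimpute.conditional import loglik_rows
    j = int(state.miss_clusters["x"][0])
    sel = ds.mask("x") & (ds.codes == j)
    prop = state.data.values("x")[sel] + 0.7
    ratio = mh_log_ratio(state, j, "x", prop)
    model = state.models[0]
    before = loglik_rows(model, state.data, clusters=[j])
    saved = state.data._values["x"][sel].copy()
    state.data._values["x"][sel] = prop
    after = loglik_rows(model, state.data, clusters=[j])
    state.data._values["x"][sel] = saved
    assert ratio == pytest.approx(after - before, abs=1e-12)


def test_mh_log_ratio_matches_brute_force_density_product():
    """2-row single-cluster toy, one missing x cell, fixed parameters: the
    log ratio equals the difference of hand-computed normal density
    products with the cluster mean recomputed under the proposal."""
    ds = MultilevelDataset(
        {"x": np.array([0.8, np.nan]), "z": np.array([0.5, 0.5]),
         "y": np.array([1.1, -0.4])},
        np.zeros(2), {"x": 1, "z": 2, "y": 1})
    seq = SequenceSpec(
        (parse_formula("x ~ z + (1 | cluster)"),),
        parse_formula("y ~ x + cmean(x) + x:z"))
    state = _make_state(ds, seq, seed=7)
    # overwrite fitted models with fixed parameters
    bx = np.array([0.1, 0.4])
    ux = np.array([[0.3]])
    state.models[0] = NormalLevel1Model(seq.covariate_models[0], bx, 0.6,
                                        np.array([[0.2]]), ux)
    by = np.array([0.2, 0.7, -0.5, 0.3])
    state.models[1] = NormalLevel1Model(seq.outcome_model, by, 0.9,
                                        np.empty((0, 0)), np.zeros((1, 0)))
    x_obs, z, y = 0.8, 0.5, np.array([1.1, -0.4])

    def brute(x_miss):
        x = np.array([x_obs, x_miss])
        xbar = x.mean()
        ll = stats.norm.logpdf(x, 0.1 + 0.4 * z + 0.3, np.sqrt(0.6)).sum()
        mu_y = 0.2 + 0.7 * x - 0.5 * xbar + 0.3 * x * z
        ll += stats.norm.logpdf(y, mu_y, np.sqrt(0.9)).sum()
        return ll

    cur = float(state.data.values("x")[1])
    prop = 0.25
    expected = brute(prop) - brute(cur)
    assert mh_log_ratio(state, 0, "x", np.array([prop])) == \
        pytest.approx(expected, abs=1e-10)


# -- MH step -----------------------------------------------------------------

def test_mh_step_always_accepts_nonnegative_log_ratio(incomplete_dataset,
                                                      monkeypatch):
    state = _make_state(incomplete_dataset)
    monkeypatch.setattr(engine, "mh_log_ratio",
                        lambda *a, **k: 0.0)
    rng = np.random.default_rng(1)
    assert all(mh_step(state, 0, "x", rng) for _ in range(200))


def test_mh_step_acceptance_frequency_matches_fixed_ratio(incomplete_dataset,
                                                          monkeypatch):
    M = 0.3
    state = _make_state(incomplete_dataset)
    monkeypatch.setattr(engine, "mh_log_ratio",
                        lambda *a, **k: float(np.log(M)))
    rng = np.random.default_rng(2)
    n = 20_000
    acc = sum(mh_step(state, 0, "x", rng) for _ in range(n))
    se = np.sqrt(M * (1 - M) / n)
    assert acc / n == pytest.approx(M, abs=3 * se)


def test_observed_cells_immutable_through_steps(incomplete_dataset):
    state = _make_state(incomplete_dataset)
    obs = ~incomplete_dataset.mask("x")
    before = state.data.values("x")[obs].copy()
    rng = np.random.default_rng(3)
    for _ in range(50):
        for j in state.miss_clusters["x"]:
            mh_step(state, int(j), "x", rng)
    np.testing.assert_array_equal(state.data.values("x")[obs], before)


# -- adaptation --------------------------------------------------------------

def test_adaptation_monotone_and_frozen(incomplete_dataset, caplog):
    state = _make_state(incomplete_dataset, burn_in=100)
    jm = state.miss_clusters["x"]
    base = state.scales["x"].copy()
    state.win_attempts["x"][jm] = 20
    state.win_accepts["x"][jm] = 20          # acceptance 1.0 -> scale up
    adapt_proposals(state)
    miss = incomplete_dataset.mask("x")
    assert np.all(state.scales["x"][miss] > base[miss])

    up = state.scales["x"].copy()
    state.win_attempts["x"][jm] = 20
    state.win_accepts["x"][jm] = 0           # acceptance 0.0 -> scale down
    adapt_proposals(state)
    assert np.all(state.scales["x"][miss] < up[miss])

    state.frozen = True
    frozen_scales = state.scales["x"].copy()
    state.win_attempts["x"][jm] = 20
    state.win_accepts["x"][jm] = 20
    with caplog.at_level(logging.WARNING, logger="smcimpute"):
        adapt_proposals(state)
    assert "ignored" in caplog.text
    np.testing.assert_array_equal(state.scales["x"], frozen_scales)


# -- R-hat -------------------------------------------------------------------

def test_rhat_identical_chains_is_one():
    c = np.tile(np.sin(np.arange(100.0)), (3, 1))
    assert rhat(c) == 1.0


def test_rhat_disjoint_chains_is_large():
    chains = np.stack([np.random.default_rng(0).normal(0, 1, 200),
                       np.random.default_rng(1).normal(50, 1, 200)])
    assert rhat(chains) > 10


def test_rhat_matches_textbook_formula_on_fixed_chains():
    rng = np.random.default_rng(9)
    chains = rng.standard_normal((2, 80)) + np.array([[0.0], [0.4]])
    # independent hand computation: split each chain in half, then the
    # usual between/within variance ratio
    split = np.concatenate([chains[:, :40], chains[:, 40:]], axis=0)
    L = 40
    W = split.var(axis=1, ddof=1).mean()
    B = L * split.mean(axis=1).var(ddof=1)
    expected = np.sqrt(((L - 1) / L * W + B / L) / W)
    assert rhat(chains) == pytest.approx(float(expected), abs=1e-10)


# -- full runs ---------------------------------------------------------------

def test_complete_data_returns_identical_copies(toy_dataset):
    seq = _sequence()
    ctl = SamplerControls(burn_in=20, n_between=5, m=3, seed=0)
    res = run_smc(toy_dataset, seq, ctl)
    assert res.m == 3
    for d in res.datasets:
        for v in toy_dataset.variables:
            np.testing.assert_array_equal(d.values(v), toy_dataset.values(v))


def test_same_seed_identical_imputation_sets(incomplete_dataset):
    seq = _sequence()
    ctl = SamplerControls(burn_in=30, n_between=5, m=3, seed=11)
    r1 = run_smc(incomplete_dataset, seq, ctl)
    r2 = run_smc(incomplete_dataset, seq, ctl)
    for d1, d2 in zip(r1.datasets, r2.datasets):
        for v in d1.variables:
            np.testing.assert_array_equal(d1.values(v), d2.values(v))
    assert r1.acceptance == r2.acceptance
    assert r1.rhat == r2.rhat


def test_run_preserves_observed_cells_and_shapes(incomplete_dataset):
    seq = _sequence()
    ctl = SamplerControls(burn_in=30, n_between=5, m=4, seed=2)
    res = run_smc(incomplete_dataset, seq, ctl)
    obs = ~incomplete_dataset.mask("x")
    for d in res.datasets:
        assert not np.isnan(d.values("x")).any()
        np.testing.assert_array_equal(d.values("x")[obs],
                                      incomplete_dataset.values("x")[obs])
    assert set(res.acceptance) == {"x"}
    assert all(v >= 1.0 for v in res.rhat.values())


def test_imputer_estimator_interface(incomplete_dataset):
    from sklearn.base import clone
    imp = SMCImputer(formulas=["x ~ z + (1 | cluster)",
                               "y ~ x + z + (1 + x | cluster)"],
                     burn_in=20, n_between=4, m=2, seed=3)
    clone(imp)  # sklearn get_params/set_params contract
    stacked = imp.fit_transform(incomplete_dataset.to_frame())
    assert ".imp" in stacked.columns
    assert sorted(stacked[".imp"].unique()) == [0, 1, 2]
    orig = stacked[stacked[".imp"] == 0]
    assert orig["x"].isna().sum() == 2
    assert stacked[stacked[".imp"] > 0]["x"].notna().all()
    assert imp.n_imputations_ == 2
    assert "acceptance_rates" in imp.diagnostics_


def test_imputer_requires_fit_before_transform():
    imp = SMCImputer(formulas=["y ~ x"])
    with pytest.raises(RuntimeError):
        imp.transform(None)
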