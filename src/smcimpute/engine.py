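"""Sequential-modeling MCMC engine for substantive-model-compatible MI.

The joint distribution of the analysis variables is factorized into an
ordered sequence of conditional models — one per (incomplete) explanatory
variable, each conditioning only on variables placed earlier — closed by
the substantive outcome model.  Each iteration

1. Gibbs-updates every model's parameters given the current completed data,
2. draws Metropolis-Hastings replacements for the missing cells of every
   incomplete variable.

The MH ratio for variable q multiplies the density contributions of q's
own conditional model and of every later model in which q appears as a
predictor (directly or through a derived term), with all cluster means,
deviations, interactions and powers recomputed under the proposal.  When
q reaches a model through an aggregated score (cluster mean, deviation,
or a cluster-level model), all missing cells of a cluster are proposed
and accepted jointly — changing one value moves the cluster mean and
hence the posterior of every other value in the cluster.  When every
relevant model references q only through row-local terms, the density
factorizes by row and cells are accepted individually, which also lets
the chain move between the separated posterior branches created by even
powers of q.  Proposals mix per-cell Gaussian random-walk steps with
independence draws from q's own conditional model; both kernels preserve
the target.

Random-walk scales are adapted multiplicatively during burn-in to steer
per-(variable, cluster) acceptance into a target band and are frozen
afterwards, so the post-burn-in chain is a fixed-kernel MH sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .conditional import (NormalLevel1Model, NormalLevel2Model, Priors,
                          cluster_loglik, gibbs_update_level1,
                          gibbs_update_level2, init_level1_model,
                          init_level2_model, predict_mean)
from .data import ModelSpec, MultilevelDataset

__all__ = [
    "SequenceSpec",
    "SamplerControls",
    "SamplerState",
    "ImputationSet",
    "initialize_missing",
    "mh_log_ratio",
    "mh_step",
    "adapt_proposals",
    "run_smc",
    "rhat",
    "default_sequence_order",
    "SMCImputer",
]

logger = logging.getLogger("smcimpute")


@dataclass(frozen=True)
class SequenceSpec:
    """Ordered covariate models followed by the outcome/substantive model."""

    covariate_models: tuple[ModelSpec, ...]
    outcome_model: ModelSpec

    @property
    def models(self) -> tuple[ModelSpec, ...]:
        return self.covariate_models + (self.outcome_model,)

    def validate(self, dataset: MultilevelDataset) -> None:
        """Enforce the triangular structure of the sequence."""
        outcome = self.outcome_model.outcome
        modelled = [m.outcome for m in self.covariate_models]
        if len(set(modelled)) != len(modelled):
            raise ValueError("a variable owns more than one conditional model")
        if outcome in modelled:
            raise ValueError("the outcome cannot also own a covariate model")
        unmodelled = [v for v in dataset.variables
                      if v not in modelled and v != outcome]
        for v in unmodelled:
            if dataset.n_missing(v):
                raise ValueError(
                    f"incomplete variable {v!r} owns no conditional model")
        allowed = set(unmodelled)
        for m in self.covariate_models:
            for v in m.predictor_variables:
                if v == outcome:
                    raise ValueError(
                        f"covariate model for {m.outcome!r} conditions on the "
                        f"outcome {outcome!r}")
                if v == m.outcome:
                    raise ValueError(
                        f"model for {m.outcome!r} conditions on itself")
                if v not in allowed:
                    raise ValueError(
                        f"model for {m.outcome!r} conditions on {v!r}, which is "
                        f"placed later in the sequence")
            allowed.add(m.outcome)
        for v in self.outcome_model.predictor_variables:
            if v == outcome:
                raise ValueError("the outcome model conditions on itself")
            if v not in allowed:
                raise ValueError(f"outcome model uses unknown variable {v!r}")


def default_sequence_order(dataset: MultilevelDataset,
                           models: list[ModelSpec]) -> list[ModelSpec]:
    """Default ordering: level-2 variables before level-1, then ascending
    percentage of missing data (conditional models for the easier, more
    complete variables come first)."""
    def key(m: ModelSpec):
        frac = dataset.n_missing(m.outcome) / dataset.n_rows
        return (0 if dataset.level(m.outcome) == 2 else 1, frac)
    return sorted(models, key=key)


@dataclass(frozen=True)
class SamplerControls:
    burn_in: int = 2000
    n_between: int = 100
    m: int = 10
    adapt_every: int = 25
    accept_band: tuple[float, float] = (0.3, 0.6)
    indep_prob: float = 0.5
    seed: int | None = None
    priors: Priors = field(default_factory=Priors)

    def __post_init__(self):
        if self.burn_in < 0 or self.n_between < 1 or self.m < 1:
            raise ValueError("controls must be positive")
        lo, hi = self.accept_band
        if not (0 < lo < hi < 1):
            raise ValueError("accept_band must satisfy 0 < lo < hi < 1")
        if not (0 <= self.indep_prob < 1):
            raise ValueError("indep_prob must lie in [0, 1)")


def initialize_missing(dataset: MultilevelDataset, rng: np.random.Generator,
                       method: str = "regression") -> MultilevelDataset:
    """Fill missing cells with starting draws; returns a completed copy.

    ``method="regression"`` (default) draws each missing cell from the
    complete-case linear regression of the variable on every fully
    observed variable (including the outcome).  Conditioning the start
    values on the observed outcome matters: when a later model depends on
    the variable through an even power, the posterior has well-separated
    branches, and a start ignoring y can place whole clusters on the
    wrong branch, which random-walk and model-based proposals alike take
    very long to leave.  ``method="moments"`` falls back to draws from the
    variable's observed-cell mean/SD normal (also used when no complete
    covariates exist).
    """
    if method not in ("regression", "moments"):
        raise ValueError(f"unknown initialization method {method!r}")
    out = dataset.copy()
    complete = [v for v in out.variables if not dataset.mask(v).any()]
    for name in out.variables:
        m = out.mask(name)
        if not m.any():
            continue
        col = out._values[name]
        obs = ~m
        if not obs.any():
            raise ValueError(f"variable {name!r} has no observed cells")
        mu_fill = None
        if method == "regression" and complete:
            X = np.column_stack(
                [np.ones(out.n_rows)] + [out._values[v] for v in complete])
            coefs, *_ = np.linalg.lstsq(X[obs], col[obs], rcond=None)
            fitted = X @ coefs
            resid_sd = float(np.std(col[obs] - fitted[obs]))
            if np.isfinite(resid_sd):
                mu_fill, sd = fitted, resid_sd
        if mu_fill is None:
            mu_fill = np.full(out.n_rows, float(col[obs].mean()))
            sd = float(col[obs].std())
        if out.level(name) == 2:
            miss_clusters = np.unique(out.codes[m])
            mu_pc = out.cluster_mean(mu_fill)
            draws = mu_pc[miss_clusters] + sd * \
                rng.standard_normal(len(miss_clusters))
            per_cluster = np.zeros(out.n_clusters)
            per_cluster[miss_clusters] = draws
            col[m] = per_cluster[out.codes][m]
        else:
            col[m] = mu_fill[m] + sd * rng.standard_normal(int(m.sum()))
    return out


class SamplerState:
    """Mutable state of the sampler: completed data, fitted conditional
    models, per-cell proposal scales and acceptance counters."""

    def __init__(self, dataset: MultilevelDataset, sequence: SequenceSpec,
                 controls: SamplerControls, rng: np.random.Generator):
        sequence.validate(dataset)
        self.original = dataset
        self.sequence = sequence
        self.controls = controls
        self.data = initialize_missing(dataset, rng)
        self.iteration = 0
        self.frozen = controls.burn_in == 0

        self.models: list = []
        for spec in sequence.models:
            if dataset.level(spec.outcome) == 1:
                self.models.append(init_level1_model(spec, dataset))
            else:
                self.models.append(init_level2_model(spec))

        self.incomplete = [m.outcome for m in sequence.models
                           if dataset.n_missing(m.outcome)]
        # models whose density involves variable q: its own model plus every
        # later model referencing q as a predictor
        self.eval_models: dict[str, list[int]] = {}
        self.own_model: dict[str, int] = {}
        specs = sequence.models
        for q in self.incomplete:
            own = next(i for i, s in enumerate(specs) if s.outcome == q)
            idx = [own] + [i for i in range(own + 1, len(specs))
                           if q in specs[i].predictor_variables]
            self.eval_models[q] = idx
            self.own_model[q] = own

        # whole-cluster joint acceptance is required only when q reaches a
        # model through an aggregated score (cluster mean / deviation) or
        # through a cluster-level model; otherwise the density factorizes
        # by row and per-cell acceptance is valid (and mixes much better,
        # e.g. across the twin modes of quadratic outcome terms)
        self.cluster_coupled: dict[str, bool] = {}
        for q in self.incomplete:
            if dataset.level(q) == 2:
                self.cluster_coupled[q] = True
                continue
            coupled = False
            for i in self.eval_models[q][1:]:
                spec = specs[i]
                if dataset.level(spec.outcome) == 2:
                    coupled = True
                    break
                for t in spec.terms + spec.random_terms:
                    for f in t.factors:
                        if f[0] == q and f[1] in ("cluster_mean",
                                                  "within_deviation"):
                            coupled = True
            self.cluster_coupled[q] = coupled

        self.scales: dict[str, np.ndarray] = {}
        self.miss_clusters: dict[str, np.ndarray] = {}
        self.accepts: dict[str, np.ndarray] = {}
        self.attempts: dict[str, np.ndarray] = {}
        self.win_accepts: dict[str, np.ndarray] = {}
        self.win_attempts: dict[str, np.ndarray] = {}
        for q in self.incomplete:
            mask = dataset.mask(q)
            obs_sd = float(np.nanstd(dataset.values(q)[~mask]))
            init = 0.5 * obs_sd if obs_sd > 0 else 0.1
            if dataset.level(q) == 2:
                self.scales[q] = np.full(dataset.n_clusters, init)
            else:
                self.scales[q] = np.full(dataset.n_rows, init)
            self.miss_clusters[q] = np.unique(dataset.codes[mask])
            J = dataset.n_clusters
            self.accepts[q] = np.zeros(J)
            self.attempts[q] = np.zeros(J)
            self.win_accepts[q] = np.zeros(J)
            self.win_attempts[q] = np.zeros(J)

    # -- likelihood bookkeeping ---------------------------------------------
    def _model_cluster_loglik(self, indices) -> np.ndarray:
        ll = np.zeros(self.data.n_clusters)
        for i in indices:
            ll += cluster_loglik(self.models[i], self.data)
        return ll

    def _cluster_loglik_sum(self, q: str) -> np.ndarray:
        return self._model_cluster_loglik(self.eval_models[q])

    def acceptance_rates(self) -> dict[str, float]:
        out = {}
        for q in self.incomplete:
            att = self.attempts[q][self.miss_clusters[q]]
            acc = self.accepts[q][self.miss_clusters[q]]
            out[q] = float((acc / np.maximum(att, 1)).mean()) if att.sum() else np.nan
        return out


def mh_log_ratio(state: SamplerState, j: int, q: str,
                 proposal: np.ndarray) -> float:
    """Log MH ratio for replacing the missing cells of variable q in
    cluster j by ``proposal`` (posterior-density ratio, Gaussian random-walk
    proposals cancel)."""
    if q not in state.incomplete:
        raise ValueError(f"variable {q!r} is not flagged incomplete")
    mask = state.original.mask(q)
    sel = mask & (state.data.codes == j)
    if state.original.level(q) == 2:
        if j not in state.miss_clusters[q]:
            raise ValueError(f"cluster {j} has no missing cells for {q!r}")
        rows = state.data.codes == j
        proposal = np.broadcast_to(np.asarray(proposal, dtype=float).ravel(),
                                   (int(rows.sum()),))
        sel = rows
    else:
        if not sel.any():
            raise ValueError(f"cluster {j} has no missing cells for {q!r}")
        proposal = np.asarray(proposal, dtype=float)
        if proposal.shape != (int(sel.sum()),):
            raise ValueError("proposal must cover exactly the missing cells")
    col = state.data._values[q]
    cur = col[sel].copy()
    ll_cur = state._cluster_loglik_sum(q)[j]
    col[sel] = proposal
    ll_prop = state._cluster_loglik_sum(q)[j]
    col[sel] = cur
    return float(ll_prop - ll_cur)


def mh_step(state: SamplerState, j: int, q: str, rng: np.random.Generator
            ) -> bool:
    """One whole-cluster MH step for (cluster j, variable q): all proposed
    cells are accepted jointly or none."""
    mask = state.original.mask(q)
    if state.original.level(q) == 2:
        rows = state.data.codes == j
        if j not in state.miss_clusters[q]:
            raise ValueError(f"cluster {j} has no missing cells for {q!r}")
        cur = state.data._values[q][rows][0]
        proposal = cur + state.scales[q][j] * rng.standard_normal()
        sel = rows
        prop_vals = np.full(int(rows.sum()), proposal)
    else:
        sel = mask & (state.data.codes == j)
        if not sel.any():
            raise ValueError(f"cluster {j} has no missing cells for {q!r}")
        cur = state.data._values[q][sel]
        prop_vals = cur + state.scales[q][sel] * rng.standard_normal(cur.shape)
    log_ratio = mh_log_ratio(state, j, q, prop_vals if state.original.level(q) == 1
                             else prop_vals[:1])
    accept = np.log(rng.uniform()) < log_ratio
    if accept:
        state.data._values[q][sel] = prop_vals
    state.attempts[q][j] += 1
    state.win_attempts[q][j] += 1
    if accept:
        state.accepts[q][j] += 1
        state.win_accepts[q][j] += 1
    return bool(accept)


def _mh_sweep(state: SamplerState, q: str, rng: np.random.Generator) -> None:
    """Vectorized MH step for variable q across all clusters with missing
    cells.  Clusters are mutually independent given the parameters, so the
    joint sweep is exactly equivalent to looping over clusters.

    A mixture of two proposal kernels is used (both preserve the target):

    * random walk — per-cell Gaussian steps with adapted scales;
    * independence — whole-cluster draws from q's own conditional model,
      whose density then cancels out of the MH ratio.  This kernel can
      jump between the separated modes that arise when a later model
      depends on q through an even power (e.g. a quadratic outcome term),
      where a random walk would remain trapped on one branch.
    """
    data = state.data
    mask = state.original.mask(q)
    col = data._values[q]
    jm = state.miss_clusters[q]
    use_indep = rng.uniform() < state.controls.indep_prob
    if use_indep:
        mu = predict_mean(state.models[state.own_model[q]], data)
        sd = np.sqrt(state.models[state.own_model[q]].sigma2)
    if data.level(q) == 2:
        per_cluster = data.cluster_mean(col)
        prop_pc = per_cluster.copy()
        if use_indep:
            prop_pc[jm] = mu[jm] + sd * rng.standard_normal(len(jm))
        else:
            prop_pc[jm] = per_cluster[jm] + state.scales[q][jm] * \
                rng.standard_normal(len(jm))
        prop_col = prop_pc[data.codes]
        sel = np.isin(data.codes, jm)
    else:
        prop_col = col.copy()
        nmiss = int(mask.sum())
        if use_indep:
            prop_col[mask] = mu[mask] + sd * rng.standard_normal(nmiss)
        else:
            prop_col[mask] = col[mask] + state.scales[q][mask] * \
                rng.standard_normal(nmiss)
        sel = mask
    eval_idx = state.eval_models[q]
    if use_indep:
        # own-model density cancels against the proposal density
        eval_idx = eval_idx[1:]
    ll_cur = state._model_cluster_loglik(eval_idx)
    saved = col[sel].copy()
    col[sel] = prop_col[sel]
    ll_prop = state._model_cluster_loglik(eval_idx)
    delta = ll_prop[jm] - ll_cur[jm]
    accept = np.log(rng.uniform(size=len(jm))) < delta
    # revert rejected clusters
    rejected = jm[~accept]
    if len(rejected):
        rej_rows = np.isin(data.codes, rejected) & sel
        col[rej_rows] = saved[np.isin(data.codes[sel], rejected)]
    state.attempts[q][jm] += 1
    state.accepts[q][jm] += accept
    if not use_indep:
        # adaptation targets the random-walk kernel only
        state.win_attempts[q][jm] += 1
        state.win_accepts[q][jm] += accept


def _mh_sweep_percell(state: SamplerState, q: str, rng: np.random.Generator
                      ) -> None:
    """Per-cell MH for a level-1 variable that enters every relevant model
    only through row-local terms: each missing cell is accepted or
    rejected on its own row's density ratio.  Uses the same random-walk /
    independence proposal mixture as the cluster-level sweep."""
    from .conditional import row_loglik
    data = state.data
    mask = state.original.mask(q)
    col = data._values[q]
    nmiss = int(mask.sum())
    use_indep = rng.uniform() < state.controls.indep_prob
    if use_indep:
        own = state.models[state.own_model[q]]
        mu = predict_mean(own, data)
        prop = mu[mask] + np.sqrt(own.sigma2) * rng.standard_normal(nmiss)
        eval_idx = state.eval_models[q][1:]
    else:
        prop = col[mask] + state.scales[q][mask] * rng.standard_normal(nmiss)
        eval_idx = state.eval_models[q]

    def rows_ll():
        ll = np.zeros(data.n_rows)
        for i in eval_idx:
            ll += row_loglik(state.models[i], data)
        return ll[mask]

    ll_cur = rows_ll()
    saved = col[mask].copy()
    col[mask] = prop
    ll_prop = rows_ll()
    accept = np.log(rng.uniform(size=nmiss)) < ll_prop - ll_cur
    restore = mask.copy()
    restore[mask] = ~accept
    col[restore] = saved[~accept]

    jm = state.miss_clusters[q]
    cells = np.bincount(data.codes[mask], minlength=data.n_clusters)
    acc = np.bincount(data.codes[mask], accept, minlength=data.n_clusters)
    state.attempts[q] += cells
    state.accepts[q] += acc
    if not use_indep:
        state.win_attempts[q] += cells
        state.win_accepts[q] += acc


def adapt_proposals(state: SamplerState,
                    band: tuple[float, float] | None = None) -> None:
    """Multiplicative (Robbins-Monro flavoured) rescaling of proposal SDs
    toward the target acceptance band; burn-in only, no-op afterwards."""
    if state.frozen:
        logger.warning("adapt_proposals called after burn-in; ignored")
        return
    lo, hi = band if band is not None else state.controls.accept_band
    mid = 0.5 * (lo + hi)
    for q in state.incomplete:
        jm = state.miss_clusters[q]
        att = state.win_attempts[q][jm]
        if not att.sum():
            continue
        rate = state.win_accepts[q][jm] / np.maximum(att, 1)
        factor = np.ones(len(jm))
        outside = (rate < lo) | (rate > hi)
        factor[outside] = np.exp(rate[outside] - mid)
        if state.original.level(q) == 2:
            state.scales[q][jm] *= factor
        else:
            per_cluster = np.ones(state.data.n_clusters)
            per_cluster[jm] = factor
            miss = state.original.mask(q)
            state.scales[q][miss] *= per_cluster[state.data.codes][miss]
        state.win_accepts[q][jm] = 0.0
        state.win_attempts[q][jm] = 0.0


@dataclass
class ImputationSet:
    """m completed datasets plus convergence and acceptance diagnostics."""

    datasets: list[MultilevelDataset]
    rhat: dict[str, float]
    acceptance: dict[str, float]
    controls: SamplerControls
    chains: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def to_stacked_frame(self, original: MultilevelDataset | None = None,
                         cluster_col: str = "cluster",
                         imp_col: str = ".imp") -> pd.DataFrame:
        """Stacked long CSV convention: imputation index 0 is the original
        (with missing cells), 1..m are the completed datasets."""
        frames = []
        if original is not None:
            f0 = original.to_frame(cluster_col)
            f0.insert(0, imp_col, 0)
            frames.append(f0)
        for i, d in enumerate(self.datasets, start=1):
            f = d.to_frame(cluster_col)
            f.insert(0, imp_col, i)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def diagnostics_report(self) -> dict:
        return {
            "m": self.m,
            "burn_in": self.controls.burn_in,
            "n_between": self.controls.n_between,
            "acceptance_rates": {k: round(v, 4) for k, v in self.acceptance.items()},
            "rhat": {k: round(v, 4) for k, v in self.rhat.items()},
            "max_rhat": round(max(self.rhat.values()), 4) if self.rhat else None,
        }


def rhat(chains: np.ndarray) -> float:
    """Potential scale reduction over >= 2 chains (rows), split in half.

    Clipped below at 1.0, so identical chains give exactly 1.0.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_draws) array")
    n = chains.shape[1] // 2
    split = np.concatenate([chains[:, :n], chains[:, n:2 * n]], axis=0)
    L = split.shape[1]
    means = split.mean(axis=1)
    W = split.var(axis=1, ddof=1).mean()
    B = L * means.var(ddof=1)
    if W <= 0:
        return 1.0 if B <= 0 else np.inf
    var_plus = (L - 1) / L * W + B / L
    return float(max(1.0, np.sqrt(var_plus / W)))


def _record_params(state: SamplerState, store: dict[str, list]) -> None:
    for model, spec in zip(state.models, state.sequence.models):
        base = spec.outcome
        if isinstance(model, NormalLevel1Model):
            for name, b in zip(spec.coefficient_names(), model.beta):
                store.setdefault(f"{base}.beta[{name}]", []).append(b)
            store.setdefault(f"{base}.sigma2", []).append(model.sigma2)
            k = spec.n_random
            rnames = spec.random_coefficient_names()
            for a in range(k):
                for c in range(a, k):
                    store.setdefault(
                        f"{base}.T[{rnames[a]},{rnames[c]}]", []
                    ).append(model.T[a, c])
        else:
            for name, g in zip(spec.coefficient_names(), model.gamma):
                store.setdefault(f"{base}.gamma[{name}]", []).append(g)
            store.setdefault(f"{base}.sigma2", []).append(model.sigma2)


def _gibbs_sweep(state: SamplerState, rng: np.random.Generator) -> None:
    priors = state.controls.priors
    for i, model in enumerate(state.models):
        if isinstance(model, NormalLevel1Model):
            state.models[i] = gibbs_update_level1(model, state.data, rng, priors)
        else:
            state.models[i] = gibbs_update_level2(model, state.data, rng, priors)


def run_smc(dataset: MultilevelDataset, sequence: SequenceSpec,
            controls: SamplerControls = SamplerControls(),
            rng: np.random.Generator | None = None) -> ImputationSet:
    """Run the sequential-modeling sampler and return m completed datasets.

    With no missing cells the engine degrades to pure Bayesian estimation of
    the sequence and all returned datasets equal the input.
    """
    if rng is None:
        rng = np.random.default_rng(controls.seed)
    state = SamplerState(dataset, sequence, controls, rng)
    fingerprint = dataset.observed_fingerprint()

    chains: dict[str, list] = {}
    datasets: list[MultilevelDataset] = []
    total = controls.burn_in + controls.n_between * controls.m
    next_save = controls.burn_in + controls.n_between
    for t in range(1, total + 1):
        state.iteration = t
        _gibbs_sweep(state, rng)
        for q in state.incomplete:
            if state.cluster_coupled[q]:
                _mh_sweep(state, q, rng)
            else:
                _mh_sweep_percell(state, q, rng)
        if t <= controls.burn_in:
            if t % controls.adapt_every == 0:
                adapt_proposals(state)
            if t == controls.burn_in:
                state.frozen = True
        else:
            _record_params(state, chains)
            if t == next_save:
                datasets.append(state.data.completed_copy())
                next_save += controls.n_between
                if len(datasets) % max(1, controls.m // 2) == 0:
                    logger.info("saved imputation %d/%d", len(datasets), controls.m)

    assert state.data.observed_fingerprint() == fingerprint, \
        "observed cells changed during sampling"

    chain_arrays = {k: np.asarray(v) for k, v in chains.items()}
    rhats = {}
    for k, v in chain_arrays.items():
        if len(v) >= 4:
            half = len(v) // 2
            rhats[k] = rhat(np.stack([v[:half], v[half:2 * half]]))
    result = ImputationSet(datasets, rhats, state.acceptance_rates(),
                           controls, chain_arrays)
    bad = {k: v for k, v in rhats.items() if v > 1.1}
    if bad:
        logger.warning("potential non-convergence (R-hat > 1.1): %s",
                       {k: round(v, 3) for k, v in bad.items()})
    return result


class SMCImputer(BaseEstimator, TransformerMixin):
    """Substantive-model-compatible multilevel imputer (sklearn-style).

    Parameters
    ----------
    formulas : list of str
        Conditional-model formulas; the last one is the substantive outcome
        model.  See :mod:`smcimpute.formula` for the grammar.
    cluster_col : str
        Name of the cluster-identifier column in the input frame.
    levels : dict or None
        Variable -> level (1 or 2); inferred from within-cluster constancy
        when omitted.
    order : "given" or "auto"
        "auto" reorders covariate models level-2-first then by ascending
        missing-data percentage.
    """

    def __init__(self, formulas=None, cluster_col="cluster", levels=None,
                 order="given", burn_in=2000, n_between=100, m=10,
                 adapt_every=25, accept_band=(0.3, 0.6), indep_prob=0.5,
                 seed=None, priors=None):
        self.formulas = formulas
        self.cluster_col = cluster_col
        self.levels = levels
        self.order = order
        self.burn_in = burn_in
        self.n_between = n_between
        self.m = m
        self.adapt_every = adapt_every
        self.accept_band = accept_band
        self.indep_prob = indep_prob
        self.seed = seed
        self.priors = priors

    def _build(self, X) -> tuple[MultilevelDataset, SequenceSpec, SamplerControls]:
        from .formula import parse_formula
        if isinstance(X, MultilevelDataset):
            dataset = X
        else:
            dataset = MultilevelDataset.from_frame(
                pd.DataFrame(X), self.cluster_col, self.levels)
        if not self.formulas:
            raise ValueError("formulas must list at least the outcome model")
        specs = []
        for f in self.formulas:
            outcome = f.split("~")[0].strip()
            specs.append(parse_formula(f, level=dataset.level(outcome),
                                       cluster_name=self.cluster_col))
        cov, outcome_model = specs[:-1], specs[-1]
        if self.order == "auto":
            cov = default_sequence_order(dataset, cov)
        sequence = SequenceSpec(tuple(cov), outcome_model)
        controls = SamplerControls(
            burn_in=self.burn_in, n_between=self.n_between, m=self.m,
            adapt_every=self.adapt_every, accept_band=tuple(self.accept_band),
            indep_prob=self.indep_prob, seed=self.seed,
            priors=self.priors or Priors())
        return dataset, sequence, controls

    def fit(self, X, y=None):
        dataset, sequence, controls = self._build(X)
        self.result_ = run_smc(dataset, sequence, controls)
        self.dataset_ = dataset
        self.sequence_ = sequence
        self.diagnostics_ = self.result_.diagnostics_report()
        self.n_imputations_ = self.result_.m
        return self

    def transform(self, X=None):
        """Return the stacked completed data (imputation index 0 = original)."""
        if not hasattr(self, "result_"):
            raise RuntimeError("SMCImputer is not fitted")
        return self.result_.to_stacked_frame(self.dataset_, self.cluster_col)

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)
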