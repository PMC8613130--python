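"""Building-block conditional models of the imputation sequence.

Two model families cover the sequence: a normal linear mixed model for
level-1 variables (random effects carried explicitly by data augmentation)
and a normal regression for level-2 variables.  Both expose log-density
evaluation per row/cluster and conjugate Gibbs parameter updates.

Priors (all weakly informative, keeping every update in closed form):
flat on regression coefficients; inverse-gamma(eps, eps) on residual
variances; inverse-Wishart(dim + 1, s * I) on the random-effect covariance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import (MultilevelDataset, ModelSpec, design_matrix,
                   random_design_matrix)

__all__ = [
    "Priors",
    "NormalLevel1Model",
    "NormalLevel2Model",
    "init_level1_model",
    "init_level2_model",
    "loglik_rows",
    "cluster_loglik",
    "gibbs_update_level1",
    "gibbs_update_level2",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class Priors:
    """Hyperparameters of the conjugate priors (exposed in the config)."""

    var_shape: float = 1e-3   # inverse-gamma shape for sigma^2
    var_rate: float = 1e-3    # inverse-gamma rate for sigma^2
    t_scale: float = 1e-3     # inverse-Wishart scale = t_scale * I
    t_df_extra: float = 1.0   # inverse-Wishart df = dim(T) + t_df_extra


@dataclass(frozen=True)
class NormalLevel1Model:
    """y_ij = x_ij' beta + w_ij' u_j + e_ij,  e ~ N(0, sigma2), u_j ~ N(0, T)."""

    spec: ModelSpec
    beta: np.ndarray          # (p,)
    sigma2: float
    T: np.ndarray             # (k, k), k = number of random coefficients
    u: np.ndarray             # (J, k) current random-effect draws

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        k = self.spec.n_random
        if self.T.shape != (k, k):
            raise ValueError("T dimension does not match the random part")
        if k and not np.allclose(self.T, self.T.T):
            raise ValueError("T must be symmetric")
        if k and np.linalg.eigvalsh(self.T).min() < -1e-10:
            raise ValueError("T must be positive semidefinite")
        if self.u.shape[1] != k:
            raise ValueError("u dimension does not match the random part")


@dataclass(frozen=True)
class NormalLevel2Model:
    """Cluster-level regression x_j = c_j' gamma + e_j, e_j ~ N(0, sigma2)."""

    spec: ModelSpec
    gamma: np.ndarray
    sigma2: float

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


def init_level1_model(spec: ModelSpec, dataset: MultilevelDataset
                      ) -> NormalLevel1Model:
    p = len(spec.coefficient_names())
    k = spec.n_random
    return NormalLevel1Model(spec, np.zeros(p), 1.0,
                             np.eye(k) * 0.1 if k else np.empty((0, 0)),
                             np.zeros((dataset.n_clusters, k)))


def init_level2_model(spec: ModelSpec) -> NormalLevel2Model:
    p = len(spec.coefficient_names())
    return NormalLevel2Model(spec, np.zeros(p), 1.0)


# -- design helpers ----------------------------------------------------------

def _level2_design(dataset: MultilevelDataset, spec: ModelSpec
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Cluster-level outcome and design (one row per cluster)."""
    Xr, _ = design_matrix(dataset, spec)
    y = dataset.values(spec.outcome)
    if np.isnan(y).any():
        raise ValueError(
            f"outcome {spec.outcome!r} has missing cells; complete it first")
    # predictors and outcome are cluster-constant; within-cluster means
    # collapse the row-level columns exactly
    X2 = np.stack([dataset.cluster_mean(Xr[:, c]) for c in range(Xr.shape[1])],
                  axis=1) if Xr.shape[1] else np.empty((dataset.n_clusters, 0))
    y2 = dataset.cluster_mean(y)
    return y2, X2


def _row_residuals(model: NormalLevel1Model, dataset: MultilevelDataset
                   ) -> np.ndarray:
    X, _ = design_matrix(dataset, model.spec)
    y = dataset.values(model.spec.outcome)
    if np.isnan(y).any():
        raise ValueError(
            f"outcome {model.spec.outcome!r} has missing cells; complete it first")
    mu = X @ model.beta
    if model.spec.n_random:
        W, _ = random_design_matrix(dataset, model.spec)
        mu = mu + np.einsum("ij,ij->i", W, model.u[dataset.codes])
    return y - mu


def predict_mean(model, dataset: MultilevelDataset) -> np.ndarray:
    """Model-implied mean: per row (level-1 model, including the current
    random effects u_j) or per cluster (level-2 model)."""
    if isinstance(model, NormalLevel1Model):
        X, _ = design_matrix(dataset, model.spec)
        mu = X @ model.beta
        if model.spec.n_random:
            W, _ = random_design_matrix(dataset, model.spec)
            mu = mu + np.einsum("ij,ij->i", W, model.u[dataset.codes])
        return mu
    Xr, _ = design_matrix(dataset, model.spec)
    X2 = np.stack([dataset.cluster_mean(Xr[:, c]) for c in range(Xr.shape[1])],
                  axis=1) if Xr.shape[1] else np.empty((dataset.n_clusters, 0))
    return X2 @ model.gamma


# -- log densities -----------------------------------------------------------

def row_loglik(model: NormalLevel1Model, dataset: MultilevelDataset
               ) -> np.ndarray:
    """Per-row log density of a level-1 model under current parameters."""
    r = _row_residuals(model, dataset)
    return -0.5 * (_LOG2PI + np.log(model.sigma2)) - r * r / (2 * model.sigma2)


def cluster_loglik(model, dataset: MultilevelDataset) -> np.ndarray:
    """Per-cluster summed log density under the current parameters.

    For a level-1 model the mean includes the cluster's current random
    effects u_j; for a level-2 model each cluster contributes one term.
    """
    if isinstance(model, NormalLevel1Model):
        return np.bincount(dataset.codes, row_loglik(model, dataset),
                           minlength=dataset.n_clusters)
    y2, X2 = _level2_design(dataset, model.spec)
    r = y2 - X2 @ model.gamma
    return -0.5 * (_LOG2PI + np.log(model.sigma2)) - r * r / (2 * model.sigma2)


def loglik_rows(model, dataset: MultilevelDataset, rows=None, clusters=None
                ) -> float:
    """Sum of log densities over a row selection (level-1 models) or a
    cluster selection.  Additive over disjoint selections."""
    if isinstance(model, NormalLevel2Model) or rows is None:
        per_cluster = cluster_loglik(model, dataset)
        if clusters is None:
            return float(per_cluster.sum())
        return float(per_cluster[np.asarray(clusters)].sum())
    r = _row_residuals(model, dataset)[np.asarray(rows)]
    return float(np.sum(-0.5 * (_LOG2PI + np.log(model.sigma2))
                        - r * r / (2 * model.sigma2)))


# -- Gibbs updates -----------------------------------------------------------

def _draw_mvn(mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator
              ) -> np.ndarray:
    L = np.linalg.cholesky(cov)
    return mean + L @ rng.standard_normal(mean.shape[0])


def _cluster_grams(dataset: MultilevelDataset, W: np.ndarray, r: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster W_j'W_j (J,k,k) and W_j'r_j (J,k)."""
    J, k = dataset.n_clusters, W.shape[1]
    G = np.empty((J, k, k))
    b = np.empty((J, k))
    for a in range(k):
        b[:, a] = np.bincount(dataset.codes, W[:, a] * r, minlength=J)
        for c in range(a, k):
            g = np.bincount(dataset.codes, W[:, a] * W[:, c], minlength=J)
            G[:, a, c] = g
            G[:, c, a] = g
    return G, b


def gibbs_update_level1(model: NormalLevel1Model, dataset: MultilevelDataset,
                        rng: np.random.Generator, priors: Priors = Priors(),
                        update=("beta", "u", "sigma2", "T"),
                        ) -> NormalLevel1Model:
    """One sweep of the exact full conditionals (beta, u_j, sigma2, T).

    ``update`` restricts the sweep (used by tests that freeze sub-blocks);
    draws are deterministic given the generator state.
    """
    spec = model.spec
    X, names = design_matrix(dataset, spec)
    y = dataset.values(spec.outcome)
    if np.isnan(y).any():
        raise ValueError(f"outcome {spec.outcome!r} has missing cells")
    k = spec.n_random
    W = random_design_matrix(dataset, spec)[0] if k else None
    beta, sigma2, T, u = model.beta, model.sigma2, model.T, model.u

    def u_rows(uu):
        return np.einsum("ij,ij->i", W, uu[dataset.codes]) if k else 0.0

    if "beta" in update:
        resid = y - u_rows(u)
        XtX = X.T @ X
        try:
            cov = np.linalg.inv(XtX) * sigma2
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular precision matrix for fixed effects of "
                f"{spec.outcome!r} (terms: {names})") from err
        mean = np.linalg.solve(XtX, X.T @ resid)
        beta = _draw_mvn(mean, cov, rng)

    if k and "u" in update:
        r = y - X @ beta
        G, b = _cluster_grams(dataset, W, r)
        try:
            Tinv = np.linalg.inv(T)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular random-effect covariance for {spec.outcome!r}") from err
        A = G / sigma2 + Tinv[None]
        Ainv = np.linalg.inv(A)
        mean = np.einsum("jab,jb->ja", Ainv, b) / sigma2
        L = np.linalg.cholesky(Ainv)
        u = mean + np.einsum("jab,jb->ja", L,
                             rng.standard_normal((dataset.n_clusters, k)))

    if "sigma2" in update:
        r = y - X @ beta - u_rows(u)
        shape = priors.var_shape + dataset.n_rows / 2.0
        rate = priors.var_rate + float(r @ r) / 2.0
        sigma2 = rate / rng.gamma(shape)

    if k and "T" in update:
        df = k + priors.t_df_extra + dataset.n_clusters
        scale = priors.t_scale * np.eye(k) + u.T @ u
        T = np.atleast_2d(stats.invwishart.rvs(df, scale, random_state=rng))

    return dataclasses.replace(model, beta=beta, sigma2=sigma2, T=T, u=u)


def gibbs_update_level2(model: NormalLevel2Model, dataset: MultilevelDataset,
                        rng: np.random.Generator, priors: Priors = Priors(),
                        update=("gamma", "sigma2")) -> NormalLevel2Model:
    """Conjugate update of the cluster-level regression (one row per cluster)."""
    y2, X2 = _level2_design(dataset, model.spec)
    gamma, sigma2 = model.gamma, model.sigma2

    if "gamma" in update:
        XtX = X2.T @ X2
        try:
            cov = np.linalg.inv(XtX) * sigma2
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular precision matrix for {model.spec.outcome!r}") from err
        mean = np.linalg.solve(XtX, X2.T @ y2)
        gamma = _draw_mvn(mean, cov, rng)

    if "sigma2" in update:
        r = y2 - X2 @ gamma
        shape = priors.var_shape + len(y2) / 2.0
        rate = priors.var_rate + float(r @ r) / 2.0
        sigma2 = rate / rng.gamma(shape)

    return dataclasses.replace(model, gamma=gamma, sigma2=sigma2)
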