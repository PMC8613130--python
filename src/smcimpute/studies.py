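"""Monte Carlo study designs: data generation, missingness, and metrics.

Three generating processes are provided, mirroring a family of two-level
designs with standardized variables (Var(x) = Var(y) = Var(z) = 1):

* study 1 — x splits into level-2 and level-1 normal components with
  ICC rho_Ix; (x_L2, z) bivariate normal with Cor(x, z) = rho_xz; outcome
  model with conflated effect of x, effect of z, cross-level interaction
  x*z, random intercept and random slope on x.
* study 2 — same covariates; outcome model cluster-mean-centered, with
  separate within/between effects of x, CLI of wdev(x) with z, a level-2
  interaction cmean(x)*z, and a random slope on wdev(x).
* study 3 — z standard normal; the level-2 part of x is a quadratic
  function of z, with the linear and quadratic parts contributing
  fractions (1-w, w) of a total R2_xz of Var(x); outcome model adds
  quadratic effects x^2 and z^2.

The quadratic generator treats R2_xz as a fraction of the *total* unit
variance of x: phi1 = sqrt((1-w) R2), phi2 = sqrt(w R2 / 2), phi0 = -phi2
(zero mean), with the residual variance (1 - R2) split between levels by
rho_Ix — level-2 innovation variance rho_Ix (1 - R2) and level-1 variance
(1 - rho_Ix)(1 - R2) — so Var(x) = 1 exactly and Cor(x, z) =
sqrt((1-w) R2) (about .71 at w = 0 down to 0 at w = 1).

Random slopes have fixed variance tau1_sq with tau01 = 0; the random
intercept variance and the level-1 residual variance are calibrated so
that the ICC of y matches rho_Iy and Var(y) = 1.  Both are obtained
deterministically by Gauss-Hermite quadrature, which is exact here because
every integrand is a low-degree polynomial in jointly normal variables.

Missingness follows a latent-propensity model r = lambda0 + lambda1 y + v,
v ~ N(0, 1 - lambda1^2): a cell of the target variable is deleted where
r > 0.  Because Var(y) = 1 and E[y] = 0, r is standard normal and lambda0
is simply the normal quantile of the target missing proportion (lambda0 =
-0.674 gives 25%); lambda1 = 0 gives MCAR, lambda1 > 0 makes missingness
depend on the outcome (MAR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import MultilevelDataset, compute_term
from .engine import SamplerControls, SequenceSpec, run_smc
from .formula import parse_formula
from .lmm import fit_lmm
from .pooling import pool_fits

__all__ = [
    "StudyDesign",
    "study_design",
    "gen_covariates_linear",
    "gen_covariates_quadratic",
    "gen_covariates",
    "gen_outcome",
    "induce_missing",
    "substantive_formula",
    "imputation_formulas",
    "true_parameters",
    "MetricsTable",
    "run_study",
]

logger = logging.getLogger("smcimpute")

_STUDY_BETAS = {
    # coefficient labels follow the substantive model term order
    1: {"x": 0.40, "z": 0.20, "x:z": 0.20},
    2: {"wdev(x)": 0.40, "cmean(x)": 0.0, "z": 0.20,
        "wdev(x):z": 0.20, "cmean(x):z": 0.0},
    3: {"x": 0.15, "z": 0.15, "x:z": 0.15, "x^2": 0.15, "z^2": 0.15},
}

_FORMULAS = {
    1: "y ~ x + z + x:z + (1 + x | cluster)",
    2: ("y ~ wdev(x) + cmean(x) + z + wdev(x):z + cmean(x):z "
        "+ (1 + wdev(x) | cluster)"),
    3: "y ~ x + z + x:z + x^2 + z^2 + (1 + x | cluster)",
}

_IMPUTATION_X_MODEL = {
    1: "x ~ z + (1 | cluster)",
    2: "x ~ z + (1 | cluster)",
    3: "x ~ z + z^2 + (1 | cluster)",
}


@dataclass(frozen=True)
class StudyDesign:
    study: int
    n: int
    J: int
    icc_x: float
    icc_y: float
    rho_xz: float = 0.20          # studies 1-2
    r2_xz: float = 0.50           # study 3: total R2 of x on z
    w: float = 0.0                # study 3: nonlinear share of R2_xz
    betas: dict = field(default_factory=dict)
    tau1_sq: float = 0.10
    tau01: float = 0.0
    miss_prop: float = 0.30
    lambda1: float = 0.0
    replications: int = 1000
    base_seed: int = 0

    def __post_init__(self):
        if self.study not in (1, 2, 3):
            raise ValueError("study must be 1, 2 or 3")
        if not (0 < self.icc_x < 1) or not (0 < self.icc_y < 1):
            raise ValueError("ICCs must lie in (0, 1)")
        if not (0 <= self.miss_prop <= 1):
            raise ValueError("missing proportion must lie in [0, 1]")
        if not (0 <= self.w <= 1):
            raise ValueError("nonlinear weight w must lie in [0, 1]")
        if self.replications < 1:
            raise ValueError("replication count must be >= 1")
        if abs(self.lambda1) > 1:
            raise ValueError("|lambda1| must not exceed 1")

    @property
    def lambda0(self) -> float:
        # quantile convention: r is standard normal by construction, so the
        # intercept of the propensity model is the quantile of the target
        # proportion under MCAR and MAR alike
        return float(stats.norm.ppf(self.miss_prop))

    @property
    def coef(self) -> dict:
        return self.betas or _STUDY_BETAS[self.study]


def study_design(study: int, n: int | None = None, J: int | None = None,
                 icc: float = 0.20, lambda1: float = 0.0, w: float = 0.0,
                 replications: int = 1000, base_seed: int = 0,
                 **kw) -> StudyDesign:
    """Convenience factory with each study's tabled defaults."""
    defaults = {1: (10, 200), 2: (10, 200), 3: (20, 1000)}
    dn, dJ = defaults[study]
    design = StudyDesign(study=study, n=n or dn, J=J or dJ, icc_x=icc,
                         icc_y=icc, lambda1=lambda1, w=w,
                         replications=replications, base_seed=base_seed, **kw)
    if study == 3:
        # under the correlation-pinned quadratic generator the level-2 part
        # of x carries R2 + rho_Ix (1 - R2) of its variance, so the fixed
        # between-cluster share of y can exceed the nominal ICC; clamp to
        # the nearest feasible value (keeping Var(y) = 1 exact)
        between_fix, _ = variance_decomposition(design)
        floor = between_fix + 0.02
        if design.icc_y < floor:
            design = replace(design, icc_y=float(floor))
    return design


# -- covariate generators ----------------------------------------------------

def _level2_coefficients(design: StudyDesign):
    """Unified level-2 model of x: x_L2 = c0 + c1 z + c2 z^2 + c_sd * eta."""
    if design.study in (1, 2):
        if design.icc_x < design.rho_xz ** 2:
            raise ValueError(
                f"Cor(x, z) = {design.rho_xz} requires ICC(x) >= "
                f"{design.rho_xz ** 2:.3f}")
        c_sd = float(np.sqrt(design.icc_x - design.rho_xz ** 2))
        return 0.0, design.rho_xz, 0.0, c_sd, 1.0 - design.icc_x
    phi1 = float(np.sqrt((1 - design.w) * design.r2_xz))
    phi2 = float(np.sqrt(design.w * design.r2_xz / 2.0))
    c_sd = float(np.sqrt(design.icc_x * (1 - design.r2_xz)))
    s2 = (1 - design.icc_x) * (1 - design.r2_xz)
    return -phi2, phi1, phi2, c_sd, s2


def _make_covariate_dataset(design, z, x, codes) -> MultilevelDataset:
    return MultilevelDataset({"x": x, "z": z[codes]}, codes,
                             {"x": 1, "z": 2})


def gen_covariates_linear(design: StudyDesign, rng: np.random.Generator
                          ) -> MultilevelDataset:
    """x with bivariate-normal level-2 components: Var(x) = 1, ICC(x) =
    icc_x, z standard normal at level 2, Cor(x, z) = rho_xz."""
    if design.study == 3:
        raise ValueError("study 3 uses the quadratic generator")
    c0, c1, c2, c_sd, s2 = _level2_coefficients(design)
    z = rng.standard_normal(design.J)
    x_l2 = c1 * z + c_sd * rng.standard_normal(design.J)
    codes = np.repeat(np.arange(design.J), design.n)
    x = x_l2[codes] + np.sqrt(s2) * rng.standard_normal(len(codes))
    return _make_covariate_dataset(design, z, x, codes)


def gen_covariates_quadratic(design: StudyDesign, rng: np.random.Generator
                             ) -> MultilevelDataset:
    """Quadratic level-2 regression of x on z (study 3); Var(x) = 1 and
    E[x] = 0 by construction."""
    c0, c1, c2, c_sd, s2 = _level2_coefficients(
        design if design.study == 3 else replace(design, study=3))
    z = rng.standard_normal(design.J)
    x_l2 = c0 + c1 * z + c2 * z * z + c_sd * rng.standard_normal(design.J)
    codes = np.repeat(np.arange(design.J), design.n)
    x = x_l2[codes] + np.sqrt(s2) * rng.standard_normal(len(codes))
    return _make_covariate_dataset(design, z, x, codes)


def gen_covariates(design: StudyDesign, rng: np.random.Generator
                   ) -> MultilevelDataset:
    if design.study == 3:
        return gen_covariates_quadratic(design, rng)
    return gen_covariates_linear(design, rng)


# -- outcome calibration and generation --------------------------------------

def _gh_grid(n_nodes: int = 16):
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    weights = weights / weights.sum()
    return nodes, weights


def variance_decomposition(design: StudyDesign) -> tuple[float, float]:
    """Fixed-part between- and within-cluster variance contributions of the
    generating model (random intercept and level-1 residual excluded),
    computed exactly by Gauss-Hermite quadrature."""
    c0, c1, c2, c_sd, s2 = _level2_coefficients(design)
    b = design.coef
    z1, wq = _gh_grid()
    Z, E = np.meshgrid(z1, z1, indexing="ij")
    Wgt = np.outer(wq, wq)
    X2 = c0 + c1 * Z + c2 * Z * Z + c_sd * E

    if design.study == 1:
        m = b["x"] * X2 + b["z"] * Z + b["x:z"] * X2 * Z
        between_extra = design.tau1_sq * float((Wgt * X2 * X2).sum())
        A = b["x"] + b["x:z"] * Z
        extra_within = 0.0
    elif design.study == 2:
        m = b["cmean(x)"] * X2 + b["z"] * Z + b["cmean(x):z"] * X2 * Z
        A = b["wdev(x)"] + b["wdev(x):z"] * Z
        # manifest (sample) centering at cluster size n: the deviation
        # carries s2 (1 - 1/n) of its variance, and the sample mean adds
        # s2 / n of noise on top of the level-2 component; the random
        # slope attaches to the deviation, so it adds nothing between
        between_extra = (b["cmean(x)"] ** 2
                         + b["cmean(x):z"] ** 2) * s2 / design.n
        s2 = s2 * (1.0 - 1.0 / design.n)
        extra_within = 0.0
    else:
        m = (b["x"] * X2 + b["z"] * Z + b["x:z"] * X2 * Z
             + b["x^2"] * (X2 * X2 + s2) + b["z^2"] * Z * Z)
        between_extra = design.tau1_sq * float((Wgt * X2 * X2).sum())
        A = b["x"] + b["x:z"] * Z + 2 * b["x^2"] * X2
        extra_within = b["x^2"] ** 2 * 2.0 * s2 * s2

    mbar = float((Wgt * m).sum())
    between_fix = float((Wgt * (m - mbar) ** 2).sum()) + between_extra
    within_fix = (float((Wgt * A * A).sum()) + design.tau1_sq) * s2 + extra_within
    return between_fix, within_fix


def calibrate_outcome_variances(design: StudyDesign) -> tuple[float, float]:
    """Solve for (tau0_sq, sigma2) so that ICC(y) = rho_Iy and Var(y) = 1."""
    between_fix, within_fix = variance_decomposition(design)
    tau0_sq = design.icc_y - between_fix
    sigma2 = (1.0 - design.icc_y) - within_fix
    if tau0_sq < 0 or sigma2 < 0:
        lo, hi = between_fix, 1.0 - within_fix
        raise ValueError(
            f"requested ICC(y) = {design.icc_y} is infeasible with slope "
            f"variance {design.tau1_sq}; feasible range is "
            f"[{lo:.4f}, {hi:.4f}]")
    return float(tau0_sq), float(sigma2)


def _intercept_for_zero_mean(design: StudyDesign) -> float:
    """beta0 making E[y] = 0 exactly, which keeps the quantile convention
    of the propensity model honest (interaction and quadratic terms have
    nonzero means even with centered inputs)."""
    c0, c1, c2, c_sd, s2 = _level2_coefficients(design)
    b = design.coef
    # normal moments: E[z^2] = 1, E[z^3] = 0, E[z^4] = 3; E[x z] = c1
    if design.study == 1:
        return -b["x:z"] * c1
    if design.study == 2:
        return -b["cmean(x):z"] * c1
    e_x2 = c0 + c2
    e_x2sq = c0 ** 2 + c1 ** 2 + 3 * c2 ** 2 + 2 * c0 * c2 + c_sd ** 2
    return -(b["x^2"] * (e_x2sq + s2) + b["z^2"] * 1.0
             + b["x:z"] * c1 + b["x"] * e_x2)


def gen_outcome(design: StudyDesign, dataset: MultilevelDataset,
                rng: np.random.Generator) -> MultilevelDataset:
    """Add the outcome y drawn from the study's generating model (manifest
    cluster means for the centered design of study 2)."""
    tau0_sq, sigma2 = calibrate_outcome_variances(design)
    b = design.coef
    spec = parse_formula(substantive_formula(design.study), level=1)
    X = np.column_stack([compute_term(dataset, t) for t in spec.terms])
    beta = np.array([b[t.label()] for t in spec.terms])
    codes = dataset.codes
    u0 = np.sqrt(tau0_sq) * rng.standard_normal(dataset.n_clusters)
    u1 = np.sqrt(design.tau1_sq) * rng.standard_normal(dataset.n_clusters)
    slope_col = compute_term(dataset, spec.random_terms[0])
    e = np.sqrt(sigma2) * rng.standard_normal(dataset.n_rows)
    y = (_intercept_for_zero_mean(design) + X @ beta
         + u0[codes] + u1[codes] * slope_col + e)
    data = {v: dataset.values(v).copy() for v in dataset.variables}
    data["y"] = y
    levels = dict(dataset.levels)
    levels["y"] = 1
    mask = {v: dataset.mask(v).copy() for v in dataset.variables}
    return MultilevelDataset(data, dataset.cluster_labels[codes], levels, mask)


def induce_missing(dataset: MultilevelDataset, target: str, lambda0: float,
                   lambda1: float, rng: np.random.Generator
                   ) -> MultilevelDataset:
    """Delete cells of ``target`` where the latent propensity
    r = lambda0 + lambda1 y + v exceeds zero (v ~ N(0, 1 - lambda1^2))."""
    if abs(lambda1) > 1:
        raise ValueError("|lambda1| must not exceed 1")
    y = dataset.values("y")
    v = np.sqrt(1.0 - lambda1 ** 2) * rng.standard_normal(dataset.n_rows)
    r = lambda0 + lambda1 * y + v
    out = dataset.copy()
    miss = r > 0
    out._mask[target] = out._mask[target] | miss
    out._values[target][miss] = np.nan
    return out


# -- strategy comparison -----------------------------------------------------

def substantive_formula(study: int) -> str:
    return _FORMULAS[study]


def imputation_formulas(study: int) -> list[str]:
    """Sequence of conditional-model formulas, outcome model last."""
    return [_IMPUTATION_X_MODEL[study], _FORMULAS[study]]


def true_parameters(design: StudyDesign) -> dict[str, float]:
    out = {"(Intercept)": _intercept_for_zero_mean(design)}
    out.update(design.coef)
    out["tau1_sq"] = design.tau1_sq
    return out


@dataclass
class MetricsTable:
    """Per-parameter relative bias, RMSE and CI coverage with their Monte
    Carlo standard errors; ``raw`` holds the per-replication estimates."""

    frame: pd.DataFrame
    strategy: str
    n_replications: int
    n_failed: int = 0
    raw: pd.DataFrame | None = None

    def row(self, parameter: str) -> pd.Series:
        return self.frame.set_index("parameter").loc[parameter]


def _metrics(estimates: np.ndarray, hits: np.ndarray, names: list[str],
             truth: np.ndarray, strategy: str, n_failed: int) -> MetricsTable:
    R = estimates.shape[0]
    mean = estimates.mean(axis=0)
    sd = estimates.std(axis=0, ddof=1) if R > 1 else np.zeros_like(mean)
    err = estimates - truth
    rmse = np.sqrt((err ** 2).mean(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        bias_pct = np.where(np.abs(truth) > 1e-12,
                            100.0 * (mean - truth) / truth, np.nan)
        bias_pct_mcse = np.where(np.abs(truth) > 1e-12,
                                 100.0 * sd / (np.abs(truth) * np.sqrt(R)),
                                 np.nan)
        rmse_mcse = (err ** 2).std(axis=0, ddof=1) / (2 * rmse * np.sqrt(R))
    all_nan = np.isnan(hits).all(axis=0)
    cov = np.full(hits.shape[1], np.nan)
    cov[~all_nan] = 100.0 * np.nanmean(hits[:, ~all_nan], axis=0)
    cov_mcse = np.sqrt(np.maximum(cov * (100 - cov), 0.0) / R)
    frame = pd.DataFrame({
        "parameter": names, "truth": truth, "mean_estimate": mean,
        "bias": mean - truth, "bias_pct": bias_pct,
        "bias_pct_mcse": bias_pct_mcse, "rmse": rmse, "rmse_mcse": rmse_mcse,
        "coverage": cov, "coverage_mcse": cov_mcse,
    })
    return MetricsTable(frame, strategy, R, n_failed)


def _fit_and_summarize(dataset, spec, df_com):
    fit = fit_lmm(dataset, spec)
    if not fit.converged or np.isnan(fit.beta).any():
        return None
    tcrit = stats.t.ppf(0.975, df_com)
    lower = fit.beta - tcrit * fit.se
    upper = fit.beta + tcrit * fit.se
    tau1 = fit.T[-1, -1] if fit.T.size else np.nan
    return fit.beta, lower, upper, tau1


def run_study(design: StudyDesign, strategies=("CD", "LD", "SMC"),
              controls: SamplerControls | None = None,
              ) -> dict[str, MetricsTable]:
    """Replicate generate -> delete -> (impute) -> fit -> pool and collect
    bias/RMSE/coverage per strategy.

    Reproducible from ``design.base_seed``: each replication draws from a
    deterministic spawned stream.
    """
    if controls is None:
        # reduced-scale sampler settings for simulation batches; the engine
        # defaults (2000 / 100) remain in place for one-shot imputation
        controls = SamplerControls(burn_in=500, n_between=50, m=10,
                                   adapt_every=25)
    spec = parse_formula(substantive_formula(design.study), level=1)
    seq_specs = [parse_formula(f, level=1)
                 for f in imputation_formulas(design.study)]
    sequence = SequenceSpec(tuple(seq_specs[:-1]), seq_specs[-1])
    truth_map = true_parameters(design)
    names = spec.coefficient_names() + ["tau1_sq"]
    truth = np.array([truth_map.get(nm, np.nan) for nm in names])
    df_com = design.J - len(spec.coefficient_names())

    streams = np.random.SeedSequence(design.base_seed).spawn(design.replications)
    results = {s: [] for s in strategies}
    hits = {s: [] for s in strategies}
    n_failed = {s: 0 for s in strategies}

    for r, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        complete = gen_outcome(design, gen_covariates(design, rng), rng)
        incomplete = induce_missing(complete, "x", design.lambda0,
                                    design.lambda1, rng)
        for strat in strategies:
            try:
                if strat == "CD":
                    out = _fit_and_summarize(complete, spec, df_com)
                elif strat == "LD":
                    out = _fit_and_summarize(incomplete, spec, df_com)
                elif strat == "SMC":
                    imp = run_smc(incomplete, sequence, controls, rng)
                    fits = [fit_lmm(d, spec) for d in imp.datasets]
                    pooled, _ = pool_fits(fits, df_com)
                    ok = [f for f in fits if f.converged]
                    tau1 = float(np.mean([f.T[-1, -1] for f in ok])) \
                        if ok and ok[0].T.size else np.nan
                    out = (pooled.qbar, pooled.ci_lower, pooled.ci_upper, tau1)
                else:
                    raise ValueError(f"unknown strategy {strat!r}")
            except (ValueError, np.linalg.LinAlgError) as err:
                logger.warning("replication %d failed for %s: %s", r, strat, err)
                out = None
            if out is None:
                n_failed[strat] += 1
                continue
            est, lo, hi, tau1 = out
            results[strat].append(np.concatenate([est, [tau1]]))
            h = ((lo <= truth[:-1]) & (truth[:-1] <= hi)).astype(float)
            hits[strat].append(np.concatenate([h, [np.nan]]))

    tables = {}
    for strat in strategies:
        if not results[strat]:
            raise RuntimeError(f"all replications failed for {strat!r}")
        est = np.stack(results[strat])
        hit = np.stack(hits[strat])
        tables[strat] = _metrics(est, hit, names, truth, strat,
                                 n_failed[strat])
        tables[strat].raw = pd.DataFrame(est, columns=names)
    return tables
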