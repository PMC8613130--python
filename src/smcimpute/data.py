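"""Two-level datasets and the term algebra for multilevel model formulas.

A :class:`MultilevelDataset` holds long-format data (one row per level-1
unit) with a cluster identifier, a level tag (1 or 2) per variable, and an
explicit missing-cell mask.  Observed cells are immutable throughout
sampling; missing cells are represented by the mask, never by a sentinel.

Terms are products of transformed variables.  The available transforms are
the identity, the (manifest) cluster mean ``cmean(x)``, the within-cluster
deviation ``wdev(x) = x - cmean(x)``, and integer powers ``x^k`` (k >= 2).
Cluster means are always recomputed from the *current* completed values, so
a model term reacts immediately when a value in the cluster changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MultilevelDataset",
    "TermSpec",
    "ModelSpec",
    "compute_term",
    "design_matrix",
    "read_long_csv",
    "write_long_csv",
]

_TRANSFORMS = ("identity", "cluster_mean", "within_deviation", "power")


@dataclass(frozen=True)
class TermSpec:
    """A product of transformed variables.

    Each factor is ``(variable, transform)`` or ``(variable, transform, k)``
    for the power transform.  The term's column is the row-wise product of
    its factor columns.
    """

    factors: tuple[tuple, ...]

    def __post_init__(self):
        if len(self.factors) == 0:
            raise ValueError("a term needs at least one factor")
        for f in self.factors:
            if len(f) == 2:
                name, tr = f
                k = None
            elif len(f) == 3:
                name, tr, k = f
            else:
                raise ValueError(f"malformed factor {f!r}")
            if tr not in _TRANSFORMS:
                raise ValueError(f"unknown transform {tr!r}")
            if tr == "power":
                if k is None or int(k) != k or k < 2:
                    raise ValueError("power exponent must be an integer >= 2")
            elif k is not None:
                raise ValueError(f"transform {tr!r} takes no exponent")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(f[0] for f in self.factors)

    def label(self) -> str:
        parts = []
        for f in self.factors:
            name, tr = f[0], f[1]
            if tr == "identity":
                parts.append(name)
            elif tr == "cluster_mean":
                parts.append(f"cmean({name})")
            elif tr == "within_deviation":
                parts.append(f"wdev({name})")
            else:
                parts.append(f"{name}^{f[2]}")
        return ":".join(parts)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"TermSpec<{self.label()}>"


def term(*factors) -> TermSpec:
    """Convenience constructor: ``term(("x", "identity"), ("z", "identity"))``."""
    return TermSpec(tuple(tuple(f) for f in factors))


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one conditional (or substantive) model.

    ``random_terms`` must be a subset of ``terms``; together with
    ``random_intercept`` they define the cluster-varying part.  Level-2
    outcome models carry no random part and only level-2-representable
    predictors (level-2 variables or cluster means / powers thereof).
    """

    outcome: str
    level: int
    terms: tuple[TermSpec, ...]
    intercept: bool = True
    random_intercept: bool = False
    random_terms: tuple[TermSpec, ...] = ()

    def __post_init__(self):
        if self.level not in (1, 2):
            raise ValueError("level must be 1 or 2")
        for rt in self.random_terms:
            if rt not in self.terms:
                raise ValueError(f"random term {rt.label()} is not a fixed term")
        if self.level == 2 and (self.random_intercept or self.random_terms):
            raise ValueError("a level-2 model cannot have random terms")

    @property
    def n_random(self) -> int:
        return int(self.random_intercept) + len(self.random_terms)

    @property
    def predictor_variables(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.terms:
            for v in t.variables:
                if v not in seen:
                    seen.append(v)
        return tuple(seen)

    def coefficient_names(self) -> list[str]:
        names = ["(Intercept)"] if self.intercept else []
        names += [t.label() for t in self.terms]
        return names

    def random_coefficient_names(self) -> list[str]:
        names = ["(Intercept)"] if self.random_intercept else []
        names += [t.label() for t in self.random_terms]
        return names


class MultilevelDataset:
    """Long-format two-level data with an explicit missing mask.

    Parameters
    ----------
    data : mapping of variable name -> 1-d float array (NaN allowed only
        where the mask is True; NaN cells are folded into the mask).
    cluster : 1-d array of cluster labels, one per row, no missing.
    levels : mapping name -> 1 or 2.
    mask : optional mapping name -> boolean array, True = missing.
    """

    def __init__(self, data: Mapping[str, np.ndarray], cluster: np.ndarray,
                 levels: Mapping[str, int], mask: Mapping[str, np.ndarray] | None = None):
        cluster = np.asarray(cluster)
        if cluster.ndim != 1:
            raise ValueError("cluster must be one-dimensional")
        if pd.isna(cluster).any():
            raise ValueError("cluster identifiers must not be missing")
        self.n_rows = cluster.shape[0]
        self.cluster_labels, self.codes = np.unique(cluster, return_inverse=True)
        self.n_clusters = len(self.cluster_labels)
        self.cluster_sizes = np.bincount(self.codes, minlength=self.n_clusters)

        self.variables: list[str] = list(data)
        self.levels = dict(levels)
        for name in self.variables:
            if name not in self.levels:
                raise ValueError(f"no level declared for variable {name!r}")
            if self.levels[name] not in (1, 2):
                raise ValueError(f"bad level for {name!r}")

        self._values: dict[str, np.ndarray] = {}
        self._mask: dict[str, np.ndarray] = {}
        for name in self.variables:
            col = np.asarray(data[name], dtype=float)
            if col.shape != (self.n_rows,):
                raise ValueError(f"column {name!r} has wrong shape")
            m = np.zeros(self.n_rows, dtype=bool)
            if mask is not None and name in mask:
                m = np.asarray(mask[name], dtype=bool).copy()
                if m.shape != (self.n_rows,):
                    raise ValueError(f"mask for {name!r} has wrong shape")
            m |= np.isnan(col)
            col = col.copy()
            col[m] = np.nan
            self._values[name] = col
            self._mask[name] = m
        self._validate_level2()

    # -- construction helpers ------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cluster_col: str,
                   levels: Mapping[str, int] | None = None) -> "MultilevelDataset":
        """Build from a long-format DataFrame; NaN/NA cells become missing.

        If ``levels`` is omitted, a variable constant within every cluster
        (over observed cells) is tagged level 2, otherwise level 1.
        """
        if cluster_col not in frame.columns:
            raise ValueError(f"cluster column {cluster_col!r} not in frame")
        cluster = frame[cluster_col].to_numpy()
        names = [c for c in frame.columns if c != cluster_col]
        data = {c: frame[c].to_numpy(dtype=float) for c in names}
        if levels is None:
            levels = {}
            codes = np.unique(cluster, return_inverse=True)[1]
            for c in names:
                levels[c] = 2 if _constant_within(data[c], codes) else 1
        return cls(data, cluster, levels)

    def _validate_level2(self) -> None:
        for name in self.variables:
            if self.levels[name] != 2:
                continue
            col, m = self._values[name], self._mask[name]
            if not _constant_within(col, self.codes):
                raise ValueError(
                    f"level-2 variable {name!r} varies within a cluster")
            # missingness of a level-2 variable is a cluster-level event
            miss_frac = np.bincount(self.codes, m.astype(float),
                                    minlength=self.n_clusters) / self.cluster_sizes
            if np.any((miss_frac > 0) & (miss_frac < 1)):
                raise ValueError(
                    f"level-2 variable {name!r} is partially missing within a cluster")

    # -- accessors -----------------------------------------------------------
    def values(self, name: str) -> np.ndarray:
        if name not in self._values:
            raise KeyError(f"unknown variable {name!r}")
        return self._values[name]

    def mask(self, name: str) -> np.ndarray:
        if name not in self._mask:
            raise KeyError(f"unknown variable {name!r}")
        return self._mask[name]

    def n_missing(self, name: str) -> int:
        return int(self._mask[name].sum())

    @property
    def any_missing(self) -> bool:
        return any(m.any() for m in self._mask.values())

    def level(self, name: str) -> int:
        return self.levels[name]

    def copy(self) -> "MultilevelDataset":
        return MultilevelDataset(
            {k: v.copy() for k, v in self._values.items()},
            self.cluster_labels[self.codes],
            dict(self.levels),
            {k: m.copy() for k, m in self._mask.items()},
        )

    def completed_copy(self) -> "MultilevelDataset":
        """Copy with the missing mask cleared: current values become
        observed.  Requires every cell to be filled."""
        for name in self.variables:
            if np.isnan(self._values[name]).any():
                raise ValueError(
                    f"variable {name!r} still has unfilled cells")
        return MultilevelDataset(
            {k: v.copy() for k, v in self._values.items()},
            self.cluster_labels[self.codes], dict(self.levels))

    def with_values(self, updates: Mapping[str, np.ndarray]) -> "MultilevelDataset":
        """Return a copy with some columns replaced (mask preserved as-is
        except cells that are no longer NaN become observed)."""
        vals = {k: v.copy() for k, v in self._values.items()}
        mask = {k: m.copy() for k, m in self._mask.items()}
        for k, v in updates.items():
            v = np.asarray(v, dtype=float)
            vals[k] = v.copy()
            mask[k] = np.isnan(v)
        return MultilevelDataset(vals, self.cluster_labels[self.codes],
                                 dict(self.levels), mask)

    def to_frame(self, cluster_col: str = "cluster") -> pd.DataFrame:
        out = {cluster_col: self.cluster_labels[self.codes]}
        for name in self.variables:
            out[name] = self._values[name]
        return pd.DataFrame(out)

    def observed_fingerprint(self) -> int:
        """Hash of all observed cells; constant across a valid sampler run."""
        h = 0
        for name in self.variables:
            obs = self._values[name][~self._mask[name]]
            h ^= hash((name, obs.tobytes()))
        return h

    # -- grouped helpers -----------------------------------------------------
    def cluster_mean(self, col: np.ndarray) -> np.ndarray:
        sums = np.bincount(self.codes, col, minlength=self.n_clusters)
        return sums / self.cluster_sizes

    def expand(self, per_cluster: np.ndarray) -> np.ndarray:
        return per_cluster[self.codes]


def _constant_within(col: np.ndarray, codes: np.ndarray) -> bool:
    obs = ~np.isnan(col)
    if not obs.any():
        return True
    c, v = codes[obs], col[obs]
    n = codes.max() + 1
    lo = np.full(n, np.inf)
    hi = np.full(n, -np.inf)
    np.fmin.at(lo, c, v)
    np.fmax.at(hi, c, v)
    seen = np.isfinite(lo)
    return bool(np.all(hi[seen] - lo[seen] <= 1e-12))


# -- term evaluation ---------------------------------------------------------

def _factor_column(dataset: MultilevelDataset, factor: tuple) -> np.ndarray:
    name, tr = factor[0], factor[1]
    col = dataset.values(name)
    if np.isnan(col).any():
        raise ValueError(
            f"variable {name!r} has missing cells; terms require completed data")
    if tr == "identity":
        return col
    if tr == "cluster_mean":
        return dataset.expand(dataset.cluster_mean(col))
    if tr == "within_deviation":
        return col - dataset.expand(dataset.cluster_mean(col))
    if tr == "power":
        return col ** factor[2]
    raise AssertionError(tr)


def compute_term(dataset: MultilevelDataset, term: TermSpec) -> np.ndarray:
    """Evaluate a term on the current (completed) data.

    Cluster means and deviations are manifest: they are recomputed from the
    values present in ``dataset`` at call time.
    """
    out = _factor_column(dataset, term.factors[0])
    for f in term.factors[1:]:
        out = out * _factor_column(dataset, f)
    return out


def design_matrix(dataset: MultilevelDataset, spec: ModelSpec
                  ) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix in declaration order (intercept first)."""
    cols = []
    if spec.intercept:
        cols.append(np.ones(dataset.n_rows))
    for t in spec.terms:
        cols.append(compute_term(dataset, t))
    X = np.column_stack(cols) if cols else np.empty((dataset.n_rows, 0))
    return X, spec.coefficient_names()


def random_design_matrix(dataset: MultilevelDataset, spec: ModelSpec
                         ) -> tuple[np.ndarray, list[str]]:
    cols = []
    if spec.random_intercept:
        cols.append(np.ones(dataset.n_rows))
    for t in spec.random_terms:
        cols.append(compute_term(dataset, t))
    W = np.column_stack(cols) if cols else np.empty((dataset.n_rows, 0))
    return W, spec.random_coefficient_names()


# -- CSV I/O -----------------------------------------------------------------

def read_long_csv(path, cluster_col: str,
                  levels: Mapping[str, int] | None = None) -> MultilevelDataset:
    """Read long-format CSV; empty fields and literal "NA" are missing."""
    frame = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    return MultilevelDataset.from_frame(frame, cluster_col, levels)


def write_long_csv(dataset: MultilevelDataset, path, cluster_col: str = "cluster"
                   ) -> None:
    dataset.to_frame(cluster_col).to_csv(path, index=False, na_rep="NA")
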