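"""Registry preprocessing: deduplication, missingness filtering, KNN
imputation, normalization, and minority-class rebalancing.

The leakage-free order is: drop duplicate rows on the full table, split into
train/test, fit the column filter + imputer + normalizer on the training
rows only and apply the fitted state unchanged to the test rows, then
rebalance (SMOTE) the training rows only.  ``RegistryPreprocessor`` is the
scikit-learn-style transformer holding the fitted state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.impute import KNNImputer

from .datagen import TrialTable


@dataclass
class PreprocessState:
    """Fitted preprocessing state carried from training data to new data."""

    dropped_columns: list[str] = field(default_factory=list)
    numeric_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    k_neighbors: int = 5
    normalization: str = "zscore"
    smote_applied: bool = False
    n_synthetic: int = 0


def drop_duplicates(table: TrialTable) -> TrialTable:
    """Collapse exact-duplicate rows (covariates and labels); first kept."""
    df = table.to_frame()
    keep = ~df.duplicated(keep="first").to_numpy()
    return table.subset(np.flatnonzero(keep))


def drop_sparse_columns(
    table: TrialTable, threshold: float = 0.8
) -> tuple[TrialTable, list[str]]:
    """Drop covariate columns whose missing fraction strictly exceeds
    ``threshold`` (default: more than 80% missing)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    frac = np.isnan(table.covariates).mean(axis=0)
    dropped = [name for name, f in zip(table.column_names, frac) if f > threshold]
    if len(dropped) == table.p:
        raise ValueError("all covariate columns exceed the missingness threshold")
    keep = [i for i, name in enumerate(table.column_names) if name not in dropped]
    return (
        TrialTable(
            table.covariates[:, keep],
            table.time,
            table.event,
            [table.column_names[i] for i in keep],
            [c for c in table.numeric_column_names if c not in dropped],
            None
            if table.clean_covariates is None
            else table.clean_covariates[:, keep],
        ),
        dropped,
    )


def knn_impute(table: TrialTable, k: int = 5) -> TrialTable:
    """Fill missing cells with the mean of the k nearest rows.

    Distances are Euclidean over mutually observed covariates, rescaled by the
    fraction of usable coordinates (nan-Euclidean); observed cells are
    untouched and the output has no missing cells.  Binary columns are rounded
    back to {0, 1} to preserve the one-hot contract.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    x = table.covariates
    if np.isnan(x).all(axis=0).any():
        bad = [
            name
            for name, allmiss in zip(table.column_names, np.isnan(x).all(axis=0))
            if allmiss
        ]
        raise ValueError(
            f"column(s) entirely missing: {bad}; apply drop_sparse_columns first"
        )
    if not np.isnan(x).any():
        return table
    imputer = KNNImputer(n_neighbors=min(k, table.n - 1), weights="uniform")
    filled = imputer.fit_transform(x)
    filled = _round_binary(filled, table)
    out = table.copy()
    out.covariates = filled
    return out


def _binary_column_indices(table: TrialTable) -> list[int]:
    numeric = set(table.numeric_column_names)
    return [i for i, c in enumerate(table.column_names) if c not in numeric]


def _round_binary(x: np.ndarray, table: TrialTable) -> np.ndarray:
    idx = _binary_column_indices(table)
    x = x.copy()
    x[:, idx] = np.clip(np.round(x[:, idx]), 0.0, 1.0)
    return x


def normalize_numeric(
    table: TrialTable, fit: bool, state: PreprocessState
) -> TrialTable:
    """Standardize numeric columns; binary columns untouched.

    ``fit=True`` learns per-column location/scale on this (training) table and
    stores them in ``state``; ``fit=False`` reuses the stored training stats
    so test data is transformed without leakage.  z-score uses the population
    standard deviation (denominator n); ``state.normalization='minmax'``
    switches to min-max scaling.
    """
    out = table.copy()
    for name in table.numeric_column_names:
        j = table.column_names.index(name)
        col = out.covariates[:, j]
        obs = col[~np.isnan(col)]
        if fit:
            if state.normalization == "minmax":
                loc, scale = float(obs.min()), float(obs.max() - obs.min())
            else:
                loc, scale = float(obs.mean()), float(obs.std(ddof=0))
            if scale <= 0:
                raise ValueError(f"numeric column '{name}' has zero variance")
            state.numeric_stats[name] = (loc, scale)
        else:
            if name not in state.numeric_stats:
                raise ValueError(f"no fitted stats for numeric column '{name}'")
            loc, scale = state.numeric_stats[name]
        out.covariates[:, j] = (col - loc) / scale
    return out


def smote_balance(
    covariates: np.ndarray,
    event: np.ndarray,
    times: np.ndarray,
    seed: int = 0,
    k: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balance the event classes by synthetic minority oversampling.

    Each synthetic row is ``x_i + u (x_nn - x_i)`` with ``u ~ Uniform(0,1)``
    and ``x_nn`` one of the k nearest minority neighbors of minority row
    ``x_i``; the synthetic ``time`` is interpolated between the two parents'
    times with the same ``u`` (keeping (x, T) jointly plausible), and the
    synthetic ``event`` is the minority label.  Original rows are preserved
    verbatim; the minority class is whichever event value is rarer.
    """
    covariates = np.asarray(covariates, dtype=float)
    event = np.asarray(event, dtype=int)
    times = np.asarray(times, dtype=float)
    classes, counts = np.unique(event, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both event classes must be present")
    minority = int(classes[np.argmin(counts)])
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class of size 1: no neighbor to interpolate")
    deficit = int(n_maj - n_min)
    if deficit == 0:
        return covariates, event, times

    rng = np.random.default_rng(seed)
    idx_min = np.flatnonzero(event == minority)
    x_min, t_min = covariates[idx_min], times[idx_min]
    d2 = ((x_min[:, None, :] - x_min[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    k_eff = min(k, n_min - 1)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k_eff]

    base = rng.integers(0, n_min, size=deficit)
    pick = rng.integers(0, k_eff, size=deficit)
    u = rng.uniform(0.0, 1.0, size=deficit)
    mate = nn[base, pick]
    x_new = x_min[base] + u[:, None] * (x_min[mate] - x_min[base])
    t_new = t_min[base] + u * (t_min[mate] - t_min[base])
    e_new = np.full(deficit, minority, dtype=int)

    return (
        np.vstack([covariates, x_new]),
        np.concatenate([event, e_new]),
        np.concatenate([times, t_new]),
    )


def split_train_test(
    table: TrialTable, ratio: float = 0.8, seed: int = 0
) -> tuple[TrialTable, TrialTable]:
    """Random disjoint/exhaustive split; floor(ratio * n) rows to train."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    n = table.n
    n_train = int(np.floor(ratio * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split would leave an empty side")
    perm = np.random.default_rng(seed).permutation(n)
    return table.subset(perm[:n_train]), table.subset(perm[n_train:])


class RegistryPreprocessor(BaseEstimator, TransformerMixin):
    """Fitted preprocessing chain: sparse-column filter -> KNN imputation ->
    normalization, with binary rounding.  ``fit`` learns on training rows;
    ``transform`` applies the identical state to any table.

    Parameters
    ----------
    sparse_threshold : drop a covariate column when its training missing
        fraction strictly exceeds this (default 0.8).
    k_impute : neighbors for KNN imputation (default 5).
    normalization : 'zscore' (default) or 'minmax' for numeric columns.
    """

    def __init__(
        self,
        sparse_threshold: float = 0.8,
        k_impute: int = 5,
        normalization: str = "zscore",
    ):
        self.sparse_threshold = sparse_threshold
        self.k_impute = k_impute
        self.normalization = normalization

    def fit(self, table: TrialTable, y=None):
        state = PreprocessState(
            k_neighbors=self.k_impute, normalization=self.normalization
        )
        filtered, dropped = drop_sparse_columns(table, self.sparse_threshold)
        state.dropped_columns = dropped
        self.train_table_ = normalize_numeric(
            knn_impute(filtered, self.k_impute), fit=True, state=state
        )
        self.state_ = state
        self.column_names_ = list(filtered.column_names)
        self.numeric_column_names_ = list(filtered.numeric_column_names)
        # training reference rows for imputing new data with training neighbors
        self._train_raw_ = filtered.covariates.copy()
        return self

    def transform(self, table: TrialTable) -> TrialTable:
        if not hasattr(self, "state_"):
            raise ValueError("RegistryPreprocessor is not fitted")
        keep = [c for c in table.column_names if c not in self.state_.dropped_columns]
        if keep != self.column_names_:
            keep_idx = [table.column_names.index(c) for c in self.column_names_]
        else:
            keep_idx = [table.column_names.index(c) for c in keep]
        sub = TrialTable(
            table.covariates[:, keep_idx],
            table.time,
            table.event,
            self.column_names_,
            self.numeric_column_names_,
            None
            if table.clean_covariates is None
            else table.clean_covariates[:, keep_idx],
        )
        if np.isnan(sub.covariates).any():
            sub = self._impute_with_train(sub)
        return normalize_numeric(sub, fit=False, state=self.state_)

    def _impute_with_train(self, table: TrialTable) -> TrialTable:
        # neighbors come from the fitted training rows, not from the new data
        imputer = KNNImputer(
            n_neighbors=min(self.k_impute, len(self._train_raw_) - 1),
            weights="uniform",
        )
        imputer.fit(self._train_raw_)
        filled = imputer.transform(table.covariates)
        out = table.copy()
        out.covariates = _round_binary(filled, table)
        return out
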