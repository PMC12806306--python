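"""Synthetic sparse clinical-trial registry generator.

Emulates a registry extract of intervention trials: one row per trial, a
mostly one-hot (sparse binary) covariate block plus a handful of numeric
covariates, an observed follow-up ``time`` in days, and an ``event`` flag
(1 = normal completion observed, 0 = right-censored).  The generator has a
known proportional-hazards ground truth so that downstream models can be
benchmarked against the Bayes-optimal risk ordering.

Generative model
----------------
Event times are exponential with subject-specific rate

    rate_i = baseline_rate * exp(x_i . beta + eps_i),   eps_i ~ N(0, noise_sd^2)

(optionally Weibull with shape ``weibull_shape``), administrative censoring
is Uniform(0, censor_max), and the observed pair is
``T = min(T_event, T_cens)``, ``E = 1{T_event <= T_cens}``.  Missingness is
injected completely at random into covariate cells only; the pre-blanking
matrix is retained so oracle quantities stay computable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TIME_COL = "time"
EVENT_COL = "event"
RESERVED_COLUMNS = (TIME_COL, EVENT_COL)


def default_coefficients(n_binary: int = 28, n_numeric: int = 5) -> np.ndarray:
    """Default true log-hazard effects: a few strong binary effects, modest
    numeric effects, and a long tail of null covariates — the shape a real
    registry tends to have (a handful of design features drive termination)."""
    beta_bin = np.zeros(n_binary)
    strong = [1.0, -0.8, 0.6, 0.5, -0.4]
    beta_bin[: min(len(strong), n_binary)] = strong[:n_binary]
    beta_num = np.zeros(n_numeric)
    modest = [0.4, -0.3, 0.2]
    beta_num[: min(len(modest), n_numeric)] = modest[:n_numeric]
    return np.concatenate([beta_bin, beta_num])


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic registry generator.

    Parameters mirror the scale of a pregnancy-trial registry extract:
    819 trials, 33 covariates of which 5 numeric, heavy one-hot sparsity.
    """

    n_trials: int = 819
    n_binary: int = 28
    n_numeric: int = 5
    sparsity: float = 0.85
    true_coefficients: np.ndarray | None = None
    baseline_rate: float = 1.0 / 500.0  # per day; mean baseline event time 500 d
    censor_max: float = 2000.0  # days of administrative follow-up
    missing_rate: float = 0.05
    noise_sd: float = 0.5
    weibull_shape: float = 1.0
    round_days: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_coefficients is None:
            self.true_coefficients = default_coefficients(self.n_binary, self.n_numeric)
        self.true_coefficients = np.asarray(self.true_coefficients, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.censor_max <= 0:
            raise ValueError("censor_max must be positive")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")
        p = self.n_binary + self.n_numeric
        if self.true_coefficients.shape != (p,):
            raise ValueError(
                f"true_coefficients must have length n_binary + n_numeric = {p}, "
                f"got {self.true_coefficients.shape}"
            )
        if not np.all(np.isfinite(self.true_coefficients)):
            raise ValueError("true_coefficients must be finite")

    @property
    def n_covariates(self) -> int:
        return self.n_binary + self.n_numeric

    def replace(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


@dataclass
class TrialTable:
    """Covariate matrix plus (time, event) labels — the currency between
    pipeline stages.

    ``covariates`` is an (n, p) float array; missing cells are NaN.  ``time``
    holds strictly positive observed follow-up in days, ``event`` is 1 for an
    observed completion and 0 for a censored record.  ``clean_covariates``,
    when present, is the pre-missingness matrix retained by the generator so
    oracle risk scores stay computable.
    """

    covariates: np.ndarray
    time: np.ndarray
    event: np.ndarray
    column_names: list[str]
    numeric_column_names: list[str] = field(default_factory=list)
    clean_covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n, p = self.covariates.shape
        if len(self.time) != n or len(self.event) != n:
            raise ValueError("time/event length must match covariate rows")
        if len(self.column_names) != p:
            raise ValueError("column_names length must match covariate columns")
        if np.any(self.time <= 0):
            raise ValueError("observed times must be strictly positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event must be 0/1")
        if n and np.isnan(self.covariates).all(axis=1).any():
            raise ValueError("no row may be entirely missing")

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=self.column_names)
        df[TIME_COL] = self.time
        df[EVENT_COL] = self.event
        return df

    def copy(self) -> "TrialTable":
        return TrialTable(
            self.covariates.copy(),
            self.time.copy(),
            self.event.copy(),
            list(self.column_names),
            list(self.numeric_column_names),
            None if self.clean_covariates is None else self.clean_covariates.copy(),
        )

    def subset(self, idx: np.ndarray) -> "TrialTable":
        return TrialTable(
            self.covariates[idx],
            self.time[idx],
            self.event[idx],
            list(self.column_names),
            list(self.numeric_column_names),
            None if self.clean_covariates is None else self.clean_covariates[idx],
        )


def generate_registry(cfg: GeneratorConfig) -> TrialTable:
    """Draw a synthetic registry under ``cfg``; deterministic for fixed seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, pb, pn = cfg.n_trials, cfg.n_binary, cfg.n_numeric

    xb = (rng.random((n, pb)) >= cfg.sparsity).astype(float)
    xn = rng.standard_normal((n, pn))
    x = np.concatenate([xb, xn], axis=1)

    eta = x @ cfg.true_coefficients
    eps = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
    rate = cfg.baseline_rate * np.exp(eta + eps)
    # exponential draw; Weibull shape k rescales: T = E^{1/k} / rate^{1/k} with
    # cumulative hazard H(t) = (rate * t)^k is equivalent to (E/rate^k)^{1/k}
    e_std = rng.exponential(1.0, size=n)
    t_event = np.power(e_std, 1.0 / cfg.weibull_shape) / np.power(
        rate, 1.0 / cfg.weibull_shape
    )
    t_cens = rng.uniform(0.0, cfg.censor_max, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if cfg.round_days:
        time = np.maximum(np.ceil(time), 1.0)
    else:
        time = np.maximum(time, np.finfo(float).tiny)

    if event.sum() == 0:
        warnings.warn("generated registry contains no observed events", stacklevel=2)

    clean = x.copy()
    if cfg.missing_rate > 0:
        mask = rng.random((n, cfg.n_covariates)) < cfg.missing_rate
        # keep at least one observed covariate per row
        full_rows = mask.all(axis=1)
        if full_rows.any():
            keep = rng.integers(0, cfg.n_covariates, size=int(full_rows.sum()))
            mask[np.flatnonzero(full_rows), keep] = False
        x = x.copy()
        x[mask] = np.nan

    names = [f"bin_{i}" for i in range(pb)] + [f"num_{i}" for i in range(pn)]
    return TrialTable(
        covariates=x,
        time=time,
        event=event,
        column_names=names,
        numeric_column_names=[f"num_{i}" for i in range(pn)],
        clean_covariates=clean,
    )


def true_risk(cfg: GeneratorConfig, table: TrialTable) -> np.ndarray:
    """The generator's true log-hazard x.beta per row (without noise) — the
    Bayes-optimal risk score for ranking metrics."""
    x = table.clean_covariates if table.clean_covariates is not None else table.covariates
    if np.isnan(x).any():
        raise ValueError("true_risk requires the pre-missingness covariate matrix")
    if x.shape[1] != cfg.true_coefficients.shape[0]:
        raise ValueError(
            f"dimension mismatch: table has {x.shape[1]} covariates, "
            f"config has {cfg.true_coefficients.shape[0]} coefficients"
        )
    return x @ cfg.true_coefficients


def write_csv(table: TrialTable, path) -> None:
    """Serialize as comma-delimited UTF-8 with a header; missing cells empty."""
    table.to_frame().to_csv(path, index=False)


def read_csv(path, numeric_columns: list[str] | None = None) -> TrialTable:
    """Read a registry CSV; ``time``/``event`` columns are required labels,
    everything else is a covariate.  Empty cells become missing markers."""
    df = pd.read_csv(path)
    for col in RESERVED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"input file lacks required column '{col}'")
    cov_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if numeric_columns is None:
        numeric_columns = [c for c in cov_cols if c.startswith("num_")]
    return TrialTable(
        covariates=df[cov_cols].to_numpy(dtype=float),
        time=df[TIME_COL].to_numpy(dtype=float),
        event=df[EVENT_COL].to_numpy(),
        column_names=cov_cols,
        numeric_column_names=[c for c in numeric_columns if c in cov_cols],
    )
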