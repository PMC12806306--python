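"""Deep Cox machinery: risk head, Breslow partial-likelihood loss, Breslow
baseline-hazard estimator, and survival-curve prediction.

Under proportional hazards the conditional hazard factorizes as
``lambda(t|x) = lambda0(t) * exp(h(x))``.  The negative log partial
likelihood with the Breslow convention for ties is

    L = - sum_{i: E_i = 1} [ h_i - log sum_{j in R(T_i)} exp(h_j) ]

with risk set ``R(t) = {j : T_j >= t}`` (tied event times share the full
risk set).  ``cox_nll_breslow`` evaluates it with a numerically stable
log-sum-exp and, by default, normalizes by the number of events so the loss
magnitude is batch-size invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import BatchNorm, Dense, Dropout, ReLU, Sequential


@dataclass
class BaselineHazard:
    """Breslow cumulative baseline hazard: a non-decreasing right-continuous
    step function with jumps only at observed event times; H0(0) = 0."""

    event_times: np.ndarray  # unique event times, increasing
    cumulative: np.ndarray  # H0 at each event time

    def cumulative_hazard(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        out = np.where(idx > 0, self.cumulative[np.maximum(idx - 1, 0)], 0.0)
        return out


@dataclass
class SurvivalCurve:
    """Predicted survival probabilities on a shared time grid.

    ``values[i, k]`` is S(times[k] | x_i); rows start at 1 (for times >= 0
    grids starting at 0) and are non-increasing in t.
    """

    times: np.ndarray
    values: np.ndarray  # (n_subjects, n_times)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    def at(self, t: float) -> np.ndarray:
        """Step-interpolated survival at time t for every subject."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return np.ones(self.values.shape[0])
        return self.values[:, idx]


def _order_by_time(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    return times[order], events[order], order


def cox_nll_breslow(
    scores, times, events, normalize: bool = True
) -> float:
    """Negative Breslow partial log-likelihood of ``scores``.

    Requires at least one event; with ``normalize`` (default) the sum is
    divided by the event count for batch-size invariance.
    """
    loss, _ = cox_nll_breslow_with_grad(scores, times, events, normalize)
    return loss


def cox_nll_breslow_with_grad(
    scores, times, events, normalize: bool = True
) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the score vector."""
    scores = np.asarray(scores, dtype=float).ravel()
    t_s, e_s, order = _order_by_time(times, events)
    s_s = scores[order]
    n = len(s_s)
    n_events = int(e_s.sum())
    if n_events == 0:
        raise ValueError(
            "batch contains no events; use larger or event-stratified batches"
        )

    smax = s_s.max()
    exp_s = np.exp(s_s - smax)
    suffix = np.cumsum(exp_s[::-1])[::-1]  # suffix[k] = sum_{j >= k} exp_s[j]

    # group tied times: risk set of a tied block starts at the block head
    heads = np.flatnonzero(np.concatenate([[True], np.diff(t_s) > 0]))
    block_of = np.repeat(np.arange(len(heads)), np.diff(np.append(heads, n)))
    risk_sum = suffix[heads]  # scaled by exp(-smax)

    ev = e_s == 1
    log_risk = np.log(risk_sum) + smax
    loss = -(s_s[ev] - log_risk[block_of[ev]]).sum()

    # gradient: dL/ds_k = -(E_k - exp_s_k * sum_{blocks b: t_b <= T_k} d_b / risk_sum_b)
    d_block = np.bincount(block_of[ev], minlength=len(heads)).astype(float)
    cum_ratio = np.cumsum(d_block / risk_sum)  # over blocks, increasing time
    grad_sorted = -(e_s - exp_s * cum_ratio[block_of])

    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    if normalize:
        loss /= n_events
        grad = grad / n_events
    return float(loss), grad


def breslow_baseline(scores, times, events) -> BaselineHazard:
    """Breslow estimator of the cumulative baseline hazard:
    ``H0(t) = sum_{event times T_i <= t} d_i / sum_{j in R(T_i)} exp(s_j)``."""
    scores = np.asarray(scores, dtype=float).ravel()
    t_s, e_s, order = _order_by_time(times, events)
    s_s = scores[order]
    if e_s.sum() == 0:
        raise ValueError("no events: baseline hazard undefined")
    smax = s_s.max()
    exp_s = np.exp(s_s - smax)
    suffix = np.cumsum(exp_s[::-1])[::-1]

    n = len(t_s)
    heads = np.flatnonzero(np.concatenate([[True], np.diff(t_s) > 0]))
    block_of = np.repeat(np.arange(len(heads)), np.diff(np.append(heads, n)))
    d_block = np.bincount(block_of[e_s == 1], minlength=len(heads)).astype(float)
    risk_sum = suffix[heads] * np.exp(smax)

    has_event = d_block > 0
    increments = d_block[has_event] / risk_sum[has_event]
    return BaselineHazard(
        event_times=t_s[heads][has_event],
        cumulative=np.cumsum(increments),
    )


def predict_survival(
    baseline: BaselineHazard, scores, t_grid
) -> SurvivalCurve:
    """Per-subject survival curves ``S(t|x) = exp(-H0(t) * exp(score))``."""
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) < 0):
        raise ValueError("time grid must be non-decreasing")
    scores = np.atleast_1d(np.asarray(scores, dtype=float)).ravel()
    h0 = baseline.cumulative_hazard(t_grid)  # (m,)
    values = np.exp(-np.outer(np.exp(scores), h0))
    return SurvivalCurve(times=t_grid, values=values)


class SurvivalHead:
    """Single-hidden-layer risk network: Dense -> BatchNorm -> ReLU ->
    Dropout -> linear unit, emitting one risk score h(x) per row.

    Evaluation mode disables dropout and uses running batch-norm statistics,
    so scores are deterministic at inference.
    """

    def __init__(
        self,
        input_dim: int,
        hidden_width: int = 16,
        dropout: float = 0.1,
        batch_norm: bool = True,
        rng: np.random.Generator | int | None = None,
    ):
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        layers: list = [Dense(input_dim, hidden_width, rng)]
        if batch_norm:
            layers.append(BatchNorm(hidden_width))
        layers += [ReLU(), Dropout(dropout, rng), Dense(hidden_width, 1, rng)]
        self.net = Sequential(layers)
        self.input_dim = input_dim

    def forward(self, y: np.ndarray, training: bool = False) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} latent columns")
        return self.net.forward(y, training)

    def risk_score(self, y: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode scores, one scalar per row."""
        return self.forward(y, training=False).ravel()

    def params(self):
        return self.net.params()

    def grads(self):
        return self.net.grads()

    def zero_grad(self):
        self.net.zero_grad()
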