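"""Censoring-aware evaluation: concordance index, Kaplan-Meier estimate of
the censoring distribution, and the inverse-probability-of-censoring-weighted
(IPCW) Brier score with its time curve.

Orientation convention: risk scores are log-hazard-like — a HIGHER risk must
pair with an EARLIER event for a pair to count as concordant, so C = 1 is
the optimum and C = 0.5 is random ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .survival import SurvivalCurve


@dataclass
class ConcordanceResult:
    """Concordance index with its pair bookkeeping.

    ``comparable`` counts ordered pairs (i, j) with T_i < T_j and E_i = 1;
    ``concordant`` those with risk_i > risk_j; ``risk_ties`` get half credit.
    """

    c_index: float
    concordant: int
    comparable: int
    risk_ties: int
    time_ties: int

    def __float__(self) -> float:
        return self.c_index


def concordance_index(risks, times, events) -> ConcordanceResult:
    """Harrell's C: among comparable pairs, the fraction ranked correctly.

    A pair is comparable iff the earlier subject's event was observed; tied
    risk scores receive 0.5 credit.  Counting is integer-exact (half credits
    are folded in by doubling) before the final division.
    """
    risks = np.asarray(risks, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events, dtype=int).ravel()
    if not len(risks) == len(times) == len(events):
        raise ValueError("risks, times and events must have equal length")

    t_lt = times[:, None] < times[None, :]
    comp = t_lt & (events[:, None] == 1)
    conc = comp & (risks[:, None] > risks[None, :])
    ties = comp & (risks[:, None] == risks[None, :])

    n_comp = int(comp.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs (all censored or simultaneous)")
    n_conc = int(conc.sum())
    n_ties = int(ties.sum())
    n_time_ties = int((np.triu(times[:, None] == times[None, :], k=1)).sum())
    c = (2 * n_conc + n_ties) / (2 * n_comp)
    return ConcordanceResult(c, n_conc, n_comp, n_ties, n_time_ties)


@dataclass
class CensoringEstimate:
    """Kaplan-Meier estimate G(t) of the censoring survival function.

    Product-limit with the censoring indicator (1 - E) as the "event":
    subjects whose completion was observed leave the risk set without a
    drop.  Right-continuous; G(0) = 1.
    """

    drop_times: np.ndarray  # times with >=1 censoring, increasing
    values: np.ndarray  # G immediately after each drop time

    def evaluate(self, t, left_limit: bool = False) -> np.ndarray:
        """G(t) (right-continuous), or the left limit G(t-) if requested."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if len(self.drop_times) == 0:
            return np.ones_like(t)
        side = "left" if left_limit else "right"
        idx = np.searchsorted(self.drop_times, t, side=side)
        return np.where(idx > 0, self.values[np.maximum(idx - 1, 0)], 1.0)


def km_censoring(times, events) -> CensoringEstimate:
    """Kaplan-Meier estimator of the censoring distribution G.

    At each distinct time t with c censorings among n at risk
    (n = #{T_j >= t}), G drops by the factor (1 - c/n).
    """
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events, dtype=int).ravel()
    if len(times) == 0:
        raise ValueError("empty sample")
    order = np.argsort(times, kind="stable")
    t_s, e_s = times[order], events[order]
    n = len(t_s)

    uniq, start = np.unique(t_s, return_index=True)
    at_risk = n - start
    n_cens = np.array([(e_s[t_s == u] == 0).sum() for u in uniq])
    has_drop = n_cens > 0
    factors = 1.0 - n_cens[has_drop] / at_risk[has_drop]
    return CensoringEstimate(
        drop_times=uniq[has_drop], values=np.cumprod(factors)
    )


def brier_score(
    surv_at_t: np.ndarray,
    times,
    events,
    t: float,
    censoring: CensoringEstimate,
    censor_eval: str = "exact",
) -> float:
    """IPCW Brier score at horizon t.

    ``surv_at_t[i]`` is the predicted S(t | x_i).  Observed completions with
    T_i <= t contribute S^2 / G(T_i); subjects still at risk past t contribute
    (1 - S)^2 / G(t); censored-before-t subjects contribute nothing directly
    (the weights redistribute their mass).  ``censor_eval='exact'`` evaluates
    G exactly at T_i; ``'left'`` uses the left limit G(T_i-), the convention
    of some references.
    """
    if censor_eval not in ("exact", "left"):
        raise ValueError("censor_eval must be 'exact' or 'left'")
    surv_at_t = np.asarray(surv_at_t, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events, dtype=int).ravel()
    n = len(times)
    if len(surv_at_t) != n:
        raise ValueError("one predicted survival value per subject is required")

    past_event = (times <= t) & (events == 1)
    still_alive = times > t

    g_at_ti = censoring.evaluate(times, left_limit=(censor_eval == "left"))
    g_at_t = float(censoring.evaluate(t)[0])
    if np.any(past_event & (g_at_ti <= 0)) or (still_alive.any() and g_at_t <= 0):
        raise ValueError(
            f"censoring survival G is zero where a weight is needed at t={t}; "
            "truncate the evaluation grid"
        )
    score = np.zeros(n)
    score[past_event] = surv_at_t[past_event] ** 2 / g_at_ti[past_event]
    score[still_alive] = (1.0 - surv_at_t[still_alive]) ** 2 / g_at_t
    return float(score.mean())


@dataclass
class BrierCurve:
    """Brier score over a time grid, with its trapezoid-integrated value
    normalized by the grid span."""

    times: np.ndarray
    values: np.ndarray
    integrated: float


def brier_curve(
    curves: SurvivalCurve,
    times,
    events,
    grid: np.ndarray | None = None,
    censoring: CensoringEstimate | None = None,
    censor_eval: str = "exact",
) -> BrierCurve:
    """Map :func:`brier_score` over a grid of horizons.

    The default grid is 100 equally spaced points from 0 to the 90th
    percentile of the observed times, avoiding the G -> 0 tail; points where
    G vanishes are excluded.
    """
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events, dtype=int).ravel()
    if censoring is None:
        censoring = km_censoring(times, events)
    if grid is None:
        grid = np.linspace(0.0, np.quantile(times, 0.9), 100)
    grid = np.asarray(grid, dtype=float)

    valid = censoring.evaluate(grid) > 0
    grid = grid[valid]
    if len(grid) == 0:
        raise ValueError("no grid point has positive censoring survival")
    values = np.array(
        [
            brier_score(curves.at(t), times, events, t, censoring, censor_eval)
            for t in grid
        ]
    )
    span = grid[-1] - grid[0]
    integrated = float(np.trapezoid(values, grid) / span) if span > 0 else float(
        values[0]
    )
    return BrierCurve(times=grid, values=values, integrated=integrated)
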