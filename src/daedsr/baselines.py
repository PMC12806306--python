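"""Linear Cox proportional hazards, fit by Newton-Raphson on the Breslow
partial likelihood — implemented rather than wrapped so it doubles as an
independent oracle for the deep models' loss machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .models import DeepSurv
from .survival import breslow_baseline, predict_survival
from .util import check_survival_y


def _breslow_derivatives(beta, x, times, events):
    """Unnormalized negative partial log-likelihood, gradient and Hessian.

    Sorted-suffix formulation: with w_j = exp(x_j . beta) and block risk sums
    S0 = sum w, S1 = sum w x, S2 = sum w x x^T over R(T_i),
    nll  = -sum_events (eta_i - log S0),
    grad = -sum_events (x_i - S1/S0),
    hess =  sum_events (S2/S0 - (S1/S0)(S1/S0)^T).
    """
    n, p = x.shape
    order = np.argsort(times, kind="stable")
    t_s, e_s, x_s = times[order], events[order], x[order]
    eta = x_s @ beta
    m = eta.max()
    w = np.exp(eta - m)

    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * x_s)[::-1], axis=0)[::-1]
    s2 = np.cumsum((w[:, None, None] * (x_s[:, :, None] * x_s[:, None, :]))[::-1], axis=0)[::-1]

    heads = np.flatnonzero(np.concatenate([[True], np.diff(t_s) > 0]))
    block_of = np.repeat(np.arange(len(heads)), np.diff(np.append(heads, n)))

    ev = e_s == 1
    hb = heads[block_of[ev]]
    s0_e, s1_e, s2_e = s0[hb], s1[hb], s2[hb]
    mean = s1_e / s0_e[:, None]

    nll = -(eta[ev] - (np.log(s0_e) + m)).sum()
    grad = -(x_s[ev] - mean).sum(axis=0)
    hess = (
        s2_e / s0_e[:, None, None] - mean[:, :, None] * mean[:, None, :]
    ).sum(axis=0)
    return nll, grad, hess


@dataclass
class LinearCphFit:
    """Result of a linear Cox fit: coefficients, convergence diagnostics and
    the final (unnormalized, unpenalized) negative partial log-likelihood."""

    coef: np.ndarray
    converged: bool
    n_iter: int
    final_nll: float


def fit_linear_cph(
    covariates,
    times,
    events,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 1e-6,
) -> LinearCphFit:
    """Newton-Raphson maximization of the Breslow partial likelihood.

    A small ridge penalty (default 1e-6) stabilizes separation and
    collinearity; convergence is declared when the penalized gradient
    max-norm falls below ``tol``.  On non-convergence the best iterate is
    returned with a warning.
    """
    x = np.asarray(covariates, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.isnan(x).any():
        raise ValueError("covariates must have no missing cells")
    if events.sum() == 0:
        raise ValueError("at least one event is required")
    const = np.ptp(x, axis=0) == 0
    if const.any():
        raise ValueError(f"constant covariate column(s) at index {np.flatnonzero(const)}")

    n, p = x.shape
    beta = np.zeros(p)
    nll, grad, hess = _breslow_derivatives(beta, x, times, events)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g_pen = grad + ridge * beta
        h_pen = hess + ridge * np.eye(p)
        try:
            step = np.linalg.solve(h_pen, g_pen)
        except np.linalg.LinAlgError:
            warnings.warn("singular Hessian; increasing ridge", stacklevel=2)
            h_pen = hess + max(ridge, 1e-3) * np.eye(p)
            step = np.linalg.solve(h_pen, g_pen)
        # backtracking on the penalized objective
        pen_obj = nll + 0.5 * ridge * beta @ beta
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            nll_c, grad_c, hess_c = _breslow_derivatives(cand, x, times, events)
            if nll_c + 0.5 * ridge * cand @ cand <= pen_obj + 1e-12:
                break
            scale /= 2.0
        beta, nll, grad, hess = cand, nll_c, grad_c, hess_c
        if np.abs(grad + ridge * beta).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"linear Cox fit did not converge in {max_iter} iterations", stacklevel=2
        )
    return LinearCphFit(coef=beta, converged=converged, n_iter=it, final_nll=float(nll))


class CoxPHNewton(BaseEstimator):
    """Linear Cox proportional hazards, scikit-learn estimator surface.

    ``predict`` returns the linear risk score X @ coef_; survival curves use
    the Breslow baseline fitted on the training data.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100, ridge: float = 1e-6):
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        times, events = check_survival_y(y)
        res = fit_linear_cph(X, times, events, self.tol, self.max_iter, self.ridge)
        self.coef_ = res.coef
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.final_nll_ = res.final_nll
        self.n_features_in_ = X.shape[1]
        self.baseline_hazard_ = breslow_baseline(X @ self.coef_, times, events)
        return self

    def predict(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_

    def predict_survival_function(self, X, times=None):
        if times is None:
            times = np.concatenate([[0.0], self.baseline_hazard_.event_times])
        return predict_survival(self.baseline_hazard_, self.predict(X), times)

    def score(self, X, y) -> float:
        from .evaluation import concordance_index

        times, events = check_survival_y(y)
        return concordance_index(self.predict(X), times, events).c_index


def fit_deepsurv(X, y, validation_data=None, **kwargs) -> DeepSurv:
    """Convenience wrapper: construct and fit the plain DeepSurv baseline."""
    model = DeepSurv(**kwargs)
    return model.fit(X, y, validation_data=validation_data)
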