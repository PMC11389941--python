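"""Cox proportional-hazards building blocks.

Breslow-approximation partial likelihood, its derivatives, and a small
Newton solver.  These primitives back the univariate concordance filter,
the zero-penalty branch of the Lasso signature, and the loss of the
neural survival model, so they are written once here and shared.
"""

from __future__ import annotations

import numpy as np

from .errors import EstimationError

__all__ = [
    "cox_partial_loss",
    "breslow_neg_log_partial_likelihood",
    "newton_cox_fit",
]


def _validate_outcomes(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1-D arrays of equal length")
    if not np.all(np.isfinite(time)):
        raise ValueError("survival times must be finite")
    return time, event


def breslow_neg_log_partial_likelihood(
    scores: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Negative Cox log partial likelihood (Breslow ties), summed over events.

    ``scores`` is the linear predictor (higher = higher hazard).  For each
    event i the contribution is ``-(s_i - log sum_{j: t_j >= t_i} exp(s_j))``;
    tied event times share one risk set (Breslow).
    """
    time, event = _validate_outcomes(time, event)
    scores = np.asarray(scores, dtype=float)
    if not event.any():
        raise EstimationError("partial likelihood undefined with zero events")
    order = np.argsort(-time, kind="stable")  # decreasing time
    s = scores[order]
    t = time[order]
    e = event[order]
    # numerically stable running log-sum-exp over the growing risk set
    smax = s.max()
    cum = np.cumsum(np.exp(s - smax))
    # risk set of subject k (in decreasing-time order) = all j with t_j >= t_k;
    # with ties, extend to the last index sharing the same time
    idx = np.searchsorted(-t, -t, side="right") - 1
    log_risk = np.log(cum[idx]) + smax
    return float(np.sum(log_risk[e] - s[e]))


def cox_partial_loss(scores, time, event) -> float:
    """Breslow negative log partial likelihood averaged over events.

    Location-invariant in the scores; used as the training objective of the
    neural survival model and as the cross-validation loss for the Lasso
    penalty choice.
    """
    time, event = _validate_outcomes(time, event)
    n_events = int(np.count_nonzero(event))
    if n_events == 0:
        raise EstimationError("Cox partial loss undefined with zero events")
    return breslow_neg_log_partial_likelihood(scores, time, event) / n_events


def _loss_grad_hess(beta, X, time, event):
    """Value, gradient and Hessian of the Breslow negative log partial likelihood."""
    order = np.argsort(-time, kind="stable")
    Xo = X[order]
    t = time[order]
    e = event[order]
    eta = Xo @ beta
    emax = eta.max()
    w = np.exp(eta - emax)
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * Xo, axis=0)
    S2 = np.cumsum(w[:, None, None] * (Xo[:, :, None] * Xo[:, None, :]), axis=0)
    idx = np.searchsorted(-t, -t, side="right") - 1
    S0r = S0[idx]
    S1r = S1[idx]
    S2r = S2[idx]
    ll = np.sum(eta[e] - (np.log(S0r[e]) + emax))
    mean = S1r[e] / S0r[e, None]
    grad = -(Xo[e].sum(axis=0) - mean.sum(axis=0))
    cov = S2r[e] / S0r[e, None, None] - mean[:, :, None] * mean[:, None, :]
    hess = cov.sum(axis=0)
    return -ll, grad, hess


def newton_cox_fit(
    X,
    time,
    event,
    *,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> np.ndarray:
    """Unpenalized Cox fit by damped Newton iteration with Breslow ties.

    Returns the coefficient vector.  Raises :class:`EstimationError` when the
    data carry no events or the iteration fails to reduce the objective
    (e.g. monotone likelihood under perfect separation).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(time)) == X.shape[1]:
        X = X.T
    time, event = _validate_outcomes(time, event)
    if not event.any():
        raise EstimationError("cannot fit Cox model: zero events")
    n, p = X.shape
    beta = np.zeros(p)
    loss, grad, hess = _loss_grad_hess(beta, X, time, event)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - singular Hessian
            raise EstimationError("singular Hessian in Newton iteration") from exc
        # damped update: halve until the objective decreases
        alpha = 1.0
        for _ in range(30):
            new_beta = beta - alpha * step
            new_loss, new_grad, new_hess = _loss_grad_hess(new_beta, X, time, event)
            if new_loss <= loss + 1e-14:
                break
            alpha /= 2.0
        else:
            raise EstimationError("Newton iteration failed to decrease the objective")
        delta = np.max(np.abs(new_beta - beta))
        beta, loss, grad, hess = new_beta, new_loss, new_grad, new_hess
        if delta < tol:
            break
    else:
        if np.max(np.abs(grad)) > 1e-4:
            raise EstimationError("Newton iteration did not converge")
    return beta
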