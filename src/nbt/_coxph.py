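"""Newton-Raphson solver for the Cox proportional-hazards partial likelihood.

Ties in event times are handled with the Efron approximation. A fully
vectorised fast path covers the common case of distinct survival times;
tied times fall back to a grouped loop. The solver is deliberately small
and allocation-light because signature selection evaluates thousands of
candidate models per run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoxFit", "cox_newton"]


@dataclass
class CoxFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n: int
    n_events: int


def _loglik_grad_info(X: np.ndarray, eta: np.ndarray, event: np.ndarray,
                      group_end: np.ndarray, group_start: np.ndarray
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron log partial likelihood, gradient and information.

    Inputs are sorted by descending time so the risk set of a tied-time
    group is the prefix ending at the group's last row.
    """
    n, p = X.shape
    w = np.exp(eta)
    Xw = X * w[:, None]
    S0 = np.cumsum(w)
    S1 = np.cumsum(Xw, axis=0)
    S2 = np.cumsum(X[:, :, None] * Xw[:, None, :], axis=0)

    if group_end.size == n:  # all times distinct: vectorised over event rows
        ev = np.flatnonzero(event == 1)
        if ev.size == 0:
            return 0.0, np.zeros(p), np.zeros((p, p))
        s0 = S0[ev]
        mu = S1[ev] / s0[:, None]
        ll = float(np.sum(eta[ev] - np.log(s0)))
        grad = X[ev].sum(axis=0) - mu.sum(axis=0)
        info = (S2[ev] / s0[:, None, None]).sum(axis=0) \
            - np.einsum("ei,ej->ij", mu, mu)
        return ll, grad, info

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for st, en in zip(group_start, group_end):
        dmask = event[st:en + 1] == 1
        d = int(dmask.sum())
        if d == 0:
            continue
        rows = np.arange(st, en + 1)[dmask]
        s0R, s1R, s2R = S0[en], S1[en], S2[en]
        s0D = np.exp(eta[rows]).sum()
        s1D = (X[rows] * np.exp(eta[rows])[:, None]).sum(axis=0)
        s2D = np.einsum("ni,nj->ij", X[rows] * np.exp(eta[rows])[:, None], X[rows])
        frac = np.arange(d) / d
        phi = s0R - frac * s0D                                  # (d,)
        z1 = s1R[None, :] - frac[:, None] * s1D[None, :]        # (d, p)
        z2 = s2R[None] - frac[:, None, None] * s2D[None]        # (d, p, p)
        mu = z1 / phi[:, None]
        ll += float(eta[rows].sum() - np.log(phi).sum())
        grad += X[rows].sum(axis=0) - mu.sum(axis=0)
        info += (z2 / phi[:, None, None]).sum(axis=0) - np.einsum("ei,ej->ij", mu, mu)
    return ll, grad, info


def cox_newton(X: np.ndarray, time: np.ndarray, event: np.ndarray,
               max_iter: int = 50, tol: float = 1e-8) -> CoxFit:
    """Fit Cox regression coefficients by Newton-Raphson with step-halving."""
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    n_events = int(event.sum())
    if p == 0:
        return CoxFit(np.zeros(0), np.zeros(0), 0.0, True, 0, n, n_events)

    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    # contiguous groups of equal time (descending order)
    boundary = np.flatnonzero(np.diff(ts) != 0)
    group_end = np.append(boundary, n - 1)
    group_start = np.insert(boundary + 1, 0, 0)

    beta = np.zeros(p)
    ll, grad, info = _loglik_grad_info(Xs, Xs @ beta, es, group_end, group_start)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        step = np.linalg.solve(info + 1e-9 * np.eye(p), grad)
        # step-halving keeps the likelihood monotone
        factor = 1.0
        for _ in range(30):
            beta_new = beta + factor * step
            ll_new, grad_new, info_new = _loglik_grad_info(
                Xs, Xs @ beta_new, es, group_end, group_start)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        else:
            break
        delta = np.max(np.abs(beta_new - beta))
        beta, ll, grad, info = beta_new, ll_new, grad_new, info_new
        if delta < tol or np.max(np.abs(beta)) > 50:
            converged = delta < tol
            break

    try:
        cov = np.linalg.inv(info + 1e-9 * np.eye(p))
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    return CoxFit(beta, se, ll, converged, it, n, n_events)
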