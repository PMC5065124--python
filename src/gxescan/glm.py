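"""Batched logistic-regression engine.

Maximum-likelihood logistic fits by iteratively reweighted least squares
(IRLS), vectorised across a leading "item" axis so that many fits sharing a
common shape (one per variant, per replicate or per permutation) run as a
handful of einsum calls.  Convergence is declared when the largest
coefficient change is below `tol` (default 1e-8, max 50 iterations);
non-convergence and separation are flagged, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

# coefficients wandering past this are treated as (quasi-)separation
_DIVERGE_BOUND = 30.0
_W_FLOOR = 1e-10


@dataclass
class BatchedFit:
    """Result of `batched_logistic` over m items.

    beta : (m, p) ML coefficients
    cov : (m, p, p) inverse observed information at the optimum
    loglik : (m,) log-likelihood at the optimum
    converged : (m,) bool; False for separation, singular designs or
        iteration-limit exits
    n_iter : (m,) IRLS iterations used
    """

    beta: np.ndarray
    cov: np.ndarray
    loglik: np.ndarray
    converged: np.ndarray
    n_iter: np.ndarray

    @property
    def se(self) -> np.ndarray:
        d = np.einsum("mpp->mp", self.cov)
        with np.errstate(invalid="ignore"):
            return np.sqrt(d)


def batched_logistic(
    y: np.ndarray,
    X: np.ndarray,
    obs_weight: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> BatchedFit:
    """Fit logistic regressions for m items at once.

    Parameters
    ----------
    y : (n,) or (m, n) binary responses; broadcast over items if 1-d.
    X : (n, p) or (m, n, p) design matrices; broadcast if 2-d.
    obs_weight : optional (n,) or (m, n) prior observation weights.  A zero
        weight excludes the observation from that item's fit (used for
        per-variant missing dosages).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 2:
        X = X[None, :, :]
    if y.ndim == 1:
        y = y[None, :]
    m = max(X.shape[0], y.shape[0])
    n, p = X.shape[1], X.shape[2]
    Xb = np.broadcast_to(X, (m, n, p))
    yb = np.broadcast_to(y, (m, n))
    if obs_weight is None:
        wb = np.ones((1, n))
    else:
        obs_weight = np.asarray(obs_weight, dtype=float)
        wb = obs_weight[None, :] if obs_weight.ndim == 1 else obs_weight
    wb = np.broadcast_to(wb, (m, n))

    beta = np.zeros((m, p))
    n_iter = np.zeros(m, dtype=int)
    diverged = np.zeros(m, dtype=bool)
    active = np.ones(m, dtype=bool)

    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Xa, ya, wa, ba = Xb[idx], yb[idx], wb[idx], beta[idx]
        eta = np.einsum("mnp,mp->mn", Xa, ba)
        mu = expit(eta)
        var = np.clip(mu * (1.0 - mu), _W_FLOOR, None)
        w = wa * var
        z = eta + (ya - mu) / var
        Xw = Xa * w[:, :, None]
        H = np.einsum("mnp,mnq->mpq", Xw, Xa)
        g = np.einsum("mnp,mn->mp", Xw, z)
        # tiny diagonal-relative ridge keeps exactly-singular designs
        # (constant columns) solvable; such items then blow past the
        # divergence bound and are flagged instead of raising inside
        # np.linalg.  Relative 1e-14 leaves well-posed solutions untouched
        # far below the 1e-8 convergence tolerance.
        diag = np.einsum("mpp->mp", H)
        diag += 1e-14 * diag + 1e-30
        try:
            new = np.linalg.solve(H, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:  # pragma: no cover - ridge normally prevents this
            diverged[idx] = True
            active[idx] = False
            break
        step = np.abs(new - ba).max(axis=1)
        beta[idx] = new
        n_iter[idx] += 1
        div = np.abs(new).max(axis=1) > _DIVERGE_BOUND
        done = step < tol
        diverged[idx[div]] = True
        active[idx[done | div]] = False

    converged = ~diverged & ~active  # `active` still True => hit max_iter

    eta = np.einsum("mnp,mp->mn", Xb, beta)
    mu = expit(eta)
    var = np.clip(mu * (1.0 - mu), _W_FLOOR, None)
    w = wb * var
    Xw = Xb * w[:, :, None]
    H = np.einsum("mnp,mnq->mpq", Xw, Xb)
    cov = np.full((m, p, p), np.nan)
    ok = np.flatnonzero(converged)
    if ok.size:
        try:
            cov[ok] = np.linalg.inv(H[ok])
        except np.linalg.LinAlgError:  # pragma: no cover
            for i in ok:
                try:
                    cov[i] = np.linalg.inv(H[i])
                except np.linalg.LinAlgError:
                    converged[i] = False
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_terms = yb * np.log(mu) + (1.0 - yb) * np.log1p(-mu)
    ll_terms = np.where(wb > 0, np.nan_to_num(ll_terms, neginf=-745.0), 0.0)
    loglik = np.einsum("mn,mn->m", wb, ll_terms)
    return BatchedFit(beta=beta, cov=cov, loglik=loglik, converged=converged, n_iter=n_iter)


def logistic_fit(y, X, obs_weight=None, tol: float = 1e-8, max_iter: int = 50):
    """Single logistic fit; returns (beta, cov, loglik, converged)."""
    fit = batched_logistic(y, np.asarray(X, dtype=float), obs_weight=obs_weight, tol=tol, max_iter=max_iter)
    return fit.beta[0], fit.cov[0], fit.loglik[0], bool(fit.converged[0])
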