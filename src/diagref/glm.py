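"""Weighted Bernoulli-logit maximum likelihood by Newton/IRLS.

This is the inner solver of the diagonal reference model: conditional on the
origin weight w the DRM is an ordinary logistic GLM, so the profile search
only needs a fast, deterministic weighted logistic fitter.  Case weights
multiply log-likelihood contributions.  Convergence: max |score| < 1e-8 or
relative log-likelihood change < 1e-10, with step-halving to keep the
likelihood monotone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit


class RankDeficientDesignError(ValueError):
    """Design matrix is not of full column rank."""


class SeparationWarning(UserWarning):
    """A coefficient diverged (quasi-)complete separation suspected."""


@dataclass
class GLMResult:
    coef: np.ndarray
    names: tuple[str, ...]
    loglik: float
    vcov: np.ndarray
    n_iter: int
    converged: bool
    separated: tuple[str, ...]


def bernoulli_loglik(eta: np.ndarray, y: np.ndarray, weights: np.ndarray) -> float:
    """Sum of case-weighted Bernoulli log-likelihood terms, numerically stable."""
    return float(np.sum(weights * (y * eta - np.logaddexp(0.0, eta))))


def fit_logistic(
    X,
    y,
    weights=None,
    names: tuple[str, ...] | None = None,
    *,
    start: np.ndarray | None = None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    loglik_tol: float = 1e-10,
    check_rank: bool = True,
    separation_bound: float = 15.0,
) -> GLMResult:
    """Weighted maximum-likelihood logistic regression (no implicit intercept)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    n, p = X.shape
    if names is None:
        names = tuple(f"x{i}" for i in range(p))
    if check_rank and np.linalg.matrix_rank(X) < p:
        raise RankDeficientDesignError(f"design with columns {names} is rank deficient")

    beta = np.zeros(p) if start is None else np.array(start, dtype=float)
    eta = X @ beta
    ll = bernoulli_loglik(eta, y, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        score = X.T @ (w * (y - mu))
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        wmu = w * mu * (1.0 - mu)
        H = (X * wmu[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        t = 1.0
        while True:
            cand = beta + t * step
            eta_c = X @ cand
            ll_c = bernoulli_loglik(eta_c, y, w)
            if ll_c >= ll - 1e-12 or t < 1e-8:
                break
            t *= 0.5
        delta_ll = ll_c - ll
        beta, eta, ll = cand, eta_c, ll_c
        if abs(delta_ll) <= loglik_tol * (abs(ll) + 1.0):
            converged = True
            break

    mu = expit(eta)
    wmu = w * mu * (1.0 - mu)
    H = (X * wmu[:, None]).T @ X
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)

    separated = tuple(names[i] for i in np.flatnonzero(np.abs(beta) > separation_bound))
    if separated:
        warnings.warn(
            f"possible separation: |coefficient| > {separation_bound} for {separated}",
            SeparationWarning,
            stacklevel=2,
        )
    return GLMResult(
        coef=beta, names=tuple(names), loglik=ll, vcov=vcov,
        n_iter=it, converged=converged, separated=separated,
    )


def fit_linear(X, y, weights=None, names: tuple[str, ...] | None = None) -> GLMResult:
    """Weighted least squares (identity link), for the continuous-outcome DRM."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    n, p = X.shape
    if names is None:
        names = tuple(f"x{i}" for i in range(p))
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficientDesignError(f"design with columns {names} is rank deficient")
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ beta
    wsum = w.sum()
    sigma2 = float(np.sum(w * resid**2) / wsum)
    ll = -0.5 * wsum * (np.log(2 * np.pi * sigma2) + 1.0)
    XtWX = (X * w[:, None]).T @ X
    vcov = sigma2 * np.linalg.inv(XtWX)
    return GLMResult(coef=beta, names=tuple(names), loglik=ll, vcov=vcov,
                     n_iter=1, converged=True, separated=())
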