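"""Logistic diagonal reference models fitted by profile likelihood over w.

The model for a person with origin i, destination j and covariates x is

    logit P(Y=1) = w * gamma_i + (1 - w) * gamma_j + delta * m + x' beta

where gamma_k is the log of the diagonal odds mu_kk (the baseline for
immobile individuals at level k), w in [0, 1] weighs origin against
destination, and m is an optional indicator of downward and/or upward
mobility whose coefficient delta is the mobility effect proper.  There is no
global intercept: the K diagonal intercepts absorb it.

Conditional on w the model is an ordinary logistic GLM, so estimation is a
one-dimensional profile search: a coarse grid on [0, 1], bounded Brent
refinement, and a final symmetric parabolic polish (which keeps the estimate
invariant, to ~1e-7, under transposing origin and destination, where the
profile mirrors exactly).  Standard errors come from the numerical Hessian
of the full log-likelihood in (gamma, w, beta); the Wald interval for w is
unconstrained and may extend outside [0, 1].  No p-value is reported for w
itself — the parameter is constrained to an interval, so the usual Wald test
against 0 is meaningless; `test_w_against` provides a supplementary test
against an interior null such as 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import glm
from .levels import LEVELS, MARITAL_LEVELS, RANK

W_BOUNDARY_TOL = 1e-6


class UnidentifiableLevelError(ValueError):
    """A level appears in neither origin nor destination."""


class AllDiagonalError(ValueError):
    """Every record is immobile: w is unidentifiable."""


class BoundaryFitError(ValueError):
    """Requested inference is invalid for a boundary/flat fit."""


@dataclass
class DRMSpec:
    """Model configuration.

    mobility_covariate: which moved-indicator(s) to include — "downward"
    and "upward" match the published Model 1 / Model 2; "both" includes two
    indicators; "none" drops the mobility term.
    covariates: record columns entering x (categorical columns expand to
    dummies against their stated reference level).
    """

    mobility_covariate: str = "downward"
    covariates: tuple[str, ...] = ()
    link: str = "logit"
    weights_column: str | None = "weight"
    levels: tuple[str, ...] = LEVELS

    def __post_init__(self) -> None:
        if self.mobility_covariate not in ("none", "downward", "upward", "both"):
            raise ValueError(f"unknown mobility_covariate {self.mobility_covariate!r}")
        if self.link not in ("logit", "identity"):
            raise ValueError(f"unknown link {self.link!r}")


@dataclass
class ProfilePoint:
    w: float
    loglik: float
    inner_converged: bool


@dataclass
class DRMFit:
    """Fitted DRM: diagonal intercepts, origin weight, covariate effects."""

    spec: DRMSpec
    levels: tuple[str, ...]
    gamma: np.ndarray              # log-odds diagonal intercepts
    gamma_se: np.ndarray
    diagonal_odds: pd.DataFrame    # level, odds, ci_low, ci_high, p
    w_hat: float
    w_se: float
    w_ci: tuple[float, float]
    beta: pd.DataFrame             # term, coef, se, odds_ratio, ci_low, ci_high, p
    loglik: float
    vcov: pd.DataFrame
    n: int
    weighted_n: float
    converged: bool
    n_profile_evals: int
    boundary: bool
    flat_profile: bool
    vcov_conditional: bool
    profile: list[ProfilePoint] = field(default_factory=list, repr=False)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(self.vcov.columns)

    def to_json(self) -> str:
        payload = {
            "levels": list(self.levels),
            "gamma": self.gamma.tolist(),
            "gamma_se": self.gamma_se.tolist(),
            "diagonal_odds": self.diagonal_odds.to_dict(orient="records"),
            "w_hat": self.w_hat,
            "w_se": self.w_se,
            "w_ci": list(self.w_ci),
            "beta": self.beta.to_dict(orient="records"),
            "loglik": self.loglik,
            "n": self.n,
            "weighted_n": self.weighted_n,
            "converged": self.converged,
            "boundary": self.boundary,
            "flat_profile": self.flat_profile,
            "vcov_conditional": self.vcov_conditional,
            "mobility_covariate": self.spec.mobility_covariate,
        }
        return json.dumps(payload, indent=2, allow_nan=True)


# ---------------------------------------------------------------------------
# design construction

def covariate_matrix(df: pd.DataFrame, covariates: tuple[str, ...]
                     ) -> tuple[np.ndarray, list[str]]:
    """Covariate block: numeric columns as-is, categoricals as dummies.

    marital_status expands against the no_partner reference; any other
    object/categorical column drops its first sorted level.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for c in covariates:
        s = df[c]
        if c == "marital_status":
            for lvl in MARITAL_LEVELS[1:]:
                cols.append((s == lvl).to_numpy(dtype=float))
                names.append(lvl)
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.dropna().unique())
            for lvl in levels[1:]:
                cols.append((s == lvl).to_numpy(dtype=float))
                names.append(f"{c}[{lvl}]")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(c)
    if not cols:
        return np.empty((len(df), 0)), names
    return np.column_stack(cols), names


def _mobility_matrix(df: pd.DataFrame, mobility: str) -> tuple[np.ndarray, list[str]]:
    o = df["origin"].map(RANK).to_numpy()
    d = df["destination"].map(RANK).to_numpy()
    down = (d < o).astype(float)
    up = (d > o).astype(float)
    if mobility == "none":
        return np.empty((len(df), 0)), []
    if mobility == "downward":
        return down[:, None], ["downward"]
    if mobility == "upward":
        return up[:, None], ["upward"]
    return np.column_stack([down, up]), ["downward", "upward"]


@dataclass
class _Prepared:
    O: np.ndarray          # n x K origin one-hot
    D: np.ndarray          # n x K destination one-hot
    MC: np.ndarray         # n x (m + p) mobility + covariate block
    y: np.ndarray
    weights: np.ndarray
    names: list[str]       # gamma names + MC names


def _prepare(df: pd.DataFrame, spec: DRMSpec) -> _Prepared:
    levels = spec.levels
    o = df["origin"].to_numpy()
    d = df["destination"].to_numpy()
    O = (o[:, None] == np.asarray(levels)).astype(float)
    D = (d[:, None] == np.asarray(levels)).astype(float)
    seen = (O.sum(axis=0) + D.sum(axis=0)) > 0
    if not seen.all():
        missing = [levels[i] for i in np.flatnonzero(~seen)]
        raise UnidentifiableLevelError(
            f"levels {missing} appear in neither origin nor destination"
        )
    M, mnames = _mobility_matrix(df, spec.mobility_covariate)
    C, cnames = covariate_matrix(df, spec.covariates)
    MC = np.hstack([M, C]) if (M.size or C.size) else np.empty((len(df), 0))
    y = df["outcome"].to_numpy(dtype=float)
    if spec.weights_column and spec.weights_column in df.columns:
        w = df[spec.weights_column].to_numpy(dtype=float)
    else:
        w = np.ones(len(df))
    names = [f"gamma[{lvl}]" for lvl in levels] + mnames + cnames
    return _Prepared(O=O, D=D, MC=MC, y=y, weights=w, names=names)


def build_conditional_design(df: pd.DataFrame, spec: DRMSpec, w: float
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Design at fixed w: column k holds w*1[origin=k] + (1-w)*1[dest=k].

    Returns (X, response, case weights, column names).  No intercept column:
    the K diagonal columns sum to 1 for immobile records and absorb it.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    b = _prepare(df, spec)
    X = np.hstack([w * b.O + (1.0 - w) * b.D, b.MC])
    return X, b.y, b.weights, b.names


def _design(b: _Prepared, w: float) -> np.ndarray:
    return np.hstack([w * b.O + (1.0 - w) * b.D, b.MC])


def _inner(b: _Prepared, w: float, link: str, start=None, check_rank=False) -> glm.GLMResult:
    X = _design(b, w)
    if link == "identity":
        return glm.fit_linear(X, b.y, b.weights, tuple(b.names))
    return glm.fit_logistic(X, b.y, b.weights, tuple(b.names),
                            start=start, check_rank=check_rank)


def fit_inner_glm(design, response, weights=None, link: str = "logit",
                  names=None) -> glm.GLMResult:
    """Weighted GLM fit on an already-constructed conditional design."""
    if link == "identity":
        return glm.fit_linear(design, response, weights, names)
    return glm.fit_logistic(design, response, weights, names)


def profile_loglik(w: float, df: pd.DataFrame, spec: DRMSpec | None = None
                   ) -> ProfilePoint:
    """Log-likelihood maximized over (gamma, beta) at fixed w."""
    spec = spec or DRMSpec()
    b = _prepare(df, spec)
    res = _inner(b, w, spec.link, check_rank=True)
    return ProfilePoint(w=float(w), loglik=res.loglik, inner_converged=res.converged)


# ---------------------------------------------------------------------------
# full-likelihood pieces for inference

def _full_loglik_fn(b: _Prepared, link: str):
    K = b.O.shape[1]
    Og, Dg = b.O, b.D

    def ll(theta: np.ndarray) -> float:
        g = theta[:K]
        w = theta[K]
        beta = theta[K + 1:]
        eta = w * (Og @ g) + (1.0 - w) * (Dg @ g)
        if beta.size:
            eta = eta + b.MC @ beta
        if link == "identity":
            resid = b.y - eta
            wsum = b.weights.sum()
            sigma2 = float(np.sum(b.weights * resid**2) / wsum)
            return -0.5 * wsum * (np.log(2 * np.pi * sigma2) + 1.0)
        return glm.bernoulli_loglik(eta, b.y, b.weights)

    return ll


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    p = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# main fitter

def fit_drm(df: pd.DataFrame, spec: DRMSpec | None = None,
            n_grid: int = 21, xatol: float = 1e-6) -> DRMFit:
    """Fit a DRM by profile likelihood over w in [0, 1].

    Strategy: evaluate the profile on a coarse grid, refine with bounded
    Brent search in the bracketing interval, then polish with a symmetric
    three-point parabolic step.  The returned w maximizes the profile over
    every point evaluated.
    """
    spec = spec or DRMSpec()
    b = _prepare(df, spec)
    K = b.O.shape[1]
    offdiag = float(np.sum(b.weights * (1.0 - np.einsum("ij,ij->i", b.O, b.D))))
    if offdiag == 0:
        raise AllDiagonalError("all records are immobile; w is unidentifiable")

    # rank check once at an interior w
    X0 = _design(b, 0.35)
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise glm.RankDeficientDesignError(
            f"conditional design with columns {b.names} is rank deficient"
        )

    evals: list[tuple[float, glm.GLMResult]] = []

    def prof(w: float, start=None) -> glm.GLMResult:
        res = _inner(b, w, spec.link, start=start)
        evals.append((float(w), res))
        return res

    grid = np.linspace(0.0, 1.0, n_grid)
    start = None
    grid_res = []
    for w in grid:
        res = prof(w, start=start)
        start = res.coef
        grid_res.append(res)
    grid_ll = np.array([r.loglik for r in grid_res])

    ll_span = grid_ll.max() - grid_ll.min()
    flat = ll_span <= 1e-8 * (abs(grid_ll.max()) + 1.0)
    if flat:
        near = np.flatnonzero(grid_ll >= grid_ll.max() - 1e-10 * (abs(grid_ll.max()) + 1.0))
        w_hat = float(0.5 * (grid[near[0]] + grid[near[-1]]))
        prof(w_hat)
    else:
        i = int(np.argmax(grid_ll))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, n_grid - 1)]
        warm = grid_res[i].coef

        def neg(w: float) -> float:
            return -prof(float(w), start=warm).loglik

        r = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                     options={"xatol": xatol})
        w0 = float(r.x)
        w_hat = w0
        h = 1e-4
        if h <= w0 <= 1.0 - h:
            # symmetric parabolic polish: invariant under profile mirroring
            llm = prof(w0 - h, start=warm).loglik
            ll0 = prof(w0, start=warm).loglik
            llp = prof(w0 + h, start=warm).loglik
            denom = llm - 2.0 * ll0 + llp
            if denom < 0:
                vertex = w0 + 0.5 * h * (llm - llp) / denom
                vertex = float(np.clip(vertex, 0.0, 1.0))
                llv = prof(vertex, start=warm).loglik
                best_ll = max(e[1].loglik for e in evals)
                if llv >= best_ll - 1e-9 * (abs(best_ll) + 1.0):
                    w_hat = vertex
        best_w, best_res = max(evals, key=lambda e: e[1].loglik)
        cur_ll = max(r.loglik for w, r in evals if w == w_hat)
        if best_res.loglik > cur_ll + 1e-9 * (abs(best_res.loglik) + 1.0):
            w_hat = best_w

    final = _inner(b, w_hat, spec.link, start=max(evals, key=lambda e: e[1].loglik)[1].coef)
    boundary = w_hat <= W_BOUNDARY_TOL or w_hat >= 1.0 - W_BOUNDARY_TOL

    # inference from the full Hessian in (gamma, w, beta)
    theta = np.concatenate([final.coef[:K], [w_hat], final.coef[K:]])
    names = b.names[:K] + ["w"] + b.names[K:]
    full_ll = _full_loglik_fn(b, spec.link)
    vcov_conditional = False
    H = _numerical_hessian(full_ll, theta)
    try:
        np.linalg.cholesky(-H)
        vcov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        vcov_conditional = True
        p_full = len(theta)
        vcov = np.full((p_full, p_full), np.nan)
        inner_idx = list(range(K)) + list(range(K + 1, p_full))
        vcov[np.ix_(inner_idx, inner_idx)] = final.vcov
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, np.inf))

    gamma = final.coef[:K]
    gamma_se = se[:K]
    z95 = stats.norm.ppf(0.975)
    diag = pd.DataFrame(
        {
            "level": list(spec.levels),
            "odds": np.exp(gamma),
            "ci_low": np.exp(gamma - z95 * gamma_se),
            "ci_high": np.exp(gamma + z95 * gamma_se),
            "p": 2.0 * stats.norm.sf(np.abs(gamma / gamma_se)),
        }
    )
    w_se = float(se[K])
    w_ci = (w_hat - z95 * w_se, w_hat + z95 * w_se)

    bcoef = final.coef[K:]
    bse = se[K + 1:]
    beta = pd.DataFrame(
        {
            "term": b.names[K:],
            "coef": bcoef,
            "se": bse,
            "odds_ratio": np.exp(bcoef),
            "ci_low": np.exp(bcoef - z95 * bse),
            "ci_high": np.exp(bcoef + z95 * bse),
            "p": 2.0 * stats.norm.sf(np.abs(bcoef / bse)),
        }
    )

    profile_pts = [
        ProfilePoint(w=float(w), loglik=r.loglik, inner_converged=r.converged)
        for w, r in sorted(((w, r) for w, r in evals), key=lambda e: e[0])
    ]
    return DRMFit(
        spec=spec,
        levels=tuple(spec.levels),
        gamma=gamma,
        gamma_se=gamma_se,
        diagonal_odds=diag,
        w_hat=float(w_hat),
        w_se=w_se,
        w_ci=w_ci,
        beta=beta,
        loglik=final.loglik,
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        n=len(df),
        weighted_n=float(b.weights.sum()),
        converged=final.converged,
        n_profile_evals=len(evals),
        boundary=bool(boundary),
        flat_profile=bool(flat),
        vcov_conditional=vcov_conditional,
        profile=profile_pts,
    )


# ---------------------------------------------------------------------------
# post-fit utilities

def test_w_against(fit: DRMFit, null_value: float = 0.5) -> dict:
    """Supplementary Wald test of w against an interior null (default 0.5)."""
    if fit.boundary or fit.flat_profile:
        raise BoundaryFitError(
            "w test refused: the profile optimum is on the boundary or flat, "
            "so the Wald approximation for w is invalid"
        )
    if not np.isfinite(fit.w_se) or fit.w_se <= 0:
        raise BoundaryFitError("w test refused: no valid standard error for w")
    z = (fit.w_hat - null_value) / fit.w_se
    p = 2.0 * stats.norm.sf(abs(z))
    covered = fit.w_ci[0] <= null_value <= fit.w_ci[1]
    return {"null": null_value, "z": float(z), "p": float(p), "ci_covers_null": bool(covered)}


def predict_cell(fit: DRMFit, origin: str, destination: str,
                 covariates: dict | None = None) -> dict:
    """Linear predictor, odds and probability for one mobility-table cell.

    covariates maps beta term names (as in ``fit.beta.term``) to values; the
    mobility indicator implied by (origin, destination) and the fitted spec
    is added automatically.
    """
    levels = dict(zip(fit.levels, fit.gamma))
    if origin not in levels or destination not in levels:
        raise ValueError(f"unknown level in ({origin!r}, {destination!r})")
    eta = fit.w_hat * levels[origin] + (1.0 - fit.w_hat) * levels[destination]
    ro, rd = RANK[origin], RANK[destination]
    status = "downward" if rd < ro else ("upward" if rd > ro else "immobile")
    coefs = dict(zip(fit.beta["term"], fit.beta["coef"]))
    if status in coefs:
        eta += coefs[status]
    if covariates:
        for term, val in covariates.items():
            if term not in coefs:
                raise ValueError(f"unknown covariate term {term!r}")
            if term in ("downward", "upward"):
                continue  # handled structurally
            eta += coefs[term] * val
    return {"eta": float(eta), "odds": float(np.exp(eta)),
            "probability": float(1.0 / (1.0 + np.exp(-eta)))}


def interpolate_odds(odds_origin: float, odds_destination: float, w: float) -> float:
    """Expository odds-scale interpolation w*odds_origin + (1-w)*odds_dest.

    The fitted model combines on the log-odds scale; this helper reproduces
    the direct-on-odds illustrative arithmetic sometimes quoted for DRMs
    (e.g. 0.35*0.41 + 0.65*0.73 = 0.618, versus exp(0.35*log 0.41 +
    0.65*log 0.73) ~ 0.597 on the link scale).
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    return w * odds_origin + (1.0 - w) * odds_destination
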