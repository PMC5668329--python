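"""The two conventional mobility-effect regression designs, and why they fail.

Design 1 ("mobility groups", Table-2 shape): logistic regression of the
outcome on dummies for eight of the nine origin x destination groups, with
the always-advantaged immobile-high group as reference.  Each mobile-group
dummy conflates having moved with the origin and destination positions
themselves, so under a pure origin/destination gradient with no true
mobility effect these dummies still come out "significant".

Design 2 ("origin control", Table-3 shape): logistic regression on mobility
status (upward/downward vs immobile) controlling for origin dummies.  The
status coefficients remain conflated with destination effects.

`demonstrate_linear_dependency` exhibits the structural reason a regression
cannot control for origin, destination and a linear mobility score at once:
the score (destination rank minus origin rank) lies exactly in the span of
the origin and destination terms, so the joint design is rank deficient.
(Replacing the score with upward/downward indicator dummies breaks the exact
collinearity on a 3x3 table, but the fitted "mobility" terms are then just a
reparameterization of origin-destination cell contrasts — the conflation
remains.)  The DRM conditional design, by contrast, is full rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import null_space

from .drm import covariate_matrix
from .levels import RANK

#: Table-2 row order: (origin, destination) with immobile-high as reference.
GROUP_ORDER: tuple[tuple[str, str], ...] = (
    ("high", "high"),      # reference: the always-advantaged group
    ("medium", "medium"),
    ("low", "low"),
    ("high", "medium"),
    ("medium", "low"),
    ("high", "low"),
    ("medium", "high"),
    ("low", "medium"),
    ("low", "high"),
)


@dataclass
class ORTableRow:
    term: str
    kind: str                     # intercept | immobile | downward | upward | mobility | origin | covariate
    odds_ratio: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan
    is_reference: bool = False
    estimate: float = np.nan      # log-odds scale
    se: float = np.nan


@dataclass
class ConventionalFit:
    design: str
    rows: list[ORTableRow]
    loglik: float
    n: int
    params: pd.Series = field(repr=False, default=None)
    vcov: pd.DataFrame = field(repr=False, default=None)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def mobility_pvalues(self) -> pd.Series:
        """p-values of the terms interpreted as 'mobility effects'.

        Design 1: the six mobile-group dummies; design 2: the two
        mobility-status terms.
        """
        kinds = {"downward", "upward"} if self.design == "groups" else {"mobility"}
        rows = [r for r in self.rows if r.kind in kinds and not r.is_reference]
        return pd.Series({r.term: r.p_value for r in rows}).dropna()


@dataclass
class RankReport:
    n_columns: int
    rank: int
    dependent_sets: list[tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.rank > self.n_columns:
            raise ValueError("rank cannot exceed the number of columns")

    @property
    def deficient(self) -> bool:
        return self.rank < self.n_columns


def _glm_fit(X: pd.DataFrame, y, weights) -> sm.GLM:
    model = sm.GLM(np.asarray(y, dtype=float), X,
                   family=sm.families.Binomial(),
                   freq_weights=np.asarray(weights, dtype=float))
    return model.fit()


def _weights(df: pd.DataFrame, weights_col: str | None) -> np.ndarray:
    if weights_col and weights_col in df.columns:
        return df[weights_col].to_numpy(dtype=float)
    return np.ones(len(df))


def _wald_rows(res, terms: list[str]) -> dict[str, ORTableRow]:
    ci = res.conf_int()
    out = {}
    with np.errstate(over="ignore"):  # near-separated dummies: CI bound -> inf
        for t in terms:
            est = float(res.params[t])
            out[t] = ORTableRow(
                term=t, kind="", estimate=est, se=float(res.bse[t]),
                odds_ratio=float(np.exp(est)),
                ci_low=float(np.exp(ci.loc[t, 0])), ci_high=float(np.exp(ci.loc[t, 1])),
                p_value=float(res.pvalues[t]),
            )
    return out


def fit_mobility_group_model(df: pd.DataFrame, covariates: tuple[str, ...] = (),
                             weights_col: str | None = "weight") -> ConventionalFit:
    """Design 1: eight mobility-group dummies against immobile-high."""
    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    present = set(map(tuple, df[["origin", "destination"]].drop_duplicates().to_numpy()))
    kept: list[tuple[str, str]] = []
    for o, d in GROUP_ORDER[1:]:
        if (o, d) not in present:
            warnings.warn(f"mobility group ({o}, {d}) has no records; dummy dropped")
            continue
        X[f"{o}-{d}"] = ((df["origin"] == o) & (df["destination"] == d)).astype(float)
        kept.append((o, d))
    C, cnames = covariate_matrix(df, covariates)
    for j, name in enumerate(cnames):
        X[name] = C[:, j]
    res = _glm_fit(X, df["outcome"], _weights(df, weights_col))
    fitted = _wald_rows(res, [c for c in X.columns])

    def group_kind(o: str, d: str) -> str:
        if o == d:
            return "immobile"
        return "downward" if RANK[d] < RANK[o] else "upward"

    rows = [fitted["intercept"]]
    rows[0].kind = "intercept"
    for o, d in GROUP_ORDER:
        kind = group_kind(o, d)
        if (o, d) == GROUP_ORDER[0]:
            rows.append(ORTableRow(term=f"{o}-{d}", kind=kind, is_reference=True))
        elif (o, d) in kept:
            r = fitted[f"{o}-{d}"]
            r.kind = kind
            rows.append(r)
    for name in cnames:
        r = fitted[name]
        r.kind = "covariate"
        rows.append(r)
    return ConventionalFit(design="groups", rows=rows, loglik=float(res.llf),
                           n=len(df), params=res.params,
                           vcov=pd.DataFrame(res.cov_params()))


def fit_origin_control_model(df: pd.DataFrame, covariates: tuple[str, ...] = (),
                             weights_col: str | None = "weight") -> ConventionalFit:
    """Design 2: mobility status (vs immobile) controlling for origin (vs high)."""
    o = df["origin"].map(RANK)
    d = df["destination"].map(RANK)
    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    X["downward"] = (d < o).astype(float)
    X["upward"] = (d > o).astype(float)
    X["origin_low"] = (df["origin"] == "low").astype(float)
    X["origin_medium"] = (df["origin"] == "medium").astype(float)
    C, cnames = covariate_matrix(df, covariates)
    for j, name in enumerate(cnames):
        X[name] = C[:, j]
    res = _glm_fit(X, df["outcome"], _weights(df, weights_col))
    fitted = _wald_rows(res, list(X.columns))

    rows = [fitted["intercept"]]
    rows[0].kind = "intercept"
    rows.append(ORTableRow(term="immobile", kind="mobility", is_reference=True))
    for t in ("downward", "upward"):
        r = fitted[t]
        r.kind = "mobility"
        rows.append(r)
    for t in ("origin_low", "origin_medium"):
        r = fitted[t]
        r.kind = "origin"
        rows.append(r)
    rows.append(ORTableRow(term="origin_high", kind="origin", is_reference=True))
    for name in cnames:
        r = fitted[name]
        r.kind = "covariate"
        rows.append(r)
    return ConventionalFit(design="origin-control", rows=rows, loglik=float(res.llf),
                           n=len(df), params=res.params,
                           vcov=pd.DataFrame(res.cov_params()))


def demonstrate_linear_dependency(df: pd.DataFrame, coding: str = "score"
                                  ) -> RankReport:
    """Rank of the infeasible origin + destination + mobility design.

    coding="score" (default): intercept, origin and destination position
    dummies, and the linear mobility score destination_rank - origin_rank.
    The score is an exact linear combination of the position terms, so the
    design is structurally rank deficient on any table containing all levels.

    coding="status": upward/downward indicator dummies instead of the score;
    on a full 3x3 table this design is technically full rank (the indicators
    are not additive in origin and destination), which is why status-based
    models are estimable — yet still conflated.
    """
    o = df["origin"].map(RANK).to_numpy(dtype=float)
    d = df["destination"].map(RANK).to_numpy(dtype=float)
    cols = {
        "intercept": np.ones(len(df)),
        "origin_low": (df["origin"] == "low").to_numpy(dtype=float),
        "origin_medium": (df["origin"] == "medium").to_numpy(dtype=float),
        "dest_low": (df["destination"] == "low").to_numpy(dtype=float),
        "dest_medium": (df["destination"] == "medium").to_numpy(dtype=float),
    }
    if coding == "score":
        cols["mobility_score"] = d - o
    elif coding == "status":
        cols["downward"] = (d < o).astype(float)
        cols["upward"] = (d > o).astype(float)
    else:
        raise ValueError(f"unknown coding {coding!r}")
    names = list(cols)
    X = np.column_stack(list(cols.values()))
    rank = int(np.linalg.matrix_rank(X))
    dependent: list[tuple[str, ...]] = []
    ns = null_space(X)
    for k in range(ns.shape[1]):
        v = ns[:, k] / np.max(np.abs(ns[:, k]))
        dependent.append(tuple(n for n, vi in zip(names, v) if abs(vi) > 1e-8))
    return RankReport(n_columns=X.shape[1], rank=rank, dependent_sets=dependent)
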