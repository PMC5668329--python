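"""Monte-Carlo operating characteristics: the conflation argument, quantified.

Data are generated from a logistic DRM with *no* true mobility effect
(delta = 0) but a real origin/destination gradient, and each replicate is
analysed by (a) the DRM with a mobility covariate, (b) the mobility-group
dummy design and (c) the origin-control design.  A method "rejects" when it
declares a mobility effect at level alpha: the DRM when its delta covariate
has p < alpha; the group design when *any* of the six mobile-group dummies
does (both unadjusted and Holm-adjusted variants reported, since the
unadjusted family-wise rate inflates even an honest baseline); the
origin-control design when either mobility-status term does.  Under the
null the DRM's rate should sit at alpha while the conventional designs'
rates reflect conflation with the gradient.

Power and parameter-recovery sweeps complete the picture.  When the fitted
models contain no individual-level covariates, each replicate is collapsed
to the 18 (cell x outcome) rows with case weights before fitting — an exact
aggregation that makes large sweeps cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import conventional, drm, simulate

ALL_METHODS = ("drm_down", "drm_up", "conv_groups", "conv_origin_control")


class StudyConfigError(ValueError):
    pass


@dataclass
class StudyConfig:
    base: simulate.SimulationConfig
    n_reps: int = 1000
    alpha: float = 0.05
    methods: tuple[str, ...] = ("drm_down", "conv_groups", "conv_origin_control")
    master_seed: int = 0
    use_covariates: bool = False   # include age/native/marital in the fitted models

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise StudyConfigError("n_reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise StudyConfigError("alpha must lie in (0, 1)")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise StudyConfigError(f"unknown methods {sorted(unknown)}")


@dataclass
class StudyResult:
    rates: pd.DataFrame        # method, rejection_rate, mc_se, n_used, n_failed
    replicates: pd.DataFrame   # per-replicate audit trail of every decision
    n_reps: int
    alpha: float
    master_seed: int
    extra: pd.DataFrame | None = field(default=None)  # recovery summaries etc.


def aggregate_cells(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse records to (origin, destination, outcome) rows with weights.

    Exact for any fitter that takes case weights, provided the fitted model
    uses no individual-level covariates.
    """
    g = (
        df.groupby(["origin", "destination", "outcome"], sort=True)["weight"]
        .sum()
        .reset_index()
    )
    return g


def _fit_one(df: pd.DataFrame, methods: tuple[str, ...], alpha: float,
             covariates: tuple[str, ...]) -> dict:
    out: dict = {}
    for m in methods:
        try:
            if m in ("drm_down", "drm_up"):
                mob = "downward" if m == "drm_down" else "upward"
                fit = drm.fit_drm(df, drm.DRMSpec(mobility_covariate=mob,
                                                 covariates=covariates))
                p = float(fit.beta.set_index("term").loc[mob, "p"])
                out[m] = {"reject": bool(p < alpha), "p": p,
                          "w_hat": fit.w_hat, "w_se": fit.w_se,
                          "boundary": fit.boundary, "failed": not np.isfinite(p)}
            elif m == "conv_groups":
                fit = conventional.fit_mobility_group_model(df, covariates)
                pv = fit.mobility_pvalues()
                holm = bool(multipletests(pv.to_numpy(), alpha=alpha,
                                          method="holm")[0].any())
                out[m] = {"reject": bool((pv < alpha).any()), "holm_reject": holm,
                          "p": float(pv.min()), "failed": len(pv) == 0}
            else:
                fit = conventional.fit_origin_control_model(df, covariates)
                pv = fit.mobility_pvalues()
                out[m] = {"reject": bool((pv < alpha).any()), "p": float(pv.min()),
                          "failed": len(pv) == 0}
        except Exception as exc:  # convergence/degeneracy: not a decision
            out[m] = {"reject": None, "p": np.nan, "failed": True,
                      "error": type(exc).__name__}
    return out


def _run_reps(cfg: StudyConfig, base: simulate.SimulationConfig) -> pd.DataFrame:
    covariates = ("age_c", "native", "marital_status") if cfg.use_covariates else ()
    seeds = simulate.replicate_seeds(cfg.master_seed, cfg.n_reps)
    rows = []
    for rep, ss in enumerate(seeds):
        data, _ = simulate.sample_dataset(base, rng=np.random.default_rng(ss))
        fit_df = data if cfg.use_covariates else aggregate_cells(data)
        res = _fit_one(fit_df, cfg.methods, cfg.alpha, covariates)
        for m, r in res.items():
            rows.append({"rep": rep, "method": m, **r})
    return pd.DataFrame(rows)


def _rates(reps: pd.DataFrame, methods: tuple[str, ...]) -> pd.DataFrame:
    out = []
    for m in methods:
        sub = reps[reps["method"] == m]
        ok = sub[~sub["failed"].astype(bool)]
        n_used = len(ok)
        rate = float(ok["reject"].astype(float).mean()) if n_used else np.nan
        out.append({
            "method": m,
            "rejection_rate": rate,
            "mc_se": float(np.sqrt(rate * (1 - rate) / n_used)) if n_used else np.nan,
            "n_used": n_used,
            "n_failed": int(len(sub) - n_used),
        })
        if m == "conv_groups" and "holm_reject" in ok.columns and n_used:
            hrate = float(ok["holm_reject"].astype(float).mean())
            out.append({
                "method": "conv_groups_holm",
                "rejection_rate": hrate,
                "mc_se": float(np.sqrt(hrate * (1 - hrate) / n_used)),
                "n_used": n_used,
                "n_failed": int(len(sub) - n_used),
            })
    return pd.DataFrame(out)


def run_type1_study(cfg: StudyConfig) -> StudyResult:
    """False-positive mobility-effect rates under a delta = 0 DGP."""
    if cfg.base.delta_down != 0.0 or cfg.base.delta_up != 0.0:
        raise StudyConfigError("type-I study requires delta_down = delta_up = 0")
    reps = _run_reps(cfg, cfg.base)
    return StudyResult(rates=_rates(reps, cfg.methods), replicates=reps,
                       n_reps=cfg.n_reps, alpha=cfg.alpha,
                       master_seed=cfg.master_seed)


def run_power_study(cfg: StudyConfig, deltas: tuple[float, ...],
                    direction: str = "downward",
                    ns: tuple[int, ...] | None = None) -> StudyResult:
    """DRM rejection rate over a grid of mobility effects (and optionally n)."""
    if direction not in ("downward", "upward"):
        raise ValueError("direction must be 'downward' or 'upward'")
    ns = ns or (cfg.base.n,)
    all_reps = []
    rate_rows = []
    for n in ns:
        for delta in deltas:
            kwargs = {"n": int(n)}
            kwargs["delta_down" if direction == "downward" else "delta_up"] = float(delta)
            base = replace(cfg.base, **kwargs)
            sub_cfg = replace(cfg, base=base,
                              master_seed=cfg.master_seed)
            reps = _run_reps(sub_cfg, base)
            reps["delta"] = delta
            reps["n"] = n
            all_reps.append(reps)
            r = _rates(reps, cfg.methods)
            r["delta"] = delta
            r["n"] = n
            rate_rows.append(r)
    return StudyResult(rates=pd.concat(rate_rows, ignore_index=True),
                       replicates=pd.concat(all_reps, ignore_index=True),
                       n_reps=cfg.n_reps, alpha=cfg.alpha,
                       master_seed=cfg.master_seed)


def run_recovery_study(cfg: StudyConfig,
                       w_grid: tuple[float, ...] | None = None) -> StudyResult:
    """Bias, RMSE and CI coverage of w-hat, diagonal odds and delta-hat.

    Requires a DRM method in cfg.methods; sweeps w_true over ``w_grid``
    (default: the base configuration's value only).
    """
    drm_methods = [m for m in cfg.methods if m.startswith("drm")]
    if not drm_methods:
        raise StudyConfigError("recovery study needs a DRM method")
    method = drm_methods[0]
    mob = "downward" if method == "drm_down" else "upward"
    delta_true = cfg.base.delta_down if mob == "downward" else cfg.base.delta_up
    w_grid = w_grid or (cfg.base.w_true,)
    covariates = ("age_c", "native", "marital_status") if cfg.use_covariates else ()

    rep_rows = []
    summaries = []
    for w_true in w_grid:
        base = replace(cfg.base, w_true=float(w_true))
        seeds = simulate.replicate_seeds(cfg.master_seed, cfg.n_reps)
        for rep, ss in enumerate(seeds):
            data, _ = simulate.sample_dataset(base, rng=np.random.default_rng(ss))
            fit_df = data if cfg.use_covariates else aggregate_cells(data)
            try:
                fit = drm.fit_drm(fit_df, drm.DRMSpec(mobility_covariate=mob,
                                                      covariates=covariates))
            except Exception as exc:
                rep_rows.append({"rep": rep, "w_true": w_true, "failed": True,
                                 "error": type(exc).__name__})
                continue
            brow = fit.beta.set_index("term").loc[mob]
            z95 = 1.959963984540054
            d_lo = brow["coef"] - z95 * brow["se"]
            d_hi = brow["coef"] + z95 * brow["se"]
            row = {
                "rep": rep, "w_true": w_true, "failed": False,
                "w_hat": fit.w_hat, "w_se": fit.w_se,
                "w_cover": bool(fit.w_ci[0] <= w_true <= fit.w_ci[1]),
                "delta_hat": float(brow["coef"]), "delta_se": float(brow["se"]),
                "delta_cover": bool(d_lo <= delta_true <= d_hi),
                "boundary": fit.boundary,
            }
            for lvl, odds in zip(fit.levels, fit.diagonal_odds["odds"]):
                row[f"odds_{lvl}"] = float(odds)
            rep_rows.append(row)
        sub = pd.DataFrame([r for r in rep_rows
                            if r["w_true"] == w_true and not r["failed"]])
        if len(sub):
            summary = {
                "w_true": w_true,
                "n_used": len(sub),
                "w_mean": float(sub["w_hat"].mean()),
                "w_bias": float(sub["w_hat"].mean() - w_true),
                "w_rmse": float(np.sqrt(((sub["w_hat"] - w_true) ** 2).mean())),
                "w_coverage": float(sub["w_cover"].mean()),
                "delta_bias": float(sub["delta_hat"].mean() - delta_true),
                "delta_rmse": float(np.sqrt(((sub["delta_hat"] - delta_true) ** 2).mean())),
                "delta_coverage": float(sub["delta_cover"].mean()),
            }
            for lvl, g in zip(("low", "medium", "high"), base.gamma):
                summary[f"odds_{lvl}_mean"] = float(sub[f"odds_{lvl}"].mean())
                summary[f"odds_{lvl}_true"] = float(np.exp(g))
            summaries.append(summary)
        else:
            warnings.warn(f"no successful fits at w_true = {w_true}")
    reps = pd.DataFrame(rep_rows)
    return StudyResult(rates=pd.DataFrame(summaries), replicates=reps,
                       n_reps=cfg.n_reps, alpha=cfg.alpha,
                       master_seed=cfg.master_seed,
                       extra=pd.DataFrame(summaries))
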