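"""Publication-style table rendering and the end-to-end pipeline.

Tables follow the print conventions of the source field: odds and odds
ratios to 2 decimals, confidence intervals as "[low; high]", p-values to 3
decimals with a "<0.001" floor, reference categories shown as "(Ref.)" with
no numeric entries, and — for the DRM layout — no p-value for w, whose Wald
test against zero is meaningless for an interval-constrained weight.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import asdict, dataclass, field, replace
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conventional, data, drm, simulate

logger = logging.getLogger("diagref")

TABLE2_LABELS = {
    "intercept": "Intercept",
    "high-high": "Immobile: high",
    "medium-medium": "Immobile: medium",
    "low-low": "Immobile: low",
    "high-medium": "Downward: high-medium",
    "medium-low": "Downward: medium-low",
    "high-low": "Downward: high-low",
    "medium-high": "Upward: medium-high",
    "low-medium": "Upward: low-medium",
    "low-high": "Upward: low-high",
}
TABLE3_LABELS = {
    "intercept": "Intercept",
    "immobile": "Immobile",
    "downward": "Downwards",
    "upward": "Upwards",
    "origin_low": "Origin: low",
    "origin_medium": "Origin: medium",
    "origin_high": "Origin: high",
}
COVARIATE_LABELS = {
    "age_c": "Age (centred)",
    "native": "Native",
    "married_cohab": "Married cohabitation",
    "unmarried_cohab": "Unmarried cohabitation",
    "no_cohabitation": "No cohabitation",
    "downward": "Downwards mobility",
    "upward": "Upwards mobility",
}


def format_p(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def format_ci(lo: float, hi: float) -> str:
    if not (np.isfinite(lo) and np.isfinite(hi)):
        return ""
    return f"[{lo:.2f}; {hi:.2f}]"


def _row(term: str, or_: float, lo: float, hi: float, p: float,
         ref: bool = False, p_blank: bool = False) -> dict:
    if ref:
        return {"term": term, "OR": "(Ref.)", "CI": "", "p": ""}
    return {"term": term, "OR": f"{or_:.2f}", "CI": format_ci(lo, hi),
            "p": "" if p_blank else format_p(p)}


def render_or_table(fit, layout: str) -> pd.DataFrame:
    """Render a fit as a formatted table in the requested layout.

    layout "table2"/"table3" expect the matching ConventionalFit;
    "table4" expects a DRMFit.
    """
    if layout in ("table2", "table3"):
        if not isinstance(fit, conventional.ConventionalFit):
            raise TypeError(f"layout {layout!r} requires a conventional fit")
        expected = "groups" if layout == "table2" else "origin-control"
        if fit.design != expected:
            raise ValueError(f"layout {layout!r} requires the {expected!r} design")
        labels = TABLE2_LABELS if layout == "table2" else TABLE3_LABELS
        rows = []
        for r in fit.rows:
            label = labels.get(r.term) or COVARIATE_LABELS.get(r.term, r.term)
            rows.append(_row(label, r.odds_ratio, r.ci_low, r.ci_high,
                             r.p_value, ref=r.is_reference))
        return pd.DataFrame(rows)
    if layout == "table4":
        if not isinstance(fit, drm.DRMFit):
            raise TypeError("layout 'table4' requires a DRM fit")
        rows = []
        for i, lvl in enumerate(fit.levels):
            d = fit.diagonal_odds.iloc[i]
            rows.append(_row(f"mu_{i+1}{i+1}: {lvl}", d["odds"], d["ci_low"],
                             d["ci_high"], d["p"]))
        rows.append({"term": "w: weight of origin", "OR": f"{fit.w_hat:.2f}",
                     "CI": format_ci(*fit.w_ci), "p": ""})
        for _, r in fit.beta.iterrows():
            label = COVARIATE_LABELS.get(r["term"], r["term"])
            rows.append(_row(label, r["odds_ratio"], r["ci_low"], r["ci_high"], r["p"]))
        return pd.DataFrame(rows)
    raise ValueError(f"unknown layout {layout!r}")


def table_text(table: pd.DataFrame, title: str = "") -> str:
    widths = {c: max(len(c), *(len(str(v)) for v in table[c])) for c in table.columns}
    lines = [title] if title else []
    lines.append("  ".join(c.ljust(widths[c]) for c in table.columns))
    for _, r in table.iterrows():
        lines.append("  ".join(str(r[c]).ljust(widths[c]) for c in table.columns))
    return "\n".join(lines) + "\n"


_CI_RE = re.compile(r"\[(-?\d+\.?\d*);\s*(-?\d+\.?\d*)\]")


def parse_rendered(table: pd.DataFrame) -> pd.DataFrame:
    """Parse a rendered table back to numeric columns at printed precision."""
    out = []
    for _, r in table.iterrows():
        if r["OR"] == "(Ref.)":
            out.append({"term": r["term"], "OR": np.nan, "ci_low": np.nan,
                        "ci_high": np.nan, "p": np.nan, "is_reference": True})
            continue
        m = _CI_RE.match(r["CI"]) if r["CI"] else None
        p = r["p"]
        pval = 0.001 if p == "<0.001" else (float(p) if p else np.nan)
        out.append({
            "term": r["term"],
            "OR": float(r["OR"]) if r["OR"] != "" else np.nan,
            "ci_low": float(m.group(1)) if m else np.nan,
            "ci_high": float(m.group(2)) if m else np.nan,
            "p": pval,
            "is_reference": False,
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineConfig:
    """Validated configuration for the ingest -> fit -> report pipeline."""

    out_dir: str = "diagref_out"
    input_path: str | None = None       # CSV of records; None -> simulate
    column_map: dict = field(default_factory=dict)
    sexes: tuple[str, ...] = ("male", "female")
    n_per_sex: dict = field(default_factory=dict)  # overrides per sex
    realistic_covariates: bool = True
    min_age: float = 18.0
    exclude_enrolled: bool = True
    covariates: tuple[str, ...] = ("age_c", "native", "marital_status")
    weights_column: str = "weight"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("sexes", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Ingest (or simulate), filter, fit all designs per sex, write tables.

    Produces, per sex: Table-2/Table-3 conventional tables and a Table-4 DRM
    table (downward and upward models stacked), plus JSON fits, a filter
    report, and a comparison summary.  Deterministic given cfg.seed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    logger.addHandler(fh)
    try:
        pkg_version = version("diagref")
    except PackageNotFoundError:
        pkg_version = "unknown"
    logger.info("diagref %s | config %s | seed %d", pkg_version,
                _config_hash(cfg), cfg.seed)

    artifacts: dict[str, Path] = {}
    try:
        if cfg.input_path is not None:
            if not Path(cfg.input_path).exists():
                raise FileNotFoundError(f"input file not found: {cfg.input_path}")
            records = data.read_records(cfg.input_path, cfg.column_map or None)
        else:
            frames = []
            for i, sex in enumerate(cfg.sexes):
                sim = simulate.default_params(
                    sex, n=cfg.n_per_sex.get(sex),
                    seed=cfg.seed + i,
                    realistic_covariates=cfg.realistic_covariates)
                d, truth = simulate.sample_dataset(sim)
                frames.append(d)
                truth_path = out / f"truth_{sex}.json"
                truth_path.write_text(truth.to_json())
                artifacts[f"truth_{sex}"] = truth_path
            records = pd.concat(frames, ignore_index=True)

        records, report = data.apply_eligibility_filters(
            records, min_age=cfg.min_age, exclude_enrolled=cfg.exclude_enrolled)
        (out / "filter_report.json").write_text(report.to_json())
        artifacts["filter_report"] = out / "filter_report.json"
        if "age_c" not in records.columns:
            centred, mean = data.center_covariate(records["age"], records.get("weight"))
            records = records.assign(age_c=centred)
            logger.info("age centred around %.2f", mean)

        summary_lines = []
        for sex in cfg.sexes:
            sub = records[records["sex"] == sex].reset_index(drop=True)
            if len(sub) == 0:
                logger.warning("no records for sex=%s; skipped", sex)
                continue
            table = data.tabulate(sub)
            table.to_csv(out / f"mobility_table_{sex}.csv")
            artifacts[f"mobility_table_{sex}"] = out / f"mobility_table_{sex}.csv"

            groups = conventional.fit_mobility_group_model(
                sub, cfg.covariates, cfg.weights_column)
            origin = conventional.fit_origin_control_model(
                sub, cfg.covariates, cfg.weights_column)
            fits = {}
            for mob in ("downward", "upward"):
                fits[mob] = drm.fit_drm(sub, drm.DRMSpec(
                    mobility_covariate=mob, covariates=cfg.covariates,
                    weights_column=cfg.weights_column))

            for name, layout, fit in (
                ("table2", "table2", groups),
                ("table3", "table3", origin),
            ):
                t = render_or_table(fit, layout)
                path = out / f"{name}_{sex}.csv"
                t.to_csv(path, index=False)
                artifacts[f"{name}_{sex}"] = path
                (out / f"{name}_{sex}.txt").write_text(
                    table_text(t, f"{name} ({sex})"))
            t4 = pd.concat(
                [render_or_table(fits["downward"], "table4").assign(model="downward"),
                 render_or_table(fits["upward"], "table4").assign(model="upward")],
                ignore_index=True)
            path = out / f"table4_{sex}.csv"
            t4.to_csv(path, index=False)
            artifacts[f"table4_{sex}"] = path
            (out / f"table4_{sex}.txt").write_text(table_text(t4, f"table4 ({sex})"))
            (out / f"drm_fit_{sex}.json").write_text(json.dumps(
                {mob: json.loads(f.to_json()) for mob, f in fits.items()}, indent=2))
            artifacts[f"drm_fit_{sex}"] = out / f"drm_fit_{sex}.json"

            conv_min = min(groups.mobility_pvalues().min(),
                           origin.mobility_pvalues().min())
            drm_min = min(
                float(fits["downward"].beta.set_index("term").loc["downward", "p"]),
                float(fits["upward"].beta.set_index("term").loc["upward", "p"]))
            summary_lines.append(
                f"{sex}: smallest conventional mobility p = {format_p(conv_min)}; "
                f"smallest DRM mobility p = {format_p(drm_min)}; "
                f"w (downward model) = {fits['downward'].w_hat:.2f} "
                f"{format_ci(*fits['downward'].w_ci)}")

        summary = out / "summary.txt"
        summary.write_text("\n".join(summary_lines) + "\n")
        artifacts["summary"] = summary
        logger.info("pipeline complete: %d artifacts", len(artifacts))
        return artifacts
    except Exception:
        logger.exception("pipeline failed; partial artifacts retained in %s", out)
        raise
    finally:
        logger.removeHandler(fh)
        fh.close()
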