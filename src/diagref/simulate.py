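"""Synthetic mobility cohorts drawn from a logistic diagonal reference model.

The generator emulates the structure of a national mobility survey of adults
aged 18-45: a 3x3 origin x destination education table with the observed cell
frequencies, covariate marginals matching the published sample description
(age mean 34.95, SD 6.88; 52.6% native; marital shares 19.1/56.4/17.0/7.5%),
and a binary overweight outcome generated from a logistic DRM

    logit P(Y=1) = w * gamma_origin + (1 - w) * gamma_dest
                   + delta_down * 1[down] + delta_up * 1[up] + x'beta

i.e. the weighted origin/destination combination is applied on the log-odds
scale so that the generating model and the fitted model coincide.  Default
diagonal odds and w come from the published fits (males: odds 0.73/0.74/0.41,
w = 0.35; females: 0.98/0.55/0.31, w = 0.32) with mobility effects delta = 0
— the null world in which any detected "mobility effect" is spurious.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .levels import LEVELS, MARITAL_LEVELS, RANK

#: Published 3x3 mobility counts (rows = origin low/medium/high,
#: columns = destination low/medium/high), by sex.
TABLE1_COUNTS: dict[str, np.ndarray] = {
    "male": np.array([[361, 341, 142], [68, 220, 137], [17, 112, 171]]),
    "female": np.array([[347, 414, 126], [68, 324, 172], [18, 103, 199]]),
}

#: Published diagonal odds (low, medium, high) and origin weight w, by sex
#: (downward-mobility model).
TABLE4_DIAGONAL_ODDS = {"male": (0.73, 0.74, 0.41), "female": (0.98, 0.55, 0.31)}
TABLE4_W = {"male": 0.35, "female": 0.32}

#: Covariate odds ratios near the published fits, used by the "realistic"
#: preset (age per year, native, married/unmarried/no-cohabitation vs no partner).
REALISTIC_COVARIATE_ORS = {
    "age": 1.05,
    "native": 0.68,
    "marital": (2.38, 1.42, 1.36),
}


class DegenerateDesignError(ValueError):
    """All probability mass on the diagonal: mobility effects unidentifiable."""


@dataclass
class SimulationConfig:
    """Full data-generating-process parameterization for one synthetic cohort.

    gamma are diagonal intercepts on the log-odds scale (gamma_k = log of the
    diagonal odds mu_kk); w_true in [0,1] is the origin weight; delta_* are
    log-odds-ratios for having moved; beta_* are covariate log-ORs.
    """

    n: int = 1569
    cell_probs: np.ndarray = field(
        default_factory=lambda: TABLE1_COUNTS["male"] / TABLE1_COUNTS["male"].sum()
    )
    gamma: tuple[float, float, float] = tuple(np.log(TABLE4_DIAGONAL_ODDS["male"]))
    w_true: float = TABLE4_W["male"]
    delta_down: float = 0.0
    delta_up: float = 0.0
    beta_age: float = 0.0
    beta_native: float = 0.0
    beta_marital: tuple[float, float, float] = (0.0, 0.0, 0.0)
    age_mean: float = 34.95
    age_sd: float = 6.88
    age_range: tuple[float, float] = (18.0, 45.0)
    p_native: float = 0.526
    marital_probs: tuple[float, ...] = (0.191, 0.564, 0.170, 0.075)
    sex: str = "male"
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_probs = np.asarray(self.cell_probs, dtype=float)
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.cell_probs.shape != (len(LEVELS), len(LEVELS)):
            raise ValueError("cell_probs must be KxK")
        if (self.cell_probs < 0).any() or abs(self.cell_probs.sum() - 1.0) > 1e-12:
            raise ValueError("cell_probs must be non-negative and sum to 1")
        if not 0.0 <= self.w_true <= 1.0:
            raise ValueError("w_true must lie in [0, 1]")
        if abs(sum(self.marital_probs) - 1.0) > 1e-12:
            raise ValueError("marital_probs must sum to 1")


@dataclass(frozen=True)
class DGPTruth:
    """Immutable copy of the generating parameters, attached to each dataset."""

    n: int
    cell_probs: tuple
    gamma: tuple
    w_true: float
    delta_down: float
    delta_up: float
    beta_age: float
    beta_native: float
    beta_marital: tuple
    age_mean: float
    age_sd: float
    p_native: float
    marital_probs: tuple
    sex: str
    seed: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=list, indent=2)


def default_cell_probs(sex: str) -> np.ndarray:
    """Published mobility counts for ``sex`` normalized by the grand total."""
    counts = TABLE1_COUNTS[_check_sex(sex)]
    return counts / counts.sum()


def default_params(sex: str, n: int | None = None, seed: int = 0,
                   realistic_covariates: bool = False) -> SimulationConfig:
    """Study-condition defaults for one sex.

    Diagonal odds and w from the published downward-mobility fits; covariate
    effects are zero unless ``realistic_covariates`` (then set near the
    published covariate ORs); n defaults to the published sample size.
    """
    sex = _check_sex(sex)
    counts = TABLE1_COUNTS[sex]
    cfg = SimulationConfig(
        n=int(counts.sum()) if n is None else int(n),
        cell_probs=counts / counts.sum(),
        gamma=tuple(np.log(TABLE4_DIAGONAL_ODDS[sex])),
        w_true=TABLE4_W[sex],
        sex=sex,
        seed=seed,
    )
    if realistic_covariates:
        cfg = replace(
            cfg,
            beta_age=float(np.log(REALISTIC_COVARIATE_ORS["age"])),
            beta_native=float(np.log(REALISTIC_COVARIATE_ORS["native"])),
            beta_marital=tuple(np.log(REALISTIC_COVARIATE_ORS["marital"])),
        )
    return cfg


def linear_predictor(origin: str, destination: str, config: SimulationConfig,
                     covariates: dict | None = None) -> float:
    """Generating log-odds for one cell (and optional covariate values).

    covariates may carry 'age_c' (centred age), 'native' (0/1) and
    'marital_status' (category label).
    """
    g = dict(zip(LEVELS, config.gamma))
    eta = config.w_true * g[origin] + (1.0 - config.w_true) * g[destination]
    ro, rd = RANK[origin], RANK[destination]
    if rd < ro:
        eta += config.delta_down
    elif rd > ro:
        eta += config.delta_up
    if covariates:
        eta += config.beta_age * covariates.get("age_c", 0.0)
        eta += config.beta_native * covariates.get("native", 0.0)
        ms = covariates.get("marital_status")
        if ms is not None and ms != MARITAL_LEVELS[0]:
            eta += dict(zip(MARITAL_LEVELS[1:], config.beta_marital))[ms]
    return float(eta)


def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter making the [lo, hi]-truncated normal mean hit target."""

    def gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return float(optimize.brentq(gap, lo, hi + 4 * sd, xtol=1e-10))


def sample_dataset(config: SimulationConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, DGPTruth]:
    """Draw one synthetic cohort; fully reproducible from ``config.seed``.

    (origin, destination) ~ cell_probs; age truncated-normal on the age range
    (location calibrated so the truncated mean equals age_mean) then centred;
    native ~ Bernoulli(p_native); marital ~ categorical(marital_probs);
    outcome ~ Bernoulli(logistic(eta)) with eta from the DRM surface.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.cell_probs
    level_mass = p.sum(axis=1) + p.sum(axis=0)
    if (level_mass == 0).any():
        dead = [LEVELS[i] for i in np.flatnonzero(level_mass == 0)]
        warnings.warn(f"levels never sampled under cell_probs: {dead}")
    if np.allclose(p - np.diag(np.diag(p)), 0.0):
        warnings.warn(
            "all probability mass on the diagonal: mobility effects are "
            "unidentifiable in data generated from this configuration"
        )

    n = config.n
    flat = rng.choice(p.size, size=n, p=p.ravel())
    oi, dj = np.divmod(flat, len(LEVELS))

    lo, hi = config.age_range
    loc = _truncnorm_loc(config.age_mean, config.age_sd, lo, hi)
    a, b = (lo - loc) / config.age_sd, (hi - loc) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=loc, scale=config.age_sd, size=n,
                              random_state=rng)
    age_c = age - config.age_mean

    native = (rng.random(n) < config.p_native).astype(int)
    marital_idx = rng.choice(len(MARITAL_LEVELS), size=n, p=np.asarray(config.marital_probs))

    gamma = np.asarray(config.gamma)
    eta = config.w_true * gamma[oi] + (1.0 - config.w_true) * gamma[dj]
    eta = eta + np.where(dj < oi, config.delta_down, 0.0)
    eta = eta + np.where(dj > oi, config.delta_up, 0.0)
    eta = eta + config.beta_age * age_c + config.beta_native * native
    bm = np.asarray(config.beta_marital)
    eta = eta + np.where(marital_idx > 0, bm[np.clip(marital_idx - 1, 0, 2)], 0.0)

    outcome = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    levels = np.asarray(LEVELS)
    marital = np.asarray(MARITAL_LEVELS)
    df = pd.DataFrame(
        {
            "origin": levels[oi],
            "destination": levels[dj],
            "outcome": outcome,
            "age": age,
            "age_c": age_c,
            "native": native,
            "marital_status": marital[marital_idx],
            "weight": 1.0,
            "enrolled": 0,
            "sex": config.sex,
        }
    )
    truth = DGPTruth(
        n=n,
        cell_probs=tuple(map(tuple, p)),
        gamma=tuple(config.gamma),
        w_true=config.w_true,
        delta_down=config.delta_down,
        delta_up=config.delta_up,
        beta_age=config.beta_age,
        beta_native=config.beta_native,
        beta_marital=tuple(config.beta_marital),
        age_mean=config.age_mean,
        age_sd=config.age_sd,
        p_native=config.p_native,
        marital_probs=tuple(config.marital_probs),
        sex=config.sex,
        seed=config.seed,
    )
    return df, truth


def table1_records(sex: str) -> pd.DataFrame:
    """Record set whose origin x destination tabulation is the published table.

    Outcomes/covariates are placeholders; this fixture exists to reproduce
    cell counts and margins exactly.
    """
    counts = TABLE1_COUNTS[_check_sex(sex)]
    rows = []
    for i, o in enumerate(LEVELS):
        for j, d in enumerate(LEVELS):
            rows.extend([(o, d)] * int(counts[i, j]))
    df = pd.DataFrame(rows, columns=["origin", "destination"])
    df["outcome"] = 0
    df["sex"] = sex
    return df


def replicate_seeds(master_seed: int, n_reps: int) -> list[np.random.SeedSequence]:
    """Independent, individually reproducible per-replicate substreams."""
    return np.random.SeedSequence(master_seed).spawn(n_reps)


def _check_sex(sex: str) -> str:
    if sex not in TABLE1_COUNTS:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    return sex
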