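"""The synthetic-cohort generator: defaults, determinism, DRM surface."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import diagref as dg
from diagref.levels import LEVELS, MARITAL_LEVELS
from diagref.simulate import SimulationConfig


class TestDefaults:
    @pytest.mark.parametrize(
        "sex, cell, expected",
        [("male", ("low", "low"), 361 / 1569),
         ("female", ("high", "high"), 199 / 1771)],
    )
    def test_cell_probs_are_normalized_published_counts(self, sex, cell, expected):
        probs = dg.default_cell_probs(sex)
        i, j = LEVELS.index(cell[0]), LEVELS.index(cell[1])
        assert probs[i, j] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("sex", ["male", "female"])
    def test_cell_probs_sum_to_one(self, sex):
        assert dg.default_cell_probs(sex).sum() == pytest.approx(1.0, abs=1e-12)

    def test_male_defaults(self):
        cfg = dg.default_params("male")
        assert cfg.n == 1569
        np.testing.assert_allclose(cfg.gamma, np.log([0.73, 0.74, 0.41]))
        assert cfg.w_true == 0.35
        assert cfg.delta_down == cfg.delta_up == 0.0
        assert (cfg.age_mean, cfg.age_sd) == (34.95, 6.88)
        assert cfg.p_native == 0.526
        assert cfg.marital_probs == (0.191, 0.564, 0.170, 0.075)

    def test_female_defaults(self):
        cfg = dg.default_params("female")
        assert cfg.n == 1771
        np.testing.assert_allclose(cfg.gamma, np.log([0.98, 0.55, 0.31]))
        assert cfg.w_true == 0.32

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n=0)
        with pytest.raises(ValueError):
            SimulationConfig(w_true=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(marital_probs=(0.5, 0.5, 0.5, 0.5))


class TestLinearPredictor:
    def test_diagonal_identity_for_any_w(self):
        for w in (0.0, 0.3, 1.0):
            cfg = dg.default_params("male")
            cfg = dg.SimulationConfig(**{**cfg.__dict__, "w_true": w})
            for k, lvl in enumerate(LEVELS):
                assert dg.linear_predictor(lvl, lvl, cfg) == pytest.approx(cfg.gamma[k])

    def test_w_one_origin_only(self):
        cfg = dg.default_params("male")
        cfg = dg.SimulationConfig(**{**cfg.__dict__, "w_true": 1.0})
        assert dg.linear_predictor("low", "high", cfg) == pytest.approx(cfg.gamma[0])

    def test_mixing_at_w_07(self):
        cfg = dg.default_params("male")
        cfg = dg.SimulationConfig(**{**cfg.__dict__, "w_true": 0.7})
        eta = dg.linear_predictor("high", "low", cfg)
        assert eta == pytest.approx(0.7 * cfg.gamma[2] + 0.3 * cfg.gamma[0])

    def test_covariate_contributions(self):
        cfg = dg.default_params("male", realistic_covariates=True)
        base = dg.linear_predictor("low", "low", cfg)
        eta = dg.linear_predictor(
            "low", "low", cfg,
            {"age_c": 2.0, "native": 1, "marital_status": "married_cohab"})
        expected = base + 2 * cfg.beta_age + cfg.beta_native + cfg.beta_marital[0]
        assert eta == pytest.approx(expected)


class TestSampling:
    def test_same_seed_identical_datasets(self):
        cfg = dg.default_params("male", n=500, seed=42)
        d1, _ = dg.sample_dataset(cfg)
        d2, _ = dg.sample_dataset(cfg)
        pd.testing.assert_frame_equal(d1, d2)

    def test_immobile_high_rate_matches_closed_form(self, big_sample):
        # odds 0.41 -> P = 0.41 / 1.41
        df, _ = big_sample
        cell = df[(df.origin == "high") & (df.destination == "high")]
        p = 0.41 / 1.41
        se = np.sqrt(p * (1 - p) / len(cell))
        assert abs(cell.outcome.mean() - p) < 3 * se

    def test_cell_frequencies_match_cell_probs(self, big_sample):
        df, truth = big_sample
        counts = dg.tabulate(df).counts.to_numpy().ravel()
        expected = np.asarray(truth.cell_probs).ravel() * len(df)
        assert stats.chisquare(counts, expected).pvalue > 0.001

    def test_covariate_marginals(self, big_sample):
        df, truth = big_sample
        n = len(df)
        assert abs(df.native.mean() - truth.p_native) < \
            3 * np.sqrt(truth.p_native * (1 - truth.p_native) / n)
        for lvl, p in zip(MARITAL_LEVELS, truth.marital_probs):
            assert abs((df.marital_status == lvl).mean() - p) < \
                4 * np.sqrt(p * (1 - p) / n)
        assert df.age.between(18, 45).all()

    def test_drm_surface_recovered_cellwise(self, big_sample):
        """Empirical log-odds in every cell approach the generating surface."""
        df, truth = big_sample
        cfg = dg.default_params("male", n=len(df))
        worst = 0.0
        for o in LEVELS:
            for d in LEVELS:
                cell = df[(df.origin == o) & (df.destination == d)]
                emp = np.log(cell.outcome.mean() / (1 - cell.outcome.mean()))
                worst = max(worst, abs(emp - dg.linear_predictor(o, d, cfg)))
        assert worst < 0.05

    def test_homogeneous_model_rate(self):
        g = float(np.log(0.6))
        cfg = SimulationConfig(n=50_000, gamma=(g, g, g), w_true=0.5, seed=5)
        df, _ = dg.sample_dataset(cfg)
        p = expit(g)
        assert abs(df.outcome.mean() - p) < 3 * np.sqrt(p * (1 - p) / len(df))

    def test_all_diagonal_mass_warns(self):
        cfg = SimulationConfig(n=100, cell_probs=np.diag([0.5, 0.3, 0.2]), seed=1)
        with pytest.warns(UserWarning, match="diagonal"):
            dg.sample_dataset(cfg)

    def test_replicate_substreams_differ(self):
        seeds = dg.simulate.replicate_seeds(7, 3)
        cfg = dg.default_params("male", n=200)
        frames = [dg.sample_dataset(cfg, rng=np.random.default_rng(s))[0]
                  for s in seeds]
        assert not frames[0].equals(frames[1])
        # and are reproducible individually
        again = dg.sample_dataset(
            cfg, rng=np.random.default_rng(dg.simulate.replicate_seeds(7, 3)[1]))[0]
        pd.testing.assert_frame_equal(frames[1], again)
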