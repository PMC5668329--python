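"""The diagonal reference model fitter: design, profile, recovery, inference."""

import numpy as np
import pandas as pd
import pytest

import diagref as dg
from diagref.drm import (
    AllDiagonalError,
    BoundaryFitError,
    DRMSpec,
    UnidentifiableLevelError,
    build_conditional_design,
    interpolate_odds,
    predict_cell,
    profile_loglik,
)
from diagref.drm import test_w_against as w_wald_test
from conftest import make_cell_records


def _toy(origin, destination):
    """One record of interest (row 0) plus immobile rows covering all levels."""
    rows = [(origin, destination)] + [(lvl, lvl) for lvl in dg.LEVELS]
    df = pd.DataFrame(rows, columns=["origin", "destination"])
    df["outcome"] = 0
    df["weight"] = 1.0
    return df


class TestConditionalDesign:
    def test_immobile_column_is_one_for_any_w(self):
        for w in (0.0, 0.35, 1.0):
            X, *_ = build_conditional_design(_toy("medium", "medium"), DRMSpec(), w)
            np.testing.assert_allclose(X[0, :3], [0, 1, 0])

    def test_w_one_origin_only(self):
        X, *_ = build_conditional_design(_toy("low", "high"), DRMSpec(), 1.0)
        np.testing.assert_allclose(X[0, :3], [1, 0, 0])

    def test_midpoint(self):
        X, *_ = build_conditional_design(_toy("low", "high"), DRMSpec(), 0.5)
        np.testing.assert_allclose(X[0, :3], [0.5, 0, 0.5])

    def test_no_intercept_column(self, dataset_2k):
        df, _ = dataset_2k
        X, _, _, names = build_conditional_design(df, DRMSpec(), 0.35)
        assert "intercept" not in names
        assert X.shape[1] == 3 + 1  # gammas + downward indicator
        # diagonal columns sum to 1 row-wise: they absorb the intercept
        np.testing.assert_allclose(X[:, :3].sum(axis=1), 1.0)

    def test_absent_level_unidentifiable(self):
        df = pd.DataFrame({"origin": ["low", "low"], "destination": ["low", "medium"],
                           "outcome": [0, 1], "weight": [1.0, 1.0]})
        with pytest.raises(UnidentifiableLevelError, match="high"):
            build_conditional_design(df, DRMSpec(), 0.5)


class TestProfile:
    def test_loglik_nonpositive(self, dataset_2k):
        df, _ = dataset_2k
        for w in (0.0, 0.5, 1.0):
            assert profile_loglik(w, df).loglik <= 0

    def test_relabelling_symmetry_of_profile(self, dataset_2k):
        df, _ = dataset_2k
        swapped = df.rename(columns={"origin": "destination",
                                     "destination": "origin"})
        spec = DRMSpec(mobility_covariate="none")
        for w in (0.1, 0.35, 0.8):
            a = profile_loglik(w, df, spec).loglik
            b = profile_loglik(1 - w, swapped, spec).loglik
            assert a == pytest.approx(b, abs=1e-9)

    def test_w_true_one_profile_prefers_one(self):
        cfg = dg.default_params("male", n=50_000, seed=88)
        cfg = dg.SimulationConfig(**{**cfg.__dict__, "w_true": 1.0})
        df, _ = dg.sample_dataset(cfg)
        agg = dg.aggregate_cells(df)
        assert profile_loglik(1.0, agg).loglik >= profile_loglik(0.0, agg).loglik


class TestFit:
    def test_parameter_recovery_male_defaults(self):
        """Mean over 5 replicates at n = 50000 (SE ~ 0.02) recovers w = 0.35."""
        cfg = dg.default_params("male", n=50_000)
        w_hats, odds = [], []
        for ss in dg.simulate.replicate_seeds(31, 5):
            df, _ = dg.sample_dataset(cfg, rng=np.random.default_rng(ss))
            fit = dg.fit_drm(dg.aggregate_cells(df))
            assert fit.converged and not fit.boundary
            w_hats.append(fit.w_hat)
            odds.append(fit.diagonal_odds["odds"].to_numpy())
        assert np.mean(w_hats) == pytest.approx(0.35, abs=0.05)
        for mean_odds, truth in zip(np.mean(odds, axis=0), (0.73, 0.74, 0.41)):
            assert mean_odds == pytest.approx(truth, rel=0.10)

    def test_boundary_recovery_w_equal_one(self):
        cfg = dg.default_params("male", n=50_000, seed=88)
        cfg = dg.SimulationConfig(**{**cfg.__dict__, "w_true": 1.0})
        df, _ = dg.sample_dataset(cfg)
        fit = dg.fit_drm(dg.aggregate_cells(df))
        assert fit.w_hat > 0.9

    def test_flat_profile_balanced_cells(self):
        cells = {(o, d): (10, 10) for o in dg.LEVELS for d in dg.LEVELS}
        df = make_cell_records(cells)
        fit = dg.fit_drm(df)
        assert fit.flat_profile
        np.testing.assert_allclose(fit.gamma, 0.0, atol=1e-6)
        assert fit.loglik == pytest.approx(len(df) * np.log(0.5), abs=1e-8)
        assert fit.w_hat == pytest.approx(0.5, abs=1e-9)  # midpoint tie-break

    def test_all_diagonal_records_rejected(self):
        cells = {(lvl, lvl): (5, 5) for lvl in dg.LEVELS}
        with pytest.raises(AllDiagonalError):
            dg.fit_drm(make_cell_records(cells))

    def test_relabelling_symmetry_of_w_hat(self, dataset_2k):
        df, _ = dataset_2k
        agg = dg.aggregate_cells(df)
        swapped = agg.rename(columns={"origin": "destination",
                                      "destination": "origin"})
        f1 = dg.fit_drm(agg, DRMSpec(mobility_covariate="downward"))
        f2 = dg.fit_drm(swapped, DRMSpec(mobility_covariate="upward"))
        assert f1.w_hat == pytest.approx(1 - f2.w_hat, abs=1e-6)
        np.testing.assert_allclose(np.sort(f1.gamma), np.sort(f2.gamma), atol=1e-6)

    def test_profile_optimum_dominates_grid(self, dataset_2k):
        df, _ = dataset_2k
        fit = dg.fit_drm(dg.aggregate_cells(df))
        grid_lls = [p.loglik for p in fit.profile]
        assert fit.loglik + 1e-9 >= max(grid_lls)

    def test_vcov_symmetric_psd(self, dataset_2k):
        df, _ = dataset_2k
        fit = dg.fit_drm(dg.aggregate_cells(df))
        V = fit.vcov.to_numpy()
        np.testing.assert_allclose(V, V.T, atol=1e-10)
        assert np.linalg.eigvalsh(V).min() > -1e-10

    def test_diagonal_odds_roundtrip_gamma(self, dataset_2k):
        df, _ = dataset_2k
        fit = dg.fit_drm(dg.aggregate_cells(df))
        np.testing.assert_allclose(np.log(fit.diagonal_odds["odds"]), fit.gamma)

    def test_fit_with_covariates_and_weights(self, dataset_2k_cov):
        df, truth = dataset_2k_cov
        spec = DRMSpec(covariates=("age_c", "native", "marital_status"))
        fit = dg.fit_drm(df, spec)
        assert fit.converged
        assert set(fit.beta["term"]) == {"downward", "age_c", "native",
                                         "married_cohab", "unmarried_cohab",
                                         "no_cohabitation"}
        # age effect recovered within 3 SE
        row = fit.beta.set_index("term").loc["age_c"]
        assert abs(row["coef"] - truth.beta_age) < 3 * row["se"]


class TestPostFit:
    def test_diagonal_prediction_is_w_free(self, dataset_2k):
        df, _ = dataset_2k
        fit = dg.fit_drm(dg.aggregate_cells(df))
        for k, lvl in enumerate(fit.levels):
            pred = predict_cell(fit, lvl, lvl)
            assert pred["odds"] == pytest.approx(
                fit.diagonal_odds["odds"].iloc[k], abs=1e-12)
            assert pred["eta"] == pytest.approx(fit.gamma[k], abs=1e-12)

    def test_mixing_prediction(self, dataset_2k):
        df, _ = dataset_2k
        fit = dg.fit_drm(dg.aggregate_cells(df), DRMSpec(mobility_covariate="none"))
        pred = predict_cell(fit, "high", "low")
        expected = fit.w_hat * fit.gamma[2] + (1 - fit.w_hat) * fit.gamma[0]
        assert pred["eta"] == pytest.approx(expected, abs=1e-12)

    def test_w_zero_prediction_depends_on_destination_only(self):
        cfg = dg.default_params("male", n=50_000, seed=12)
        cfg = dg.SimulationConfig(**{**cfg.__dict__, "w_true": 0.0})
        df, _ = dg.sample_dataset(cfg)
        fit = dg.fit_drm(dg.aggregate_cells(df), DRMSpec(mobility_covariate="none"))
        assert fit.w_hat < 0.1
        if fit.w_hat == 0.0:
            a = predict_cell(fit, "low", "high")["eta"]
            b = predict_cell(fit, "medium", "high")["eta"]
            assert a == pytest.approx(b, abs=1e-12)

    def test_w_test_arithmetic(self, dataset_2k):
        df, _ = dataset_2k
        fit = dg.fit_drm(dg.aggregate_cells(df))
        res = w_wald_test(fit, null_value=fit.w_hat)
        assert res["z"] == 0 and res["p"] == pytest.approx(1.0)
        # stated-input arithmetic: w = 0.35, SE = 0.24 vs null 0.5
        z = (0.35 - 0.5) / 0.24
        assert z == pytest.approx(-0.625)
        from scipy.stats import norm
        assert 2 * norm.sf(abs(z)) == pytest.approx(0.53, abs=0.01)

    def test_w_test_refused_for_flat_fit(self):
        cells = {(o, d): (10, 10) for o in dg.LEVELS for d in dg.LEVELS}
        fit = dg.fit_drm(make_cell_records(cells))
        with pytest.raises(BoundaryFitError):
            w_wald_test(fit)

    def test_odds_scale_interpolation_helper(self):
        # expository arithmetic on published male odds
        assert interpolate_odds(0.41, 0.73, 0.35) == pytest.approx(0.618)
        # link-scale combination disagrees (documented discrepancy)
        link = np.exp(0.35 * np.log(0.41) + 0.65 * np.log(0.73))
        assert link == pytest.approx(0.597, abs=0.001)
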