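"""Two-part GAM behaviour, Moran's I and the PFOS-exclusion sensitivity path."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pfaspest.inference import (
    MoranResult,
    TwoPartFitError,
    TwoPartGAM,
    fit_gaussian_part,
    fit_logistic_part,
    morans_i,
    sensitivity_excl_pfos,
    split_two_part,
)


def synthetic_systems(n=600, seed=0, beta_latinx=np.log(1.4),
                      logit_beta=np.log(1.5), sigma=1.0, zero_frac=0.5):
    """Direct system-level two-part draws (no geometry) for estimator tests."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "pct_latinx": np.clip(rng.normal(36, 15, n), 0, 95),
        "pct_nl_poc": np.clip(rng.normal(24, 8, n), 0, 60),
        "pct_poverty": np.clip(rng.normal(27, 8, n), 0, 70),
        "pct_rented": np.clip(rng.normal(31, 9, n), 0, 80),
        "pop_density": rng.lognormal(-2.5, 1.0, n),
        "centroid_lat": rng.uniform(33, 41, n),
        "centroid_lon": rng.uniform(-124, -115, n),
        "n_wells": rng.poisson(2, n) + 1,
    })
    lat10 = (X["pct_latinx"] - X["pct_latinx"].mean()) / 10
    eta = logit_beta * lat10 + np.log(1.07) * (X["n_wells"] - X["n_wells"].mean())
    from scipy.optimize import brentq
    a0 = brentq(lambda a: (1 / (1 + np.exp(-(a + eta)))).mean() - (1 - zero_frac),
                -30, 30)
    any_ = rng.random(n) < 1 / (1 + np.exp(-(a0 + eta)))
    mu = 0.3 + beta_latinx * lat10 + rng.normal(0, sigma, n)
    dens = np.where(any_, np.exp(mu), 0.0)
    X["density_mg_per_km2"] = dens
    X["density_PFBS_mg_km2"] = dens * 1e-4
    X["density_PFBA_mg_km2"] = dens * 3e-5
    X["any_pfas"] = dens > 0
    return X


class TestSplit:
    def test_partition_properties(self):
        X = synthetic_systems(200)
        pos, full = split_two_part(X)
        assert len(pos) + (~full["any_pfas"]).sum() == len(full)
        assert (pos["density_mg_per_km2"] > 0).all()
        assert set(pos.index) <= set(full.index)

    def test_all_zero_input(self):
        X = synthetic_systems(100)
        X["density_mg_per_km2"] = 0.0
        pos, full = split_two_part(X)
        assert pos.empty and not full["any_pfas"].any()


class TestMoransI:
    def test_null_expectation_and_dual_method_agreement(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 100, (300, 2))
        res = morans_i(rng.standard_normal(300), coords, seed=1)
        assert res.expected == pytest.approx(-1 / 299)
        assert abs(res.p_permutation - res.p_analytic) < 0.05
        assert res.applicable

    def test_smooth_gradient_strongly_positive(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 100, (500, 2))
        gradient = coords[:, 0] / 50.0 + coords[:, 1] / 50.0
        res = morans_i(gradient, coords, seed=2)
        assert res.statistic > 0
        assert res.p_permutation <= 0.001

    def test_constant_residuals_not_applicable(self):
        coords = np.random.default_rng(3).uniform(0, 10, (50, 2))
        res = morans_i(np.ones(50), coords, seed=3)
        assert not res.applicable and np.isnan(res.statistic)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError, match=">= 10"):
            morans_i(np.arange(5.0), np.random.default_rng(0).uniform(0, 1, (5, 2)))


class TestTwoPartGAM:
    def test_estimates_recover_generating_betas(self):
        X = synthetic_systems(n=1500, seed=4)
        est = TwoPartGAM(compute_morans=False, random_state=4).fit(X)
        s = est.summary_.set_index(["part", "term"])
        assert s.loc[("gaussian", "pct_latinx"), "ratio"] == pytest.approx(1.4, abs=0.15)
        assert s.loc[("logistic", "pct_latinx"), "ratio"] == pytest.approx(1.5, abs=0.2)
        assert est.n_positive_ + est.n_zero_ == len(X)
        # CI bounds bracket the estimate
        assert (est.summary_["ratio_ci_low"] <= est.summary_["ratio"]).all()
        assert (est.summary_["ratio"] <= est.summary_["ratio_ci_high"]).all()

    def test_row_permutation_invariance(self):
        X = synthetic_systems(400, seed=5)
        est1 = TwoPartGAM(compute_morans=False).fit(X)
        perm = X.sample(frac=1.0, random_state=7)
        est2 = TwoPartGAM(compute_morans=False).fit(perm)
        a = est1.summary_.set_index(["part", "term"])["estimate"]
        b = est2.summary_.set_index(["part", "term"])["estimate"]
        assert np.allclose(a, b.reindex(a.index), atol=1e-8)

    def test_heavy_penalty_converges_to_linear_model(self):
        """Splines penalized to near-zero wiggliness reduce to straight lines."""
        X = synthetic_systems(300, seed=6)
        pos = X[X["any_pfas"]]
        est = TwoPartGAM(compute_morans=False, alpha=1e10)
        part = fit_gaussian_part(pos, alpha=1e10, compute_morans=False)
        ols = sm.OLS(
            np.log(pos["density_mg_per_km2"]),
            sm.add_constant(pd.DataFrame({
                "pct_latinx": pos["pct_latinx"] / 10,
                "pct_nl_poc": pos["pct_nl_poc"] / 10,
                "pct_poverty": pos["pct_poverty"] / 10,
                "pct_rented": pos["pct_rented"] / 10,
                "pop_density": pos["pop_density"],
                "centroid_lat": pos["centroid_lat"],
                "centroid_lon": pos["centroid_lon"],
            }))).fit()
        got = part.summary.set_index("term")["estimate"]
        assert got["pct_latinx"] == pytest.approx(ols.params["pct_latinx"], abs=0.02)
        assert got["pct_rented"] == pytest.approx(ols.params["pct_rented"], abs=0.02)

    def test_null_effect_gives_unit_ratio(self):
        rng = np.random.default_rng(8)
        X = synthetic_systems(1200, seed=8, beta_latinx=0.0, logit_beta=0.0)
        est = TwoPartGAM(compute_morans=False).fit(X)
        s = est.summary_.set_index(["part", "term"])
        assert s.loc[("gaussian", "pct_latinx"), "ratio"] == pytest.approx(1.0, abs=0.12)
        assert s.loc[("logistic", "pct_latinx"), "ratio"] == pytest.approx(1.0, abs=0.12)

    def test_odds_shift_matches_link_closed_form(self):
        X = synthetic_systems(500, seed=9)
        est = TwoPartGAM(compute_morans=False).fit(X)
        beta = est.result_.logistic.summary.set_index("term").loc["n_wells", "estimate"]
        X1 = X.iloc[:10]
        X2 = X1.copy()
        X2["n_wells"] = X1["n_wells"] * 2
        p1, p2 = est.predict_proba(X1), est.predict_proba(X2)
        shift = (p2 / (1 - p2)) / (p1 / (1 - p1))
        assert np.allclose(shift, np.exp(beta * X1["n_wells"]), rtol=1e-9)

    def test_rank_deficiency_names_collinear_terms(self):
        X = synthetic_systems(200, seed=10)
        X["pct_nl_poc"] = X["pct_latinx"]
        with pytest.raises(TwoPartFitError, match="pct_latinx.*pct_nl_poc|pct_nl_poc.*pct_latinx"):
            TwoPartGAM(compute_morans=False).fit(X)

    def test_complete_separation_raises(self):
        X = synthetic_systems(400, seed=11)
        X["density_mg_per_km2"] = np.where(X["pct_latinx"] > 40,
                                           np.exp(np.random.default_rng(0).normal(size=400)), 0.0)
        with pytest.raises(TwoPartFitError, match="separation"):
            TwoPartGAM(compute_morans=False).fit(X)

    def test_too_few_positives_skips_gaussian_with_diagnostic(self):
        X = synthetic_systems(200, seed=12)
        dens = X["density_mg_per_km2"].to_numpy().copy()
        keep = np.flatnonzero(dens > 0)[:10]
        mask = np.zeros(len(dens), dtype=bool)
        mask[keep] = True
        X["density_mg_per_km2"] = np.where(mask, dens, 0.0)
        est = TwoPartGAM(compute_morans=False).fit(X)
        assert est.result_.gaussian is None
        assert "positive" in est.result_.skipped["gaussian"]

    def test_fit_part_helpers_validate_inputs(self):
        X = synthetic_systems(100, seed=13)
        with pytest.raises(ValueError, match="positive"):
            fit_gaussian_part(X)  # zeros present
        X0 = X.copy()
        X0["any_pfas"] = True
        with pytest.raises(ValueError, match="single class"):
            fit_logistic_part(X0)

    def test_sklearn_params_round_trip(self):
        est = TwoPartGAM(alpha=2.0, morans_k=5)
        params = est.get_params()
        est2 = TwoPartGAM(**params)
        assert est2.get_params() == params
        est2.set_params(alpha=3.0)
        assert est2.alpha == 3.0


class TestSensitivity:
    def test_proportional_analytes_consistent_with_main(self):
        X = synthetic_systems(900, seed=14)
        est = TwoPartGAM(compute_morans=False, random_state=14).fit(X)
        sens = sensitivity_excl_pfos(X, estimator=est)
        # analyte split is proportional, so the zero pattern and coefficients
        # coincide and only the intercept (not reported) shifts
        assert sens.n_positive == est.n_positive_
        g_main = est.summary_.set_index(["part", "term"]).loc[("gaussian", "pct_latinx")]
        g_sens = sens.summary.set_index(["part", "term"]).loc[("gaussian", "pct_latinx")]
        assert g_sens["estimate"] == pytest.approx(g_main["estimate"], abs=1e-6)

    def test_all_pfos_landscape_skips_with_diagnostic(self):
        X = synthetic_systems(200, seed=15)
        X["density_PFBS_mg_km2"] = 0.0
        X["density_PFBA_mg_km2"] = 0.0
        sens = sensitivity_excl_pfos(X)
        assert sens.gaussian is None and sens.logistic is None
        assert "identically zero" in sens.skipped["sensitivity"]
        assert sens.n_positive == 0

    def test_sensitivity_positives_never_exceed_main(self):
        X = synthetic_systems(500, seed=16)
        # knock PFBS/PFBA out of half the positive systems
        rng = np.random.default_rng(16)
        knock = rng.random(len(X)) < 0.5
        X.loc[knock, ["density_PFBS_mg_km2", "density_PFBA_mg_km2"]] = 0.0
        est = TwoPartGAM(compute_morans=False).fit(X)
        sens = sensitivity_excl_pfos(X, estimator=est)
        assert sens.n_positive <= est.n_positive_
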