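"""Design construction, bivariate normal CDF, MLE and inference machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.stats import multivariate_normal

import mwtprisk as m
from mwtprisk.estimation import risk_bin_indicators


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

class TestBuildDesign:
    def test_two_point_delta_centers_to_plus_minus_03(self):
        rec = pd.DataFrame({
            "delta_p": [0.1, 0.7] * 10, "delta_k": [0.2, 0.8] * 10,
            "price": [10.0, 20.0, 40.0, 80.0, 160.0] * 4,
            "r_p": 30.0, "r_k": 20.0,
            "buy_p": [0, 1] * 10, "buy_k": [0, 1] * 10,
        })
        xp, xk = m.build_design(rec, "base")
        assert set(np.round(xp["delta"], 12)) == {-0.3, 0.3}
        assert set(np.round(xk["delta"], 12)) == {-0.3, 0.3}

    def test_price_centering_on_uniform_levels(self):
        rec = pd.DataFrame({
            "delta_p": 0.1, "delta_k": 0.2,
            "price": [10.0, 20.0, 40.0, 80.0, 160.0] * 3,
            "r_p": 30.0, "r_k": 20.0, "buy_p": 0, "buy_k": 0,
        }, index=range(15))
        rec.loc[0, "delta_p"] = 0.7  # keep delta non-constant
        rec.loc[0, "delta_k"] = 0.8
        xp, _ = m.build_design(rec, "base")
        assert set(np.round(xp["q"], 10)) == {-52.0, -42.0, -22.0, 18.0, 98.0}

    def test_all_columns_mean_zero(self, records_2211):
        for spec in ("base", "absolute", "risk_bins", "absolute_risk_bins",
                     "piecewise", "income", "children"):
            xp, xk = m.build_design(records_2211, spec)
            for x in (xp, xk):
                nonconst = x.drop(columns="const")
                assert np.abs(nonconst.mean().to_numpy()).max() < 1e-10

    def test_child_risk_14_falls_in_lowest_bin(self):
        inds = risk_bin_indicators(np.array([14.0]), m.estimation.CHILD_RISK_BIN_EDGES)
        assert inds["lowest"][0] == 1.0
        assert inds["low"][0] == 0.0
        # parent cut: 20 still lowest, 21 is "low"
        pinds = risk_bin_indicators(np.array([20.0, 21.0]),
                                    m.estimation.PARENT_RISK_BIN_EDGES)
        assert pinds["lowest"].tolist() == [1.0, 0.0]
        assert pinds["low"].tolist() == [0.0, 1.0]

    def test_empty_bin_raises_with_bin_name(self):
        rec = pd.DataFrame({
            "delta_p": [0.1, 0.7] * 10, "delta_k": [0.2, 0.8] * 10,
            "price": [10.0, 160.0] * 10,
            "r_p": 90.0, "r_k": 90.0,  # everything in the highest bin
            "buy_p": [0, 1] * 10, "buy_k": [1, 0] * 10,
        })
        with pytest.raises(ValueError, match="lowest"):
            m.build_design(rec, "risk_bins")


# ---------------------------------------------------------------------------
# Bivariate normal CDF
# ---------------------------------------------------------------------------

class TestPhi2:
    def test_closed_forms(self):
        assert m.phi2(0.0, 0.0, 0.0) == pytest.approx(0.25, abs=1e-10)
        for rho in (-0.9, -0.3, 0.5, 0.8912):
            closed = 0.25 + np.arcsin(rho) / (2 * np.pi)
            assert m.phi2(0.0, 0.0, rho) == pytest.approx(closed, abs=1e-7)

    def test_marginalization_at_large_bound(self):
        for a in (-1.3, 0.4, 2.0):
            assert m.phi2(a, 8.0, 0.6) == pytest.approx(stats.norm.cdf(a), abs=1e-7)
            assert m.phi2(8.0, a, -0.6) == pytest.approx(stats.norm.cdf(a), abs=1e-7)

    def test_rejects_degenerate_correlation(self):
        with pytest.raises(ValueError):
            m.phi2(0.0, 0.0, 1.0)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        a=st.floats(-5, 5), b=st.floats(-5, 5),
        rho=st.floats(-0.99, 0.99),
    )
    def test_matches_scipy_orthant_oracle(self, a, b, rho):
        """Independent oracle: scipy's multivariate normal CDF."""
        ref = multivariate_normal.cdf([a, b], mean=[0, 0],
                                      cov=[[1, rho], [rho, 1]])
        assert m.phi2(a, b, rho) == pytest.approx(ref, abs=1e-7)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=st.floats(-4, 4), b=st.floats(-4, 4), rho=st.floats(-0.95, 0.95))
    def test_frechet_bounds(self, a, b, rho):
        p = float(m.phi2(a, b, rho))
        fa, fb = stats.norm.cdf(a), stats.norm.cdf(b)
        assert max(0.0, fa + fb - 1.0) - 1e-12 <= p <= min(fa, fb) + 1e-12


# ---------------------------------------------------------------------------
# MLE
# ---------------------------------------------------------------------------

class TestFitBivariateProbit:
    def test_rho_zero_data_matches_univariate_probit_oracle(self):
        """At rho ~ 0 the joint MLE coincides with two independent probits
        (statsmodels as the independent oracle)."""
        sm = pytest.importorskip("statsmodels.api")
        params = m.default_params().replace(rho=0.0)
        rec = m.simulate_survey(n=20_000, params=params, seed=3)
        design = m.build_design(rec, "base")
        fit = m.fit_bivariate_probit(design, rec)
        op = sm.Probit(rec["buy_p"], design[0]).fit(disp=0)
        ok = sm.Probit(rec["buy_k"], design[1]).fit(disp=0)
        assert np.abs(fit.params_p.to_numpy() - op.params.to_numpy()).max() < 1e-3
        assert np.abs(fit.params_k.to_numpy() - ok.params.to_numpy()).max() < 1e-3
        assert abs(fit.rho) < 0.05

    def test_recovers_generating_parameters(self, records_20k, base_fit_20k):
        """Estimates at n = 20000 sit close to the generating normalized
        coefficients (consistency at large n)."""
        z = m.survey.PUBLISHED_PROPORTIONATE_FIT
        fit = base_fit_20k
        assert fit.converged
        assert fit.coef("parent", "delta") == pytest.approx(z["risk_p"], abs=0.06)
        assert fit.coef("child", "delta") == pytest.approx(z["risk_k"], abs=0.06)
        assert fit.coef("parent", "q") == pytest.approx(z["price_p"], abs=3e-4)
        assert fit.rho == pytest.approx(z["rho"], abs=0.02)

    def test_likelihood_matches_monte_carlo_orthant_probabilities(self):
        """Brute-force check of the full likelihood on a 50-record dataset:
        each record's orthant probability is estimated from 1e7 correlated
        normal draws; the summed log-likelihoods agree within 3 MC SE."""
        rec = m.simulate_survey(n=50, seed=42)
        design = m.build_design(rec, "base")
        bp = np.array([-0.4, 0.9, -0.004])
        bk = np.array([-0.35, 0.7, -0.0035])
        rho = 0.85
        ll = m.loglike_bivariate_probit(design[0], design[1],
                                        rec["buy_p"], rec["buy_k"], bp, bk, rho)
        sp = 2.0 * rec["buy_p"].to_numpy() - 1.0
        sk = 2.0 * rec["buy_k"].to_numpy() - 1.0
        a = sp * (design[0].to_numpy() @ bp)
        b = sk * (design[1].to_numpy() @ bk)
        r = sp * sk * rho
        rng = np.random.default_rng(7)
        n_draws, hits = 10_000_000, np.zeros(50)
        chunk = 1_000_000
        for _ in range(n_draws // chunk):
            e = rng.standard_normal((chunk, 2))
            for i in range(50):
                e2 = r[i] * e[:, 0] + np.sqrt(1 - r[i] ** 2) * e[:, 1]
                hits[i] += np.count_nonzero((e[:, 0] <= a[i]) & (e2 <= b[i]))
        p_hat = hits / n_draws
        ll_mc = np.log(p_hat).sum()
        se = np.sqrt(((1 - p_hat) / (n_draws * p_hat)).sum())
        assert abs(ll - ll_mc) < 3 * se

    def test_centering_absorbs_price_shift(self, records_2211):
        """Adding a constant to Q before centering changes nothing."""
        fit1 = m.fit_bivariate_probit(m.build_design(records_2211, "base"),
                                      records_2211)
        shifted = records_2211.copy()
        shifted["price"] = shifted["price"] + 500.0
        fit2 = m.fit_bivariate_probit(m.build_design(shifted, "base"), shifted)
        assert np.abs(fit1.theta - fit2.theta).max() < 1e-6

    def test_deterministic_given_data(self, records_2211):
        d = m.build_design(records_2211, "base")
        f1 = m.fit_bivariate_probit(d, records_2211)
        f2 = m.fit_bivariate_probit(d, records_2211)
        assert np.abs(f1.theta - f2.theta).max() < 1e-8

    def test_rmse_shrinks_with_sample_size(self):
        """Bias and spread of (gamma/sigma, -1/sigma, rho) shrink as n grows."""
        z = m.survey.PUBLISHED_PROPORTIONATE_FIT
        truth = np.array([z["risk_p"], z["price_p"], z["rho"]])
        rmse = {}
        for n in (500, 8000):
            errs = []
            for s in range(12):
                rec = m.simulate_survey(n=n, seed=50_000 + s)
                f = m.fit_bivariate_probit(m.build_design(rec, "base"), rec)
                est = np.array([f.coef("parent", "delta"),
                                f.coef("parent", "q"), f.rho])
                errs.append((est - truth) / truth)
            rmse[n] = np.sqrt(np.mean(np.square(errs), axis=0))
        assert (rmse[8000] < rmse[500]).all()

    def test_duplicate_outcomes_flag_boundary_rho(self):
        """Identical outcomes in both equations push rho to the boundary;
        the fit reports rather than hides the degeneracy."""
        rec = m.simulate_survey(n=800, seed=5)
        rec["buy_k"] = rec["buy_p"]
        rec["delta_k"] = rec["delta_p"]
        rec["r_k"] = rec["r_p"]
        d = m.build_design(rec, "base")
        fit = m.fit_bivariate_probit(d, rec)
        assert fit.rho > 0.99
        assert (not fit.converged) or fit.rho > 0.999

    def test_constant_outcome_rejected(self, records_2211):
        rec = records_2211.copy()
        rec["buy_p"] = 1
        with pytest.raises(ValueError, match="does not vary"):
            m.fit_bivariate_probit(m.build_design(rec, "base"), rec)

    def test_covariance_is_symmetric_psd_and_llf_negative(self, base_fit_20k):
        v = base_fit_20k.vcov.to_numpy()
        assert np.allclose(v, v.T, atol=1e-12)
        assert np.linalg.eigvalsh(v).min() > -1e-12
        assert base_fit_20k.llf < 0
        assert -1 < base_fit_20k.rho < 1


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

class TestLRTest:
    def test_identical_fits_give_zero_statistic(self, base_fit_20k):
        stat, df, p = m.lr_test(base_fit_20k, base_fit_20k)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_nested_interactions_are_12_df(self, records_2211):
        r = m.fit_bivariate_probit(
            m.build_design(records_2211, "risk_bins_main"), records_2211)
        f = m.fit_bivariate_probit(
            m.build_design(records_2211, "risk_bins"), records_2211)
        stat, df, p = m.lr_test(r, f)
        assert df == 12
        assert stat >= 0.0
        assert 0.0 <= p <= 1.0

    def test_llf_ordering_violation_raises(self, base_fit_20k):
        import dataclasses
        worse = dataclasses.replace(base_fit_20k, llf=base_fit_20k.llf - 5.0)
        with pytest.raises(RuntimeError, match="optimization failure"):
            m.lr_test(base_fit_20k, worse)


class TestWaldRatioEquality:
    def test_statistic_zero_for_identical_blocks(self, base_fit_20k):
        """Forcing identical parent/child coefficient blocks and covariance
        gives a zero Wald statistic."""
        import dataclasses
        fit = base_fit_20k
        names = fit.names
        v = fit.vcov.copy()
        # make the child block equal to the parent block, incl. covariance
        sym = dataclasses.replace(
            fit, params_k=fit.params_p.copy(),
            vcov=v,
        )
        stat, p = m.wald_ratio_equality(sym)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_doubled_parent_slope_is_rejected(self):
        """A 2x gap in the dollar slope at the study size is detected."""
        params = m.default_params()
        params = params.replace(gamma_p=2.0 * params.gamma_k)
        rejections = 0
        for s in range(20):
            rec = m.simulate_survey(n=2211, params=params, seed=900 + s)
            fit = m.fit_bivariate_probit(m.build_design(rec, "base"), rec)
            _, p = m.wald_ratio_equality(fit)
            rejections += p < 0.05
        assert rejections >= 18

    def test_unidentified_ratio_raises(self, base_fit_20k):
        import dataclasses
        fit = base_fit_20k
        p_mod = fit.params_p.copy()
        p_mod["q"] = 1e-6
        weak = dataclasses.replace(fit, params_p=p_mod)
        with pytest.raises(ValueError, match="unidentified"):
            m.wald_ratio_equality(weak)
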