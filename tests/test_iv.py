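"""IV engine: Wald ratio, 2SLS, Durbin-Wu-Hausman, IVW, and their
algebraic interrelations."""
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.sandbox.regression.gmm import IV2SLS

from bonemr import (
    AssociationEstimate,
    durbin_wu_hausman,
    ivw,
    observational_ols,
    tsls,
    wald_ratio,
)
from bonemr.exceptions import (
    DegenerateDataError,
    IdentificationError,
    UndefinedRatioError,
)


def assoc(beta, se, name="snp", trait="x", n=1000):
    return AssociationEstimate(name, trait, beta, se, 0.5, n)


def simulate_iv_data(rng, n=2000, beta=0.5, conf=0.4, r2=0.05):
    """One confounded world with a single valid instrument."""
    z = rng.binomial(2, 0.3, n).astype(float)
    u = rng.standard_normal(n)
    x = np.sqrt(r2 / 0.42) * z + conf * u + rng.standard_normal(n)
    y = beta * x + conf * u + rng.standard_normal(n)
    cov = np.column_stack([rng.normal(9.9, 0.3, n),
                           rng.integers(0, 2, n).astype(float)])
    return y, x, z, cov


class TestObservationalOLS:
    def test_identity_regression(self, rng):
        x = rng.standard_normal(500)
        est = observational_ols(x, x.copy())
        assert est.beta == pytest.approx(1.0, abs=1e-12)
        assert est.p < 1e-100

    def test_null_slope_small(self, rng):
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        est = observational_ols(y, x)
        assert abs(est.beta) < 3 * est.se and abs(est.beta) < 0.03

    def test_matches_statsmodels_with_covariates(self, rng):
        y, x, _, cov = simulate_iv_data(rng)
        est = observational_ols(y, x, cov)
        ys = (y - y.mean()) / y.std(ddof=1)
        xs = (x - x.mean()) / x.std(ddof=1)
        fit = sm.OLS(ys, sm.add_constant(np.column_stack([xs, cov]))).fit()
        assert est.beta == pytest.approx(fit.params[1], rel=1e-10)
        assert est.se == pytest.approx(fit.bse[1], rel=1e-8)
        assert est.p == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            observational_ols(np.ones(50), np.arange(50.0))


class TestWaldRatio:
    def test_simple_ratios(self):
        assert wald_ratio(assoc(1.0, 0.1), assoc(0.5, 0.1)).beta_iv == 0.5
        assert wald_ratio(assoc(0.3, 0.1), assoc(0.0, 0.1)).beta_iv == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(assoc(0.0, 0.1), assoc(0.5, 0.1))

    def test_weak_denominator_warns(self):
        with pytest.warns(UserWarning, match="weak denominator"):
            est = wald_ratio(assoc(0.05, 0.1), assoc(0.5, 0.1))
        assert est.warnings

    def test_delta_method_se_formula(self):
        est = wald_ratio(assoc(0.4, 0.02), assoc(0.2, 0.05))
        expected = np.sqrt(0.05**2 / 0.4**2 + 0.2**2 * 0.02**2 / 0.4**4)
        assert est.se == pytest.approx(expected, rel=1e-12)

    def test_delta_method_se_against_parametric_bootstrap(self, rng):
        """The first-order SE matches the SD of the ratio under independent
        normal sampling of numerator and denominator (2e5 draws)."""
        G = rng.normal(0.2, 0.05, 200_000)
        g = rng.normal(0.4, 0.02, 200_000)
        boot_sd = (G / g).std()
        est = wald_ratio(assoc(0.4, 0.02), assoc(0.2, 0.05))
        assert est.se == pytest.approx(boot_sd, rel=0.03)


class TestTSLS:
    def test_just_identified_equals_wald(self, rng):
        """Single-instrument 2SLS is algebraically the Wald ratio of the two
        sample regressions (machine precision)."""
        y, x, z, _ = simulate_iv_data(rng)
        gamma = observational_ols(x, z, standardize_variables=False,
                                  exposure_name="z")
        ys = (y - y.mean()) / y.std(ddof=1)
        xs = (x - x.mean()) / x.std(ddof=1)
        gamma_s = observational_ols(xs, z, standardize_variables=False)
        Gamma_s = observational_ols(ys, z, standardize_variables=False)
        est = tsls(y, x, z, compute_dwh=False)
        assert est.beta_iv == pytest.approx(Gamma_s.beta / gamma_s.beta, abs=1e-10)

    def test_just_identified_equals_wald_with_covariates(self, rng):
        y, x, z, cov = simulate_iv_data(rng)
        ys = (y - y.mean()) / y.std(ddof=1)
        xs = (x - x.mean()) / x.std(ddof=1)
        g = observational_ols(xs, z, cov, standardize_variables=False)
        G = observational_ols(ys, z, cov, standardize_variables=False)
        est = tsls(y, x, z, cov, compute_dwh=False)
        assert est.beta_iv == pytest.approx(G.beta / g.beta, abs=1e-10)

    def test_instrumenting_with_exposure_reproduces_ols(self, rng):
        y, x, _, cov = simulate_iv_data(rng)
        est_iv = tsls(y, x, x, cov, compute_dwh=False)
        est_ols = observational_ols(y, x, cov)
        assert est_iv.beta_iv == pytest.approx(est_ols.beta, abs=1e-10)
        assert est_iv.se == pytest.approx(est_ols.se, rel=1e-8)

    def test_matches_statsmodels_iv2sls(self, rng):
        y, x, z, cov = simulate_iv_data(rng)
        ys = (y - y.mean()) / y.std(ddof=1)
        xs = (x - x.mean()) / x.std(ddof=1)
        exog = sm.add_constant(np.column_stack([cov, xs]))
        instr = sm.add_constant(np.column_stack([cov, z]))
        ref = IV2SLS(ys, exog, instrument=instr).fit()
        est = tsls(y, x, z, cov, compute_dwh=False)
        assert est.beta_iv == pytest.approx(ref.params[-1], rel=1e-9)
        assert est.se == pytest.approx(ref.bse[-1], rel=1e-6)

    def test_under_identified_raises(self, rng):
        y, x, z, _ = simulate_iv_data(rng)
        with pytest.raises(IdentificationError):
            from bonemr.mvmr import mvmr_tsls
            mvmr_tsls(y, np.column_stack([x, x * 0.5 + 1]), z)

    def test_collinear_instruments_raise(self, rng):
        y, x, z, _ = simulate_iv_data(rng)
        with pytest.raises(IdentificationError):
            tsls(y, x, np.column_stack([z, 2 * z]), compute_dwh=False)

    def test_standardization_contract(self, rng):
        """Doubling the raw outcome scale leaves every SD-unit quantity
        unchanged."""
        y, x, z, cov = simulate_iv_data(rng)
        a = tsls(y, x, z, cov)
        b = tsls(2.0 * y, x, z, cov)
        assert a.beta_iv == pytest.approx(b.beta_iv, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)
        assert a.p_wh == pytest.approx(b.p_wh, abs=1e-12)

    def test_invariant_to_row_permutation(self, rng):
        y, x, z, cov = simulate_iv_data(rng, n=500)
        perm = rng.permutation(500)
        a = tsls(y, x, z, cov)
        b = tsls(y[perm], x[perm], z[perm], cov[perm])
        assert a.beta_iv == pytest.approx(b.beta_iv, abs=1e-10)

    def test_first_stage_f_attached(self, rng):
        y, x, z, cov = simulate_iv_data(rng, n=5000, r2=0.05)
        est = tsls(y, x, z, cov)
        assert est.f_first > 100 and not est.weak_instrument


class TestDurbinWuHausman:
    def test_perfect_instrument_gives_null(self, rng):
        n = 1000
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        stat, p = durbin_wu_hausman(y, x, x)
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert p > 0.99

    def test_detects_strong_confounding(self, rng):
        y, x, z, cov = simulate_iv_data(rng, n=8000, conf=0.8, r2=0.1)
        _, p = durbin_wu_hausman(y, x, z, cov)
        assert p < 1e-4


class TestIVW:
    def test_proportional_summaries_recover_slope_exactly(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        tab = pd.DataFrame({"gamma": g, "se_gamma": 0.01,
                            "Gamma": 0.5 * g, "se_Gamma": 0.02, "n": 100})
        est = ivw(tab)
        assert est.beta_iv == pytest.approx(0.5, abs=1e-12)

    def test_equal_weight_heterogeneous_ratios(self):
        # two SNPs with equal gamma and equal weights: ratios 0.4 and 0.6
        tab = pd.DataFrame({"gamma": [1.0, 1.0], "se_gamma": 0.01,
                            "Gamma": [0.4, 0.6], "se_Gamma": 0.05, "n": 100})
        assert ivw(tab).beta_iv == pytest.approx(0.5, abs=1e-12)

    def test_single_snp_degenerates_to_wald_with_warning(self):
        tab = pd.DataFrame({"snp_id": ["rs1"], "gamma": [0.4], "se_gamma": [0.02],
                            "Gamma": [0.2], "se_Gamma": [0.05], "n": [100]})
        with pytest.warns(UserWarning, match="single SNP"):
            est = ivw(tab)
        ref = wald_ratio(assoc(0.4, 0.02), assoc(0.2, 0.05))
        assert est.beta_iv == pytest.approx(ref.beta_iv, abs=1e-12)
        assert est.se == pytest.approx(ref.se, abs=1e-12)

    def test_matches_statsmodels_wls_through_origin(self, rng):
        m = 20
        g = rng.normal(0.1, 0.03, m)
        G = 0.4 * g + rng.normal(0, 0.02, m)
        se_G = rng.uniform(0.01, 0.04, m)
        tab = pd.DataFrame({"gamma": g, "se_gamma": 0.01, "Gamma": G,
                            "se_Gamma": se_G, "n": 100})
        est = ivw(tab)
        ref = sm.WLS(G, g[:, None], weights=1 / se_G**2).fit()
        assert est.beta_iv == pytest.approx(ref.params[0], rel=1e-10)
        assert est.se == pytest.approx(ref.bse[0], rel=1e-8)
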