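"""Per-SNP summary associations, MR-Egger regression, funnel data."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from bonemr import (
    egger_regression,
    funnel_data,
    ivw,
    make_scenario,
    simulate_cohort,
    snp_associations,
)
from bonemr.exceptions import InsufficientInstrumentsError


def summary_tables(gamma, Gamma, se_gamma=0.01, se_Gamma=0.02, maf=0.3):
    m = len(gamma)
    ids = [f"rs{i}" for i in range(m)]
    gt = pd.DataFrame({"snp_id": ids, "beta": gamma, "se": se_gamma,
                       "p": 0.5, "n": 1000, "maf": maf})
    Gt = pd.DataFrame({"snp_id": ids, "beta": Gamma, "se": se_Gamma,
                       "p": 0.5, "n": 1000})
    return gt, Gt


class TestSnpAssociations:
    def test_matches_per_snp_statsmodels(self, rng):
        n, m = 500, 5
        G = rng.binomial(2, 0.3, (n, m)).astype(float)
        cov = np.column_stack([rng.normal(9.9, 0.3, n), rng.integers(0, 2, n)])
        y = G @ rng.normal(0.1, 0.05, m) + cov @ [0.2, 0.1] + rng.standard_normal(n)
        dosages = pd.DataFrame(G, columns=[f"rs{j}" for j in range(m)])
        tab = snp_associations(y, dosages, cov)
        ys = (y - y.mean()) / y.std(ddof=1)
        for j in range(m):
            X = sm.add_constant(np.column_stack([G[:, j], cov]))
            fit = sm.OLS(ys, X).fit()
            row = tab.iloc[j]
            assert row["beta"] == pytest.approx(fit.params[1], rel=1e-9)
            assert row["se"] == pytest.approx(fit.bse[1], rel=1e-8)
            assert row["p"] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_closed_form_slope_with_known_effect(self, rng):
        """trait = 0.3*dosage + noise: the standardized per-allele slope is
        0.3/sd(trait) with sd(trait)^2 = 0.09*2pq + 1."""
        n, p = 40_000, 0.3
        g = rng.binomial(2, p, n).astype(float)
        y = 0.3 * g + rng.standard_normal(n)
        tab = snp_associations(y, pd.DataFrame({"rs0": g}))
        expected = 0.3 / np.sqrt(0.09 * 2 * p * (1 - p) + 1)
        assert tab["beta"].iloc[0] == pytest.approx(expected, abs=0.02)

    def test_monomorphic_dropped_and_row_count(self, rng, caplog):
        n = 200
        G = rng.binomial(2, 0.4, (n, 3)).astype(float)
        G[:, 1] = 0.0
        dosages = pd.DataFrame(G, columns=["rs0", "rs1", "rs2"])
        with caplog.at_level("WARNING", logger="bonemr"):
            tab = snp_associations(rng.standard_normal(n), dosages)
        assert len(tab) == 2 and "rs1" not in tab["snp_id"].tolist()
        assert any("monomorphic" in r.message for r in caplog.records)

    def test_permuted_trait_nominal_rate(self, rng):
        n, m = 2000, 64
        G = rng.binomial(2, 0.3, (n, m)).astype(float)
        y = rng.standard_normal(n)  # independent of G by construction
        tab = snp_associations(y, pd.DataFrame(G, columns=[f"rs{j}" for j in range(m)]))
        n_sig = int((tab["p"] < 0.05).sum())
        assert n_sig <= 10  # ~5% of 64 expected; binomial upper bound


class TestEggerRegression:
    def test_proportional_summaries_no_pleiotropy(self):
        g = np.linspace(0.05, 0.4, 8)
        res = egger_regression(*summary_tables(g, 0.5 * g))
        assert res.slope_beta_iv == pytest.approx(0.5, abs=1e-10)
        assert res.intercept_beta0 == pytest.approx(0.0, abs=1e-10)
        est = ivw(res.per_snp_inputs)
        assert est.beta_iv == pytest.approx(0.5, abs=1e-10)

    def test_constant_pleiotropy_affine_identity(self):
        g = np.linspace(0.05, 0.4, 8)
        res = egger_regression(*summary_tables(g, 0.5 * g + 0.02))
        assert res.slope_beta_iv == pytest.approx(0.5, abs=1e-10)
        assert res.intercept_beta0 == pytest.approx(0.02, abs=1e-10)

    def test_zero_intercept_constraint_reproduces_ivw(self, rng):
        g = rng.uniform(0.05, 0.3, 12)
        G = 0.4 * g + rng.normal(0, 0.02, 12)
        se_G = rng.uniform(0.01, 0.05, 12)
        gt, Gt = summary_tables(g, G, se_Gamma=se_G)
        res = egger_regression(gt, Gt)
        # through-origin WLS with the same weights == IVW, exactly
        w = res.per_snp_inputs["weight"].to_numpy()
        gg = res.per_snp_inputs["gamma"].to_numpy()
        GG = res.per_snp_inputs["Gamma"].to_numpy()
        constrained = float((w * gg * GG).sum() / (w * gg * gg).sum())
        assert constrained == pytest.approx(ivw(res.per_snp_inputs).beta_iv,
                                            rel=1e-12)

    def test_refit_from_per_snp_inputs_reproduces_result(self, rng):
        g = rng.uniform(-0.3, 0.3, 10)
        G = 0.3 * g + rng.normal(0.01, 0.02, 10)
        res = egger_regression(*summary_tables(g, G))
        tab = res.per_snp_inputs
        X = np.column_stack([np.ones(len(tab)), tab["gamma"]])
        w = tab["weight"].to_numpy()
        XtW = X.T * w
        b0, b1 = np.linalg.solve(XtW @ X, XtW @ tab["Gamma"].to_numpy())
        assert res.intercept_beta0 == pytest.approx(b0, abs=1e-10)
        assert res.slope_beta_iv == pytest.approx(b1, abs=1e-10)

    def test_single_snp_flip_invariance(self, rng):
        g = rng.uniform(0.05, 0.3, 9)
        G = 0.4 * g + rng.normal(0.01, 0.02, 9)
        gt, Gt = summary_tables(g, G)
        res_a = egger_regression(gt, Gt)
        gt2, Gt2 = gt.copy(), Gt.copy()
        gt2.loc[3, "beta"] *= -1  # orientation flip of one SNP
        Gt2.loc[3, "beta"] *= -1
        res_b = egger_regression(gt2, Gt2)
        assert res_a.slope_beta_iv == pytest.approx(res_b.slope_beta_iv, abs=1e-12)
        assert res_a.intercept_beta0 == pytest.approx(res_b.intercept_beta0,
                                                      abs=1e-12)

    def test_too_few_snps_raises(self):
        g = np.array([0.1, 0.2])
        with pytest.raises(InsufficientInstrumentsError):
            egger_regression(*summary_tables(g, 0.5 * g))

    def test_literal_se_weighting_flag(self, rng):
        g = rng.uniform(0.05, 0.3, 10)
        G = 0.4 * g + rng.normal(0.01, 0.03, 10)
        se_G = rng.uniform(0.01, 0.05, 10)
        gt, Gt = summary_tables(g, G, se_Gamma=se_G)
        a = egger_regression(gt, Gt, weights="inverse_variance")
        b = egger_regression(gt, Gt, weights="literal_se")
        assert a.slope_beta_iv != pytest.approx(b.slope_beta_iv, abs=1e-12)

    def test_bias_reduction_under_inside_pleiotropy(self):
        """With directional pleiotropy independent of instrument strength,
        the Egger slope is closer to the truth than IVW (here in a
        summary-level world with known truth 0.4)."""
        rng = np.random.default_rng(7)
        wins = 0
        reps = 100
        for _ in range(reps):
            m = 32
            g_true = rng.uniform(0.02, 0.12, m)
            alpha = rng.normal(0.02, 0.01, m)       # InSIDE-satisfied
            se_g, se_G = 0.005, 0.01
            g_hat = g_true + rng.normal(0, se_g, m)
            G_hat = 0.4 * g_true + alpha + rng.normal(0, se_G, m)
            gt, Gt = summary_tables(g_hat, G_hat, se_gamma=se_g, se_Gamma=se_G)
            egger_err = abs(egger_regression(gt, Gt).slope_beta_iv - 0.4)
            ivw_err = abs(ivw(egger_regression(gt, Gt).per_snp_inputs).beta_iv - 0.4)
            wins += egger_err < ivw_err
        assert wins / reps > 0.9


class TestFunnelData:
    def test_strength_formula(self):
        gt, Gt = summary_tables(np.array([0.2, 0.1, 0.3]),
                                np.array([0.1, 0.05, 0.15]), maf=0.5)
        pts = funnel_data(gt, Gt)
        assert pts[0].strength == pytest.approx(0.2 * np.sqrt(0.5), rel=1e-12)
        assert pts[0].ratio_estimate == pytest.approx(0.5, rel=1e-12)

    def test_zero_gamma_omitted(self):
        gt, Gt = summary_tables(np.array([0.2, 0.0, 0.3]),
                                np.array([0.1, 0.05, 0.15]))
        assert len(funnel_data(gt, Gt)) == 2

    def test_missing_maf_raises(self):
        gt, Gt = summary_tables(np.array([0.2, 0.1, 0.3]),
                                np.array([0.1, 0.05, 0.15]))
        gt = gt.drop(columns=["maf"])
        with pytest.raises(ValueError, match="rs"):
            funnel_data(gt, Gt)

    def test_funnel_symmetry_under_null_pleiotropy(self):
        """No correlation between strength and per-SNP ratio when pleiotropy
        is absent (cohort-level check at one seed)."""
        cohort = simulate_cohort(make_scenario(
            "null", n_individuals=4000, seed=31,
            overrides={"causal_fat_to_bmd": {"LL": 0.4}}))
        cov = cohort.covariates()
        gt = snp_associations(cohort.phenotypes["fat_mass"], cohort.dosages, cov)
        Gt = snp_associations(cohort.phenotypes["bmd_LL"], cohort.dosages, cov)
        pts = funnel_data(gt, Gt)
        strengths = np.array([p.strength for p in pts])
        # weight by strength to tame weak-SNP ratio noise, as a funnel reads
        ratios = np.array([p.ratio_estimate for p in pts])
        keep = strengths > np.median(strengths)
        r = np.corrcoef(strengths[keep], ratios[keep])[0, 1]
        assert abs(r) < 0.6
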