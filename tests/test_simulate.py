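"""Generator correctness: Hardy-Weinberg draws, determinism, calibration,
structural-equation moments, scenario presets."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonemr import (
    SITES,
    make_scenario,
    simulate_cohort,
    simulate_genotypes,
    structural_moments,
)
from bonemr.exceptions import CyclicConfigError, InvalidConfigError
from bonemr.simulate import SCENARIO_NAMES, TABLE1, N_REF


class TestGenotypes:
    def test_support_is_binomial_two(self):
        g = simulate_genotypes(4, [0.5], seed=11)
        assert g.shape == (4, 1)
        assert set(np.unique(g)) <= {0.0, 1.0, 2.0}

    def test_hwe_class_proportions(self):
        """At maf 0.2 genotype classes follow (q^2, 2pq, p^2) = (.64,.32,.04)."""
        n = 100_000
        g = simulate_genotypes(n, [0.2], seed=5)[:, 0]
        se_mean = np.sqrt(2 * 0.2 * 0.8 / n)
        assert abs(g.mean() - 0.4) < 3 * se_mean
        for k, expected in [(0, 0.64), (1, 0.32), (2, 0.04)]:
            prop = np.mean(g == k)
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(prop - expected) < 3 * se

    def test_determinism_and_seed_sensitivity(self):
        a = simulate_genotypes(10, [0.3, 0.7], seed=3)
        b = simulate_genotypes(10, [0.3, 0.7], seed=3)
        c = simulate_genotypes(10, [0.3, 0.7], seed=4)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("maf", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_maf_rejected(self, maf):
        with pytest.raises(InvalidConfigError):
            simulate_genotypes(10, [maf], seed=0)

    @given(seed=st.integers(0, 2**31 - 1),
           maf=st.floats(0.01, 0.99))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_dosage_range_property(self, seed, maf):
        g = simulate_genotypes(50, [maf], seed=seed)
        assert np.all((g >= 0) & (g <= 2))


class TestCohort:
    def test_same_seed_bit_identical(self):
        cfg = make_scenario("combined_C", n_individuals=300, seed=9)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(a.dosages, b.dosages)
        c = simulate_cohort(cfg.replace(seed=10))
        assert not a.phenotypes.equals(c.phenotypes)

    def test_dosage_mean_tracks_maf(self):
        cohort = simulate_cohort(make_scenario("null", n_individuals=20_000, seed=2))
        mafs = cohort.config.mafs
        se = np.sqrt(2 * mafs * (1 - mafs) / cohort.n)
        assert np.all(np.abs(cohort.sample_mafs().to_numpy() * 2 - 2 * mafs) < 4 * se)

    def test_null_world_has_no_phenotype_genotype_correlation(self):
        cfg = make_scenario("null", n_individuals=4000, seed=7,
                            overrides={"snp_fat_effects": np.zeros(32)})
        cohort = simulate_cohort(cfg)
        G = cohort.dosages.to_numpy(dtype=float)
        for col in ("fat_mass", "lean_mass", "bmd_LL"):
            y = cohort.phenotypes[col].to_numpy()
            r = np.corrcoef(G.T, y)[-1, :-1]
            # Bonferroni bound at alpha=0.001 over 32 SNPs
            crit = 3.85 / np.sqrt(cohort.n)
            assert np.all(np.abs(r) < crit)

    def test_table1_moment_calibration(self):
        """Simulated fat/lean means and SDs per sex match the published
        descriptive statistics of the source cohort."""
        cohort = simulate_cohort(make_scenario("combined_C",
                                               n_individuals=20_000, seed=21))
        phen = cohort.phenotypes
        for sex_code, sex_name in ((0, "male"), (1, "female")):
            sub = phen[phen["sex"] == sex_code]
            for col in ("fat_mass", "lean_mass", "bmd_LL", "height"):
                mu, sd = TABLE1[sex_name][col]
                assert abs(sub[col].mean() - mu) < 0.05 * mu + 3 * sd / np.sqrt(len(sub))
                assert abs(sub[col].std() - sd) < 0.08 * sd + 0.02
        # weight and BMI are derived; check they land near the published means
        for sex_code, sex_name in ((0, "male"), (1, "female")):
            sub = phen[phen["sex"] == sex_code]
            assert abs(sub["weight"].mean() - TABLE1[sex_name]["weight"][0]) < 0.6
            assert abs(sub["bmi"].mean() - TABLE1[sex_name]["bmi"][0]) < 0.6

    def test_genotypes_independent_of_confounder(self):
        cohort = simulate_cohort(make_scenario("combined_C",
                                               n_individuals=50_000, seed=13))
        G = cohort.dosages.to_numpy(dtype=float)
        U = cohort.latent["U"].to_numpy()
        r = np.corrcoef(G.T, U)[-1, :-1]
        assert np.all(np.abs(r) < 3.85 / np.sqrt(cohort.n))

    def test_closed_form_ols_slope_under_confounding(self, confounded_world):
        """With unit latent variances the standardized OLS slope of LL-BMD on
        fat equals causal + c_fat*c_LL = 0.6 + 0.1 (closed form)."""
        cohort = simulate_cohort(confounded_world(50_000, seed=3))
        fat = cohort.latent["fat"].to_numpy()
        bmd = cohort.latent["bmd_LL"].to_numpy()
        assert abs(fat.std() - 1) < 0.02 and abs(bmd.std() - 1) < 0.02
        slope = np.polyfit(fat / fat.std(), bmd / bmd.std(), 1)[0]
        assert abs(slope - 0.7) < 0.02

    def test_no_confounder_recovers_causal_slope(self):
        cfg = make_scenario("null", n_individuals=50_000, seed=17,
                            overrides={"causal_fat_to_bmd": {"LL": 0.6}})
        cohort = simulate_cohort(cfg)
        fat = cohort.latent["fat"].to_numpy()
        bmd = cohort.latent["bmd_LL"].to_numpy()
        slope = np.polyfit(fat / fat.std(), bmd / bmd.std(), 1)[0]
        assert abs(slope - 0.6) < 0.02

    def test_structural_moments_match_empirical(self):
        cfg = make_scenario("combined_C", n_individuals=100_000, seed=19)
        cohort = simulate_cohort(cfg)
        names = ["fat", "lean"] + [f"bmd_{s}" for s in SITES]
        emp = cohort.latent[names].cov().to_numpy()
        ana = structural_moments(cfg).to_numpy()
        assert np.abs(emp - ana).max() < 0.02

    def test_lognormal_fat_positive_and_calibrated(self):
        cohort = simulate_cohort(make_scenario("reverse_causal",
                                               n_individuals=30_000, seed=23))
        fat = cohort.phenotypes["fat_mass"]
        assert (fat > 0).all()
        males = cohort.phenotypes["sex"] == 0
        assert abs(fat[males].mean() - 7.41) < 0.2
        assert abs(fat[males].std() - 4.92) < 0.3


class TestScenarios:
    def test_unknown_name_lists_valid_names(self):
        with pytest.raises(InvalidConfigError, match="null"):
            make_scenario("not_a_scenario")

    def test_null_is_fully_null(self):
        cfg = make_scenario("null")
        assert all(v == 0 for v in cfg.causal_fat_to_bmd.values())
        assert all(v == 0 for v in cfg.causal_lean_to_bmd.values())
        assert cfg.causal_fat_to_lean == 0
        assert all(v == 0 for v in cfg.confounder_effects.values())
        assert np.all(cfg.snp_lean_effects == 0)
        assert np.all(cfg.snp_direct_outcome_effects == 0)

    def test_inside_violated_correlation_by_construction(self):
        cfg = make_scenario("inside_violated")
        d = cfg.snp_direct_outcome_effects[:, 0]
        r = np.corrcoef(cfg.snp_fat_effects, d)[0, 1]
        assert r >= 0.5

    def test_presets_have_unit_latent_variances(self):
        for name in SCENARIO_NAMES:
            mom = structural_moments(make_scenario(name))
            assert np.allclose(np.diag(mom), 1.0, atol=1e-9), name

    def test_cyclic_config_rejected(self):
        with pytest.raises(CyclicConfigError):
            make_scenario("null", overrides={
                "causal_fat_to_bmd": {"LL": 0.5},
                "causal_bmd_to_fat": {"LL": 0.3},
            })

    def test_weak_instruments_strongest_snp_f(self):
        """Median strongest single-SNP first-stage F lands near the
        calibration target of 26 (band [20, 32]) at the reference n."""
        from bonemr.egger import snp_associations

        max_f = []
        for rep in range(25):
            cohort = simulate_cohort(make_scenario(
                "weak_instruments", n_individuals=N_REF, seed=100 + rep))
            tab = snp_associations(cohort.phenotypes["fat_mass"],
                                   cohort.dosages, cohort.covariates())
            f = (tab["beta"] / tab["se"]) ** 2
            max_f.append(f.max())
        assert 20 <= np.median(max_f) <= 32

    def test_reverse_requires_acyclic_override(self):
        cfg = make_scenario("reverse_causal", overrides={
            "causal_bmd_to_fat": {"LL": 0.3},
            "causal_fat_to_bmd": {**{s: 0.0 for s in SITES}, "UL": 0.45},
        })
        assert cfg.reverse_site == "LL"
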