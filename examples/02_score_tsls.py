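"""Allelic-score instrumental-variable analysis of fat mass on BMD.

Builds the unweighted 32-SNP score, checks its first-stage strength, and
contrasts the observational (OLS) estimate with the two-stage least squares
causal estimate, including the Durbin-Wu-Hausman endogeneity p-value.
"""
from bonemr import (build_allelic_score, first_stage, make_scenario,
                    observational_ols, simulate_cohort, tsls)
import numpy as np

# a confounded world: true fat -> LL-BMD effect 0.6 SD/SD, OLS biased to ~0.7
c = np.sqrt(0.1)
cfg = make_scenario("null", n_individuals=5221, seed=7, overrides={
    "causal_fat_to_bmd": {"LL": 0.6},
    "confounder_effects": {"fat": c, "LL": c}})
cohort = simulate_cohort(cfg)

score = build_allelic_score(cohort.dosages, cohort.manifest, "BMI")
fs = first_stage(cohort.phenotypes["fat_mass"], score, cohort.covariates(),
                 instrument_id="allelic_score", exposure_name="fat_mass")
print(f"first stage: F = {fs.F_first:.1f} (R^2 = {fs.r_squared:.4f}), "
      f"weak = {fs.weak}")

obs = observational_ols(cohort.phenotypes["bmd_LL"], cohort.phenotypes["fat_mass"],
                        cohort.covariates())
est = tsls(cohort.phenotypes["bmd_LL"], cohort.phenotypes["fat_mass"],
           score.to_numpy(), cohort.covariates())
print(f"OBS : beta = {obs.beta:.3f} (se {obs.se:.3f})")
print(f"TSLS: beta = {est.beta_iv:.3f} [{est.ci_low:.3f}, {est.ci_high:.3f}], "
      f"P = {est.p:.2e}, P_WH = {est.p_wh:.3f}")
print("\nThe score F is ~10^2 (a strong composite instrument). OLS sits near "
      "0.7 (causal 0.6 + 0.1 confounding bias); TSLS should bracket the true "
      "0.6, and a small P_WH flags the OLS-IV discrepancy as endogeneity.")
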