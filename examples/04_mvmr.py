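"""Multivariable MR: separating direct fat and lean effects on BMD.

In the horizontal-pleiotropy world the instruments shift both fat and lean
mass, and both tissues affect bone.  Univariate score MR then mixes the two
pathways; multivariable 2SLS on the strong loci returns each tissue's direct
effect.
"""
from bonemr import (first_stage, make_scenario, mvmr_tsls,
                    select_strong_instruments, simulate_cohort, tsls)

cohort = simulate_cohort(make_scenario("horizontal_B", n_individuals=10_000,
                                       seed=3))
cov = cohort.covariates()

results = []
for snp in cohort.snp_ids:
    g = cohort.dosages[snp].to_numpy(dtype=float)
    for col in ("fat_mass", "lean_mass"):
        results.append(first_stage(cohort.phenotypes[col], g, cov,
                                   instrument_id=snp, exposure_name=col))
kept, audit = select_strong_instruments(results)
print(f"strong instruments (F >= 10): {len(kept)} of {len(cohort.snp_ids)}")

uni = tsls(cohort.phenotypes["bmd_LL"], cohort.phenotypes["fat_mass"],
           cohort.dosages[kept].to_numpy(), cov, compute_dwh=False)
res = mvmr_tsls(cohort.phenotypes["bmd_LL"],
                cohort.phenotypes[["fat_mass", "lean_mass"]],
                cohort.dosages[kept], cov)
print(f"univariate fat estimate : {uni.beta_iv:.3f}")
for row in res.exposures.itertuples():
    print(f"MVMR {row.exposure:10s}: {row.beta_iv:.3f} "
          f"[{row.ci_low:.3f}, {row.ci_high:.3f}] "
          f"(conditional F = {res.conditional_f[row.exposure]:.1f})")
print("\nGround truth on LL-BMD: fat direct 0.40, lean direct 0.54. The "
      "univariate estimate absorbs the lean pathway; the multivariable CIs "
      "bracket the direct effects instead. The Sanderson-Windmeijer "
      "conditional F is advisory: values below ~10 warn that the two first "
      "stages overlap and some weak-instrument shrinkage remains.")
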