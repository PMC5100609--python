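# Methods

This note documents the statistical model behind `bonemr`, the choices made
where the design was genuinely open, and what the simulator does and does not
establish.

## The estimation problem

One-sample MR with individual-level data: for exposure \(X\) (BMI or total
fat mass), outcome \(Y\) (BMD at one of five skeletal sites) and instrument
\(Z\), the package estimates \(\beta_{IV}\), the SD change in outcome per SD
change in exposure, under the instrumental-variable assumptions (relevance,
independence from confounders, exclusion restriction). Because single BMI
SNPs are weak (per-SNP \(F_{first}\) mostly below 10), the workhorse
instrument is the unweighted allelic score — the count of trait-increasing
alleles — whose first-stage F is of order \(10^2\) at \(n \approx 5000\).
The pleiotropy-robust estimators (MR-Egger, multivariable MR) address the
main threat to exclusion here: BMI-associated variants that also shift lean
mass, which itself loads bone.

## Estimators: numerical conventions

- **Standardization.** Exposures and outcomes are standardized to zero mean
  and unit SD on the analysis sample after complete-case filtering (ddof=1);
  covariates (age, sex) enter unstandardized. All reported effects are
  therefore SD-per-SD and invariant to affine rescaling of the raw traits.
- **2SLS.** Covariates appear in both stages. The covariance is the
  classical homoskedastic estimator with residuals formed against the
  *original* exposures (not the first-stage fits), \(\sigma^2\) with
  \(n-k\) degrees of freedom, and two-sided p-values from the t reference.
  The first stage is solved by QR; rank deficiency raises an identification
  error rather than silently pseudo-inverting.
- **Durbin–Wu–Hausman.** Score ("Durbin") form: first-stage residuals
  \(\hat v\) are appended to the outcome OLS and the statistic is
  \(n\,(RSS_0-RSS_1)/RSS_0\), referred to \(\chi^2\) with one df per
  exposure. A perfect instrument (zero first-stage residual variance)
  returns statistic 0, p = 1 by convention.
- **Wald ratio.** First-order delta-method SE with no covariance term
  between \(\hat\Gamma\) and \(\hat\gamma\); a warning is attached when the
  denominator's |t| < 1. Verified against a parametric bootstrap in the
  tests.
- **IVW and MR-Egger.** Both are weighted least squares of \(\hat\Gamma_j\)
  on \(\hat\gamma_j\) with weights \(1/se(\hat\Gamma_j)^2\) — IVW through
  the origin, Egger with an intercept. Inference uses the estimated residual
  scale (the multiplicative random-effects convention; what a plain weighted
  `lm` produces) with \(m-1\) / \(m-2\) df. Before the Egger fit each SNP is
  flipped so \(\hat\gamma_j \ge 0\), flipping \(\hat\Gamma_j\) in tandem;
  without this orientation the intercept is not identified. A flag disables
  orientation for sensitivity runs, and `weights="literal_se"` provides the
  alternative \(1/se\) reading of SE-weighting. No NOME/\(I^2_{GX}\)
  correction is applied. With a single SNP, IVW degenerates to the Wald
  ratio with a warning.
- **Multivariable MR.** Multi-exposure 2SLS; SEs from the 2SLS covariance
  (naive second-stage OLS SEs are known to be wrong). Conditional
  instrument strength per exposure follows Sanderson–Windmeijer: 2SLS of one
  exposure on the others, then the partial F of the instruments for the
  residual, rescaled by \(k_z/(k_z-k_x+1)\). It is advisory output only.
  Instrument selection keeps SNPs whose best first-stage F across exposures
  reaches 10 (configurable), mirroring the strong-locus practice.
- **Bidirectional MR.** Outcomes (BMI, fat mass) are natural-log transformed
  and then standardized — the base cancels under standardization — with an
  explicit error naming individuals if any value is non-positive.

## The simulator as a stated world

Cohorts are drawn from linear-Gaussian structural equations in causal order

U, age, sex → G (independent of U) → fat → lean → BMD per site,

with per-allele SNP effects on the SD scale, site-specific fat/lean causal
effects, optional per-SNP direct (horizontal-pleiotropy) outcome effects,
and a single standard-normal confounder U. Genotypes are independent
Binomial(2, maf) draws — no linkage disequilibrium, matching the treatment
of the 32 instruments as independent count contributions to the score. A
reverse-causal mode generates one designated site's BMD first and feeds it
into the fat equation; the forward edge (and any fat→lean→site chain) for
that site must be disabled, trading a simultaneous system for an acyclic one
that is sufficient for bidirectional testing.

**Calibration.** Per-SNP effects are derived from first-stage F targets at
the reference size n = 5221 via \(R^2_j = F_j/(F_j+n)\),
\(b_j = \sqrt{R^2_j / 2p_jq_j}\). The base panel has seven strong loci
(F targets 26, 20, 17, 15, 13, 12, 11 — the first is the fat-specific locus
with no lean effect) and twenty-five weak ones (F 1–6), which yields an
unweighted-score F of order \(10^2\). Residual SDs are solved from the
analytic structural covariance (`structural_moments`) so every latent
phenotype has unit variance; SD-unit causal parameters are then exact by
construction. Latent variables are mapped to natural units (kg, g/cm²,
years) through per-sex affine maps whose means/SDs are the published
descriptive statistics of the source cohort (n = 5221 nine-year-olds,
51% female; age truncated-normal 9.94 ± 0.32 on [9, 11]). Fat mass can
instead be mapped log-normally (moment-matched per sex): this keeps it
strictly positive and right-skewed — real child fat mass is; its log is what
is approximately normal — and makes log fat *affine* in the latent variable,
so the reverse-direction analyses are exactly linear. The reverse-causal
preset uses it; the affine map is the default elsewhere so that forward
SD-per-SD effects remain exact.

**Scenario presets** (`make_scenario`): `null` (everything zero),
`mediated_A` (fat→lean→BMD only), `horizontal_B` (SNPs shift fat and lean
independently; both tissues load bone directly), `combined_C` (both, plus
full confounding), `inside_violated` (direct outcome effects correlated 0.6
with the fat effects), `weak_instruments` (one strong fat-specific locus,
F ≈ 26, among a weak panel), `reverse_causal` (adds a 20-SNP BMD-score panel,
score F ≈ 80). In the mediation and horizontal presets the confounder loads
on the exposures but not on BMD, following the causal diagrams those
scenarios depict; this is also what makes the mediation property estimable:
with SNP–lean effects exactly proportional to SNP–fat effects the
multivariable first stage is population-collinear, and the fat coefficient
converges to the truth (zero) only when the residual endogeneity of lean
carries no open path to the outcome. `combined_C` carries confounding on all
nodes. Overrides may replace any config field; unless noise SDs are
overridden they are re-solved to preserve unit variances.

**What a green test does not establish.** The simulator has no LD, no
population stratification, no assortative mating, no genotyping error or
imputation uncertainty, Gaussian (or log-Gaussian) phenotypes with
homoskedastic noise, and a single confounder; calibration bands attained
here say nothing about robustness to those features. The per-sex affine maps
introduce a small (< 3%) gap between latent SD units and marginal SD units
of the natural-scale traits, visible as, e.g., a mean score-TSLS estimate of
~0.61 for a latent effect of 0.60.

## Calibration-study design choices

- The endogeneity-test power world fixes what the test sees — a 0.15-SD
  OLS–IV gap at n = 5000 — and uses a composite instrument with score
  R² = 0.10, chosen a priori to put the theoretical noncentrality near 3.3
  (≈90% power). At the study-scale score strength (R² ≈ 0.025) the same test
  has only ~40% power for that gap: a real analysis of this size should read
  a non-significant \(P_{WH}\) as weak evidence, not absence, of
  endogeneity.
- The site-contrast check classifies a cell as a strong positive signal at
  P < 0.001 — the level at which every causal cell in the source table
  prints — rather than at 0.05, where a true-null skull cell would fail the
  classification exactly 5% of the time by construction.
- Directional pleiotropy in the InSIDE world is one fixed draw
  \(\alpha_j \sim N(0.02, 0.01^2)\) independent of the instrument-strength
  vector; it is not orthogonalized against it, so a small chance correlation
  (and hence a small residual Egger bias) is part of the stated world.

## Known limitations

- Only the classical homoskedastic 2SLS covariance is implemented
  (`robust=False` is the lone mode); the era-standard choice, but
  heteroskedasticity-robust SEs would be a natural extension.
- Egger inference predates weak-instrument (NOME) corrections by design;
  with many weak instruments in one sample both Egger and IVW retain
  finite-sample bias toward the observational association.
- The multivariable conditional-F diagnostic is approximate (individual-level
  Sanderson–Windmeijer form) and advisory; no conditional weak-instrument
  correction is applied.
- Dosage-TSV input is taken at face value as effect-allele dosages; only VCF
  input is actively harmonized (REF/ALT flips, strand complements,
  palindromic flags).
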