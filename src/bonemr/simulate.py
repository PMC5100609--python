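"""Synthetic cohort generator for adiposity-bone Mendelian randomization.

The generator draws individual-level cohorts from a linear-Gaussian
structural-equation model that mirrors the causal diagrams the analysis is
meant to probe::

    U (unmeasured confounder)
    G_j ~ Binomial(2, maf_j)                      independent SNP dosages
    fat  = G b_fat + c_fat U + eps_fat            (SD units)
    lean = kappa fat + G b_lean + c_lean U + eps_lean
    BMD_s = beta_fat[s] fat + beta_lean[s] lean + G d_s + c_s U + eps_s

for each skeletal site ``s`` in {SK, UL, LL, SP, PE}.  SNP effects are
per-allele on the SD scale; causal effects are SD-per-SD.  A reverse-causal
mode replaces the fat equation's forward path to one designated site with a
BMD -> fat path (the forward edge is disabled to keep the graph acyclic).

Standardized latent phenotypes are mapped to natural units (kg, g/cm^2)
through per-sex affine maps whose means and SDs are the published descriptive
statistics of the source cohort of ~5200 nine-year-olds, so that simulated
tables look like the real ones at the marginal level.  Named scenario presets
reproduce the pleiotropy structures of interest (mediation through lean mass,
horizontal pleiotropy, their combination, an InSIDE violation, a
weak-instrument panel, and a reverse-causal world).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data import SITES, Cohort, InstrumentManifest
from .exceptions import CyclicConfigError, InvalidConfigError

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_cohort",
    "make_scenario",
    "structural_moments",
    "SCENARIO_NAMES",
    "TABLE1",
    "N_REF",
]

#: Reference sample size used to calibrate per-SNP effects from first-stage
#: F targets (the source study analysed 5221 children).
N_REF = 5221

#: Fraction of females (2660 of 5221).
FEMALE_FRAC = 2660 / 5221

#: Descriptive calibration moments, per sex: (mean, SD) in natural units.
TABLE1: dict[str, dict[str, tuple[float, float]]] = {
    "male": {
        "age": (9.94, 0.32), "height": (139.94, 6.17), "weight": (34.47, 7.20),
        "bmi": (17.49, 2.77), "fat_mass": (7.41, 4.92), "lean_mass": (25.51, 2.94),
        "bmd_SK": (1.59, 0.14), "bmd_UL": (0.66, 0.04), "bmd_LL": (0.90, 0.08),
        "bmd_SP": (0.77, 0.08), "bmd_PE": (0.83, 0.07),
    },
    "female": {
        "age": (9.94, 0.32), "height": (139.40, 6.52), "weight": (34.98, 7.59),
        "bmi": (17.88, 2.94), "fat_mass": (9.66, 5.05), "lean_mass": (23.62, 3.14),
        "bmd_SK": (1.56, 0.14), "bmd_UL": (0.65, 0.04), "bmd_LL": (0.89, 0.08),
        "bmd_SP": (0.78, 0.08), "bmd_PE": (0.83, 0.07),
    },
}

SCENARIO_NAMES = (
    "null", "mediated_A", "horizontal_B", "combined_C",
    "inside_violated", "weak_instruments", "reverse_causal",
)

# Non-palindromic allele pairs cycled through when fabricating manifests.
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


def _site_map(value, default=0.0) -> dict[str, float]:
    """Normalise a per-site argument (scalar or partial mapping) to a dict."""
    if value is None:
        return {s: default for s in SITES}
    if np.isscalar(value):
        return {s: float(value) for s in SITES}
    out = {s: default for s in SITES}
    for k, v in dict(value).items():
        if k not in SITES:
            raise InvalidConfigError(f"unknown skeletal site {k!r}; sites are {SITES}")
        out[k] = float(v)
    return out


@dataclass
class SimulationConfig:
    """Full parameterisation of the structural-equation cohort model.

    All SNP effects are per effect-allele copy on the standardized (SD)
    phenotype scale; causal effects are SD outcome per SD exposure.  A config
    fully determines the joint distribution: the same seed yields a
    bit-identical cohort.
    """

    n_individuals: int
    mafs: np.ndarray
    snp_fat_effects: np.ndarray
    snp_lean_effects: np.ndarray
    #: (n_snps, 5) horizontal-pleiotropy effects directly on each site's BMD.
    snp_direct_outcome_effects: np.ndarray
    causal_fat_to_bmd: dict[str, float]
    causal_lean_to_bmd: dict[str, float]
    causal_fat_to_lean: float = 0.0
    #: Reverse path; at most one site may be nonzero, and that site's forward
    #: fat path (and any fat->lean->site chain) must be disabled.
    causal_bmd_to_fat: dict[str, float] = field(default_factory=dict)
    #: Loadings of the unmeasured confounder U on 'fat', 'lean' and each site.
    confounder_effects: dict[str, float] = field(default_factory=dict)
    #: Residual SDs for 'fat', 'lean' and each site.
    noise_sds: dict[str, float] = field(default_factory=dict)
    #: Optional (sex, age) loadings on the latent scale, keyed like noise_sds.
    sex_age_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    female_frac: float = FEMALE_FRAC
    #: Map fat mass to natural units through a log-normal (strictly positive,
    #: right-skewed) law instead of the per-sex affine map.  Required by the
    #: reverse-direction analyses, whose outcome is log fat mass.
    lognormal_fat: bool = False
    #: Per-SNP trait tags written into the generated manifest.
    trait_tags: tuple[str, ...] | None = None
    seed: int = 0
    scenario: str | None = None

    def __post_init__(self) -> None:
        self.mafs = np.asarray(self.mafs, dtype=float)
        m = self.mafs.size
        self.snp_fat_effects = np.asarray(self.snp_fat_effects, dtype=float)
        self.snp_lean_effects = np.asarray(self.snp_lean_effects, dtype=float)
        d = np.asarray(self.snp_direct_outcome_effects, dtype=float)
        if d.ndim == 1:
            d = np.repeat(d[:, None], len(SITES), axis=1)
        self.snp_direct_outcome_effects = d
        self.causal_fat_to_bmd = _site_map(self.causal_fat_to_bmd)
        self.causal_lean_to_bmd = _site_map(self.causal_lean_to_bmd)
        self.causal_bmd_to_fat = _site_map(self.causal_bmd_to_fat)
        conf = {"fat": 0.0, "lean": 0.0, **{s: 0.0 for s in SITES}}
        conf.update({k: float(v) for k, v in self.confounder_effects.items()})
        self.confounder_effects = conf
        noise = {"fat": 1.0, "lean": 1.0, **{s: 1.0 for s in SITES}}
        noise.update({k: float(v) for k, v in self.noise_sds.items()})
        self.noise_sds = noise
        if self.trait_tags is None:
            self.trait_tags = tuple("BMI" for _ in range(m))
        self.validate()

    @property
    def n_snps(self) -> int:
        return self.mafs.size

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise InvalidConfigError("n_individuals must be positive")
        if self.mafs.size == 0:
            raise InvalidConfigError("at least one SNP required")
        if np.any((self.mafs <= 0) | (self.mafs >= 1)):
            raise InvalidConfigError("all mafs must lie strictly in (0, 1)")
        m = self.mafs.size
        for name, arr in (("snp_fat_effects", self.snp_fat_effects),
                          ("snp_lean_effects", self.snp_lean_effects)):
            if arr.shape != (m,):
                raise InvalidConfigError(f"{name} must have shape ({m},)")
        if self.snp_direct_outcome_effects.shape != (m, len(SITES)):
            raise InvalidConfigError(
                f"snp_direct_outcome_effects must have shape ({m}, {len(SITES)})")
        if len(self.trait_tags) != m:
            raise InvalidConfigError("trait_tags length must equal n_snps")
        for key, sd in self.noise_sds.items():
            if sd < 0:
                raise InvalidConfigError(f"negative noise SD for {key}")
        if not (0 < self.female_frac < 1):
            raise InvalidConfigError("female_frac must be in (0, 1)")
        reverse = [s for s in SITES if self.causal_bmd_to_fat[s] != 0.0]
        if len(reverse) > 1:
            raise CyclicConfigError(
                f"at most one reverse BMD->fat path allowed, got {reverse}")
        for s in reverse:
            if self.causal_fat_to_bmd[s] != 0.0:
                raise CyclicConfigError(
                    f"site {s}: simultaneous fat->BMD and BMD->fat paths form a cycle")
            if self.causal_fat_to_lean != 0.0 and self.causal_lean_to_bmd[s] != 0.0:
                raise CyclicConfigError(
                    f"site {s}: fat->lean->BMD chain plus BMD->fat forms a cycle")

    @property
    def reverse_site(self) -> str | None:
        for s in SITES:
            if self.causal_bmd_to_fat[s] != 0.0:
                return s
        return None

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


def simulate_genotypes(n: int, mafs, seed) -> np.ndarray:
    """Draw an (n, m) dosage matrix of independent Hardy-Weinberg SNPs.

    Each entry is the sum of two Bernoulli(maf) allele draws, i.e.
    Binomial(2, maf).  ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs >= 1)):
        raise InvalidConfigError("all mafs must lie strictly in (0, 1)")
    if n <= 0:
        raise InvalidConfigError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, mafs, size=(n, mafs.size)).astype(float)


def structural_moments(config: SimulationConfig) -> pd.DataFrame:
    """Implied covariance matrix of the latent (fat, lean, BMD per site).

    Each latent variable is expressed as a loading vector on the independent
    primitives (SNP dosages, the confounder U, the residual of each node, and
    the sex/age covariates); the covariance matrix follows exactly from the
    primitive variances.  Used to choose residual SDs when normalising
    scenario presets to unit latent variances, and as a closed-form oracle
    for expected OLS slopes under the linear structural model.
    """
    cfg = config
    m = cfg.n_snps
    s2g = 2 * cfg.mafs * (1 - cfg.mafs)
    c = cfg.confounder_effects
    kap = cfg.causal_fat_to_lean
    sexvar = cfg.female_frac * (1 - cfg.female_frac)
    D = cfg.snp_direct_outcome_effects

    # primitive order: G_1..G_m, U, eps_fat, eps_lean, eps_site*5, sex, age
    n_prim = m + 1 + 2 + len(SITES) + 2
    prim_var = np.empty(n_prim)
    prim_var[:m] = s2g
    prim_var[m] = 1.0
    prim_var[m + 1] = cfg.noise_sds["fat"] ** 2
    prim_var[m + 2] = cfg.noise_sds["lean"] ** 2
    for j, s in enumerate(SITES):
        prim_var[m + 3 + j] = cfg.noise_sds[s] ** 2
    prim_var[m + 8] = sexvar
    prim_var[m + 9] = 1.0
    U_I, EF_I, EL_I, ES0_I, SEX_I, AGE_I = m, m + 1, m + 2, m + 3, m + 8, m + 9

    def base(key: str, eps_index: int) -> np.ndarray:
        v = np.zeros(n_prim)
        v[eps_index] = 1.0
        sx, ag = cfg.sex_age_effects.get(key, (0.0, 0.0))
        v[SEX_I], v[AGE_I] = sx, ag
        return v

    L: dict[str, np.ndarray] = {}
    rev = cfg.reverse_site
    if rev is not None:
        jr = SITES.index(rev)
        v = base(rev, ES0_I + jr)
        v[:m] += D[:, jr]
        v[U_I] += c[rev]
        L[f"bmd_{rev}"] = v
    v = base("fat", EF_I)
    v[:m] += cfg.snp_fat_effects
    v[U_I] += c["fat"]
    if rev is not None:
        v = v + cfg.causal_bmd_to_fat[rev] * L[f"bmd_{rev}"]
    L["fat"] = v
    v = base("lean", EL_I) + kap * L["fat"]
    v[:m] += cfg.snp_lean_effects
    v[U_I] += c["lean"]
    L["lean"] = v
    for j, s in enumerate(SITES):
        if s == rev:
            continue
        v = (base(s, ES0_I + j) + cfg.causal_fat_to_bmd[s] * L["fat"]
             + cfg.causal_lean_to_bmd[s] * L["lean"])
        v[:m] += D[:, j]
        v[U_I] += c[s]
        L[f"bmd_{s}"] = v

    names = ["fat", "lean"] + [f"bmd_{s}" for s in SITES]
    A = np.vstack([L[name] for name in names])
    cov = (A * prim_var) @ A.T
    return pd.DataFrame(cov, index=names, columns=names)


def _solve_unit_noise(params: dict) -> dict[str, float]:
    """Residual SDs giving each latent phenotype unit variance.

    Works sequentially in causal order with a probe config whose noise is
    zero, reading off the structurally explained variance at each node.
    Raises if any node's explained variance already exceeds 1.
    """
    probe = dict(params)
    probe["noise_sds"] = {k: 0.0 for k in ["fat", "lean", *SITES]}
    cfg = SimulationConfig(**probe)
    noise: dict[str, float] = {}
    rev = cfg.reverse_site
    order = ["fat", "lean", *SITES]
    if rev is not None:  # the reverse site precedes fat in causal order
        order = [rev, "fat", "lean", *(s for s in SITES if s != rev)]
    for key in order:
        cfg = cfg.replace(noise_sds={**cfg.noise_sds, **noise})
        mom = structural_moments(cfg)
        name = key if key in ("fat", "lean") else f"bmd_{key}"
        explained = mom.loc[name, name]
        if explained > 1.0 + 1e-9:
            raise InvalidConfigError(
                f"structurally explained variance of {name} is {explained:.3f} > 1; "
                "cannot normalise to unit variance")
        noise[key] = float(np.sqrt(max(1.0 - explained, 0.0)))
    return noise


def _build_manifest(config: SimulationConfig) -> InstrumentManifest:
    m = config.n_snps
    rows = []
    for j in range(m):
        eff, oth = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        rows.append({
            "snp_id": f"rs{10001 + j}",
            "effect_allele": eff,
            "other_allele": oth,
            "trait_tag": config.trait_tags[j],
            "maf": config.mafs[j],
            "published_effect": (config.snp_fat_effects[j]
                                 if config.trait_tags[j] == "BMI"
                                 else float(np.mean(config.snp_direct_outcome_effects[j]))),
        })
    return InstrumentManifest(pd.DataFrame(rows))


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw one cohort from the structural-equation model.

    Structural order: confounder and covariates, then genotypes (independent
    of U), then fat, lean and site-specific BMD.  If a reverse BMD->fat path
    is configured, that site's BMD is generated first from its genetic and
    confounder terms only.  Latent SD-scale phenotypes are then mapped to
    natural units through the per-sex calibration moments.
    """
    cfg = config
    n, m = cfg.n_individuals, cfg.n_snps
    rng = np.random.default_rng(cfg.seed)

    sex = (rng.random(n) < cfg.female_frac).astype(float)  # 1 = female
    a, b = (9.0 - 9.94) / 0.32, (11.0 - 9.94) / 0.32
    age_c = stats.truncnorm.rvs(a, b, size=n, random_state=rng)  # ~N(0,1) truncated
    age = 9.94 + 0.32 * age_c
    U = rng.standard_normal(n)
    G = simulate_genotypes(n, cfg.mafs, rng)
    Gc = G - 2 * cfg.mafs  # centered dosages keep latent means at zero

    sex_c = sex - cfg.female_frac
    c = cfg.confounder_effects

    def sa(key: str) -> np.ndarray:
        sx, ag = cfg.sex_age_effects.get(key, (0.0, 0.0))
        return sx * sex_c + ag * age_c

    z: dict[str, np.ndarray] = {}
    rev = cfg.reverse_site
    if rev is not None:
        j = SITES.index(rev)
        z[f"bmd_{rev}"] = (Gc @ cfg.snp_direct_outcome_effects[:, j]
                           + c[rev] * U + sa(rev)
                           + cfg.noise_sds[rev] * rng.standard_normal(n))
    fat = (Gc @ cfg.snp_fat_effects + c["fat"] * U + sa("fat")
           + cfg.noise_sds["fat"] * rng.standard_normal(n))
    if rev is not None:
        fat = fat + cfg.causal_bmd_to_fat[rev] * z[f"bmd_{rev}"]
    z["fat"] = fat
    z["lean"] = (cfg.causal_fat_to_lean * fat + Gc @ cfg.snp_lean_effects
                 + c["lean"] * U + sa("lean")
                 + cfg.noise_sds["lean"] * rng.standard_normal(n))
    for j, s in enumerate(SITES):
        if s == rev:
            continue
        z[f"bmd_{s}"] = (cfg.causal_fat_to_bmd[s] * z["fat"]
                         + cfg.causal_lean_to_bmd[s] * z["lean"]
                         + Gc @ cfg.snp_direct_outcome_effects[:, j]
                         + c[s] * U + sa(s)
                         + cfg.noise_sds[s] * rng.standard_normal(n))

    # Map latent SD-scale variables to natural units with per-sex moments.
    def natural(key: str, zval: np.ndarray) -> np.ndarray:
        mu_m, sd_m = TABLE1["male"][key]
        mu_f, sd_f = TABLE1["female"][key]
        mu = np.where(sex == 1, mu_f, mu_m)
        sd = np.where(sex == 1, sd_f, sd_m)
        return mu + sd * zval

    def natural_lognormal(key: str, zval: np.ndarray) -> np.ndarray:
        # log-normal map matching the same per-sex mean/SD by moments; keeps
        # the variable strictly positive and right-skewed, and makes its log
        # affine in the latent variable.
        mu_m, sd_m = TABLE1["male"][key]
        mu_f, sd_f = TABLE1["female"][key]
        mu = np.where(sex == 1, mu_f, mu_m)
        sd = np.where(sex == 1, sd_f, sd_m)
        s2 = np.log1p((sd / mu) ** 2)
        return np.exp(np.log(mu) - s2 / 2 + np.sqrt(s2) * zval)

    ids = pd.Index([f"I{i + 1:06d}" for i in range(n)], name="individual_id")
    phen = pd.DataFrame(index=ids)
    fat_map = natural_lognormal if cfg.lognormal_fat else natural
    phen["fat_mass"] = fat_map("fat_mass", z["fat"])
    phen["lean_mass"] = natural("lean_mass", z["lean"])
    for s in SITES:
        phen[f"bmd_{s}"] = natural(f"bmd_{s}", z[f"bmd_{s}"])
    height_z = 0.4 * age_c + np.sqrt(1 - 0.4 ** 2) * rng.standard_normal(n)
    phen["height"] = natural("height", height_z)
    rest_mu = {sx: TABLE1[sx]["weight"][0] - TABLE1[sx]["fat_mass"][0]
               - TABLE1[sx]["lean_mass"][0] for sx in ("male", "female")}
    rest = (np.where(sex == 1, rest_mu["female"], rest_mu["male"])
            + 0.5 * rng.standard_normal(n))
    phen["weight"] = phen["fat_mass"] + phen["lean_mass"] + rest
    phen["bmi"] = phen["weight"] / (phen["height"] / 100.0) ** 2
    phen["age"] = age
    phen["sex"] = sex

    dosages = pd.DataFrame(G, index=ids, columns=[f"rs{10001 + j}" for j in range(m)])
    latent = pd.DataFrame({k: v for k, v in z.items()}, index=ids)
    latent["U"] = U
    return Cohort(dosages=dosages, phenotypes=phen, manifest=_build_manifest(cfg),
                  config=cfg, latent=latent)


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

def _effects_from_f_targets(f_targets: np.ndarray, mafs: np.ndarray) -> np.ndarray:
    """Per-allele effects hitting given first-stage F targets at ``N_REF``.

    Uses F ~= n R^2 / (1 - R^2) per SNP, i.e. R^2_j = F_j / (F_j + n), and
    b_j = sqrt(R^2_j / (2 p_j q_j)) on a unit-variance exposure.
    """
    f_targets = np.asarray(f_targets, dtype=float)
    r2 = f_targets / (f_targets + N_REF)
    return np.sqrt(r2 / (2 * mafs * (1 - mafs)))


_BASE_MAFS = np.linspace(0.12, 0.48, 32)
#: Heterogeneous instrument-strength targets: seven strong loci (the first is
#: the fat-specific one, F ~ 26) and twenty-five weak ones, mimicking the
#: observed spread of first-stage F statistics.
_BASE_F_TARGETS = np.concatenate([
    [26.0, 20.0, 17.0, 15.0, 13.0, 12.0, 11.0], np.linspace(1.0, 6.0, 25)])
_WEAK_F_TARGETS = np.concatenate([
    [26.0, 14.0, 12.0, 11.0, 10.0, 10.0, 9.0], np.linspace(1.0, 8.0, 25)])

_SITE_FAT_DIRECT = {"SK": 0.0, "UL": 0.45, "LL": 0.40, "SP": 0.42, "PE": 0.40}
_SITE_LEAN_DIRECT = {"SK": 0.25, "UL": 0.50, "LL": 0.54, "SP": 0.50, "PE": 0.50}
_SITE_FAT_TOTAL = {"SK": 0.0, "UL": 0.45, "LL": 0.60, "SP": 0.50, "PE": 0.45}


#: Lean-mass first-stage F targets with a pattern distinct from the fat
#: targets: the seven strong loci are strong for lean too but in a different
#: order (as observed for those loci), except the first, fat-specific one;
#: the weak panel is a rotation of the weak fat targets.
_LEAN_F_TARGETS = np.concatenate([
    [0.0, 18.0, 24.0, 12.0, 20.0, 15.0, 11.0],
    np.roll(np.linspace(1.0, 6.0, 25), 11)])


def _lean_independent_effects(mafs: np.ndarray) -> np.ndarray:
    """Lean effects whose pattern is not proportional to the fat effects.

    Needed for horizontal-pleiotropy worlds and for multivariable MR, whose
    identification requires the two first stages to be well separated.
    """
    return _effects_from_f_targets(_LEAN_F_TARGETS, mafs)


def make_scenario(name: str, n_individuals: int = N_REF, seed: int = 0,
                  overrides: Mapping | None = None) -> SimulationConfig:
    """Return a fully populated scenario preset.

    ``overrides`` replaces any :class:`SimulationConfig` field after the
    preset is assembled; unless ``noise_sds`` itself is overridden, residual
    SDs are re-solved so every latent phenotype keeps unit variance.
    """
    if name not in SCENARIO_NAMES:
        raise InvalidConfigError(
            f"unknown scenario {name!r}; valid names: {SCENARIO_NAMES}")
    mafs = _BASE_MAFS.copy()
    b_fat = _effects_from_f_targets(_BASE_F_TARGETS, mafs)
    m = mafs.size
    params: dict = dict(
        n_individuals=n_individuals,
        mafs=mafs,
        snp_fat_effects=b_fat,
        snp_lean_effects=np.zeros(m),
        snp_direct_outcome_effects=np.zeros((m, len(SITES))),
        causal_fat_to_bmd={},
        causal_lean_to_bmd={},
        causal_fat_to_lean=0.0,
        causal_bmd_to_fat={},
        confounder_effects={},
        sex_age_effects={},
        seed=seed,
        scenario=name,
    )

    if name == "null":
        pass  # all causal, pleiotropy and confounder effects zero
    elif name == "mediated_A":
        params.update(
            causal_fat_to_lean=0.30,
            causal_lean_to_bmd=dict(_SITE_LEAN_DIRECT),
            confounder_effects={"fat": 0.25, "lean": 0.25},
        )
    elif name == "horizontal_B":
        params.update(
            snp_lean_effects=_lean_independent_effects(mafs),
            causal_fat_to_bmd=dict(_SITE_FAT_DIRECT),
            causal_lean_to_bmd=dict(_SITE_LEAN_DIRECT),
            confounder_effects={"fat": 0.25, "lean": 0.25},
        )
    elif name == "combined_C":
        params.update(
            snp_lean_effects=_lean_independent_effects(mafs),
            causal_fat_to_lean=0.30,
            causal_fat_to_bmd=dict(_SITE_FAT_DIRECT),
            causal_lean_to_bmd=dict(_SITE_LEAN_DIRECT),
            confounder_effects={"fat": 0.30, "lean": 0.20,
                                **{s: 0.25 for s in SITES}},
        )
    elif name == "inside_violated":
        # Direct outcome effects correlated (r = 0.6 by construction) with
        # the instrument-fat effects: a directional InSIDE violation.
        bz = (b_fat - b_fat.mean()) / b_fat.std()
        eta = np.random.default_rng(777).standard_normal(m)
        eta = eta - bz * (eta @ bz) / (bz @ bz)
        eta = (eta - eta.mean()) / eta.std()
        d = 0.02 + 0.012 * (0.6 * bz + 0.8 * eta)
        params.update(
            snp_lean_effects=_lean_independent_effects(mafs),
            snp_direct_outcome_effects=np.repeat(d[:, None], len(SITES), axis=1),
            causal_fat_to_bmd=dict(_SITE_FAT_DIRECT),
            causal_lean_to_bmd=dict(_SITE_LEAN_DIRECT),
            confounder_effects={"fat": 0.25, "lean": 0.25},
        )
    elif name == "weak_instruments":
        b_weak = _effects_from_f_targets(_WEAK_F_TARGETS, mafs)
        b_lean = 0.6 * b_weak
        b_lean[0] = 0.0  # the fat-specific strong locus
        params.update(
            snp_fat_effects=b_weak,
            snp_lean_effects=b_lean,
            causal_fat_to_bmd=dict(_SITE_FAT_TOTAL),
            confounder_effects={"fat": 0.30, "lean": 0.20,
                                **{s: 0.25 for s in SITES}},
        )
    elif name == "reverse_causal":
        n_bmd = 20
        mafs = np.concatenate([_BASE_MAFS, np.linspace(0.15, 0.45, n_bmd)])
        mtot = mafs.size
        b_fat = np.concatenate([_effects_from_f_targets(_BASE_F_TARGETS, _BASE_MAFS),
                                np.zeros(n_bmd)])
        # BMD-score SNPs: equal-split effects giving a score F ~ 80 at N_REF.
        r2_bmd = 80.0 / (80.0 + N_REF)
        s2g_bmd = 2 * mafs[32:] * (1 - mafs[32:])
        d_per = np.sqrt(r2_bmd / s2g_bmd.sum())
        D = np.zeros((mtot, len(SITES)))
        D[32:, :] = d_per
        params.update(
            mafs=mafs,
            snp_fat_effects=b_fat,
            snp_lean_effects=np.zeros(mtot),
            snp_direct_outcome_effects=D,
            causal_fat_to_bmd=dict(_SITE_FAT_TOTAL),
            confounder_effects={"fat": 0.30, **{s: 0.25 for s in SITES}},
            trait_tags=tuple(["BMI"] * 32 + ["FN-BMD"] * n_bmd),
            lognormal_fat=True,
        )

    if overrides:
        unknown = set(overrides) - {f.name for f in dataclasses.fields(SimulationConfig)}
        if unknown:
            raise InvalidConfigError(f"unknown override fields: {sorted(unknown)}")
        params.update(overrides)
        if "mafs" in overrides:
            params.setdefault("trait_tags", None)

    if overrides is None or "noise_sds" not in overrides:
        params["noise_sds"] = _solve_unit_noise(params)
    return SimulationConfig(**params)
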