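"""End-to-end analysis orchestration and report generation.

:func:`run_analysis` drives the full study workflow over a cohort — either
simulated from a named scenario or loaded from genotype/phenotype/manifest
files — and assembles a report bundle shaped like the source study's summary
table: per exposure and skeletal site, an observational (OBS) row, an
allelic-score two-stage least squares (TSLS) row with the endogeneity
p-value, and an MR-Egger (MR-E) row, plus supporting tables (per-SNP
single-instrument estimates, first-stage strength, Egger intercepts,
multivariable MR, bidirectional MR, funnel/scatter coordinates) and a
structured log.  Any cell that fails is recorded and the remaining cells
still run.  Identical configuration and seed yield a byte-identical bundle
on disk.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_io, egger, instruments, iv, mvmr
from .bidirectional import reverse_mr
from .data import SITES, Cohort
from .exceptions import BonemrError, InvalidConfigError
from .simulate import make_scenario, simulate_cohort

__all__ = ["AnalysisConfig", "ReportBundle", "run_analysis", "render_plots"]

TABLE2_COLUMNS = ("Trait", "Method", "beta", "CI-L", "CI-U", "P", "P_WH")

ALL_ESTIMATORS = ("OBS", "TSLS-single", "TSLS-score", "IVW", "MR-Egger",
                  "MVMR", "bidirectional")

#: Exposure label -> phenotype column.
EXPOSURE_COLUMNS = {"BMI": "bmi", "fat": "fat_mass"}


@dataclass
class AnalysisConfig:
    """Configuration for one full analysis run.

    Exactly one of ``scenario`` (simulate) or the three input paths (load)
    must be provided.
    """

    scenario: str | None = None
    n_individuals: int = 5221
    scenario_overrides: dict | None = None
    genotypes_path: str | None = None
    genotypes_format: str = "dosage_tsv"
    phenotypes_path: str | None = None
    manifest_path: str | None = None
    exposures: tuple[str, ...] = ("BMI", "fat")
    sites: tuple[str, ...] = SITES
    estimators: tuple[str, ...] = ALL_ESTIMATORS
    alpha: float = 0.05
    seed: int = 0
    drop_palindromic: bool = False

    def __post_init__(self) -> None:
        paths = (self.genotypes_path, self.phenotypes_path, self.manifest_path)
        has_paths = any(p is not None for p in paths)
        if (self.scenario is None) == (not has_paths):
            raise InvalidConfigError(
                "exactly one of a simulation scenario or input paths must be set")
        if has_paths and not all(p is not None for p in paths):
            raise InvalidConfigError(
                "genotypes_path, phenotypes_path and manifest_path are all required")
        unknown = set(self.estimators) - set(ALL_ESTIMATORS)
        if unknown:
            raise InvalidConfigError(f"unknown estimators: {sorted(unknown)}")
        bad = [e for e in self.exposures if e not in EXPOSURE_COLUMNS]
        if bad:
            raise InvalidConfigError(
                f"unknown exposures {bad}; valid: {sorted(EXPOSURE_COLUMNS)}")


@dataclass
class ReportBundle:
    """All outputs of one analysis run, writable as deterministic TSVs."""

    config: AnalysisConfig
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)
    n: int = 0

    def table2(self, exposure: str) -> pd.DataFrame:
        return self.tables[f"table2_{exposure}"]

    def write(self, out_dir) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name in sorted(self.tables):
            path = out / f"{name}.tsv"
            self.tables[name].to_csv(path, sep="\t", index=False,
                                     float_format="%.10g", na_rep="NA")
            written.append(path)
        log_path = out / "run_log.txt"
        log_path.write_text("".join(line + "\n" for line in self.log))
        written.append(log_path)
        return written


def _acquire_cohort(config: AnalysisConfig) -> Cohort:
    if config.scenario is not None:
        sim = make_scenario(config.scenario, n_individuals=config.n_individuals,
                            seed=config.seed, overrides=config.scenario_overrides)
        return simulate_cohort(sim)
    manifest = cohort_io.read_manifest(config.manifest_path)
    dosages = cohort_io.read_genotypes(
        config.genotypes_path, config.genotypes_format, manifest,
        drop_palindromic=config.drop_palindromic)
    phenotypes = cohort_io.read_phenotypes(config.phenotypes_path)
    return cohort_io.align_cohort(dosages, phenotypes, manifest=manifest)


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run every requested estimator over every exposure x site cell."""
    bundle = ReportBundle(config=config)
    log = bundle.log
    log.append(f"seed={config.seed} alpha={config.alpha}")
    cohort = _acquire_cohort(config)
    bundle.n = cohort.n
    log.append(f"cohort n={cohort.n} snps={len(cohort.snp_ids)}")
    if cohort.exclusions is not None:
        log.append(f"exclusions: {cohort.exclusions.summary()}")
    phen = cohort.phenotypes
    covariates = cohort.covariates()
    want = set(config.estimators)

    bmi_manifest = cohort.manifest.for_tag("BMI")
    bmi_snps = bmi_manifest.snp_ids
    score = None
    if want & {"TSLS-score", "MVMR"}:
        score = instruments.build_allelic_score(cohort.dosages, cohort.manifest,
                                                "BMI").to_numpy()

    first_rows: list[dict] = []
    per_snp_rows: list[dict] = []
    egger_rows: list[dict] = []
    funnel_rows: list[dict] = []
    scatter_rows: list[dict] = []

    for exposure in config.exposures:
        xcol = EXPOSURE_COLUMNS[exposure]
        x = phen[xcol].to_numpy(dtype=float)
        rows: list[dict] = []
        gamma_tab = None
        if want & {"IVW", "MR-Egger", "TSLS-single"}:
            gamma_tab = egger.snp_associations(
                x, cohort.dosages[bmi_snps], covariates, trait_name=exposure)
        if "TSLS-score" in want and score is not None:
            fs = instruments.first_stage(x, score, covariates,
                                         instrument_id="allelic_score",
                                         exposure_name=exposure)
            first_rows.append(dataclasses.asdict(fs))
        for site in config.sites:
            trait = f"{site}-BMD"
            y = phen[f"bmd_{site}"].to_numpy(dtype=float)

            def cell(method, fn):
                try:
                    fn()
                except (BonemrError, ValueError) as exc:
                    log.append(f"ERROR {exposure}/{trait}/{method}: {exc}")
                    rows.append({"Trait": trait, "Method": method,
                                 "beta": np.nan, "CI-L": np.nan, "CI-U": np.nan,
                                 "P": np.nan, "P_WH": np.nan})

            if "OBS" in want:
                def _obs():
                    est = iv.observational_ols(y, x, covariates,
                                               outcome_name=trait,
                                               exposure_name=exposure)
                    z = 1.959963984540054  # 95% normal quantile
                    rows.append({"Trait": trait, "Method": "OBS",
                                 "beta": est.beta, "CI-L": est.beta - z * est.se,
                                 "CI-U": est.beta + z * est.se, "P": est.p,
                                 "P_WH": np.nan})
                cell("OBS", _obs)
            if "TSLS-score" in want and score is not None:
                def _tsls():
                    est = iv.tsls(y, x, score, covariates, outcome_name=trait,
                                  exposure_name=exposure)
                    rows.append({"Trait": trait, "Method": "TSLS",
                                 "beta": est.beta_iv, "CI-L": est.ci_low,
                                 "CI-U": est.ci_high, "P": est.p,
                                 "P_WH": est.p_wh})
                cell("TSLS", _tsls)
            Gamma_tab = None
            if gamma_tab is not None and want & {"IVW", "MR-Egger", "TSLS-single"}:
                Gamma_tab = egger.snp_associations(
                    y, cohort.dosages[bmi_snps], covariates, trait_name=trait)
            if "MR-Egger" in want and Gamma_tab is not None:
                def _egger():
                    res = egger.egger_regression(gamma_tab, Gamma_tab,
                                                 exposure_name=exposure,
                                                 outcome_name=trait)
                    lo, hi = res.slope_ci
                    rows.append({"Trait": trait, "Method": "MR-E",
                                 "beta": res.slope_beta_iv, "CI-L": lo,
                                 "CI-U": hi, "P": res.slope_p, "P_WH": np.nan})
                    egger_rows.append({
                        "exposure": exposure, "Trait": trait,
                        "intercept": res.intercept_beta0,
                        "intercept_se": res.intercept_se,
                        "intercept_p": res.intercept_p, "n_snps": res.n_snps})
                    for r in res.per_snp_inputs.itertuples():
                        scatter_rows.append({
                            "exposure": exposure, "Trait": trait,
                            "snp_id": r.snp_id, "gamma": r.gamma,
                            "se_gamma": r.se_gamma, "Gamma": r.Gamma,
                            "se_Gamma": r.se_Gamma, "weight": r.weight})
                cell("MR-E", _egger)
            if "IVW" in want and Gamma_tab is not None:
                def _ivw():
                    est = iv.ivw(egger._merge_summaries(gamma_tab, Gamma_tab),
                                 exposure_name=exposure, outcome_name=trait)
                    per_snp_rows.append({
                        "exposure": exposure, "Trait": trait, "snp_id": "IVW",
                        "beta_iv": est.beta_iv, "ci_low": est.ci_low,
                        "ci_high": est.ci_high, "p": est.p})
                    for pt in egger.funnel_data(gamma_tab, Gamma_tab):
                        funnel_rows.append({
                            "exposure": exposure, "Trait": trait,
                            "snp_id": pt.snp_id, "strength": pt.strength,
                            "ratio_estimate": pt.ratio_estimate})
                cell("IVW", _ivw)
            if "TSLS-single" in want and Gamma_tab is not None:
                merged = egger._merge_summaries(gamma_tab, Gamma_tab)
                for r in merged.itertuples():
                    if r.gamma == 0:
                        continue
                    g = iv.AssociationEstimate(r.snp_id, exposure, r.gamma,
                                               r.se_gamma, 1.0, cohort.n)
                    G = iv.AssociationEstimate(r.snp_id, trait, r.Gamma,
                                               r.se_Gamma, 1.0, cohort.n)
                    import warnings as _w
                    with _w.catch_warnings():
                        _w.simplefilter("ignore")
                        est = iv.wald_ratio(g, G)
                    per_snp_rows.append({
                        "exposure": exposure, "Trait": trait, "snp_id": r.snp_id,
                        "beta_iv": est.beta_iv, "ci_low": est.ci_low,
                        "ci_high": est.ci_high, "p": est.p})
        bundle.tables[f"table2_{exposure}"] = pd.DataFrame(
            rows, columns=list(TABLE2_COLUMNS))

    if "TSLS-single" in want or "MVMR" in want:
        x_fat = phen["fat_mass"].to_numpy(dtype=float)
        x_lean = phen["lean_mass"].to_numpy(dtype=float)
        for snp in bmi_snps:
            g = cohort.dosages[snp].to_numpy(dtype=float)
            for name, xv in (("fat_mass", x_fat), ("lean_mass", x_lean)):
                try:
                    fs = instruments.first_stage(xv, g, covariates,
                                                 instrument_id=snp,
                                                 exposure_name=name)
                    first_rows.append(dataclasses.asdict(fs))
                except BonemrError as exc:
                    log.append(f"ERROR first_stage/{snp}/{name}: {exc}")

    if "MVMR" in want and score is not None:
        fs_objs = [instruments.FirstStageResult(**{k: v for k, v in r.items()})
                   for r in first_rows if r["instrument_id"] != "allelic_score"]
        mvmr_rows: list[dict] = []
        try:
            kept, audit = mvmr.select_strong_instruments(fs_objs)
            log.append(f"MVMR strong instruments (F>=10): {kept}")
            Zsel = cohort.dosages[kept].to_numpy(dtype=float)
            expo = phen[["fat_mass", "lean_mass"]]
            for site in config.sites:
                trait = f"{site}-BMD"
                try:
                    res = mvmr.mvmr_tsls(
                        phen[f"bmd_{site}"].to_numpy(dtype=float), expo, Zsel,
                        covariates, outcome_name=trait,
                        instrument_ids=tuple(kept))
                    for r in res.exposures.itertuples():
                        mvmr_rows.append({
                            "Trait": trait, "exposure": r.exposure,
                            "beta_iv": r.beta_iv, "ci_low": r.ci_low,
                            "ci_high": r.ci_high, "p": r.p,
                            "conditional_F": res.conditional_f[r.exposure]})
                except (BonemrError, ValueError) as exc:
                    log.append(f"ERROR MVMR/{trait}: {exc}")
        except BonemrError as exc:
            log.append(f"ERROR MVMR selection: {exc}")
        bundle.tables["mvmr"] = pd.DataFrame(
            mvmr_rows, columns=["Trait", "exposure", "beta_iv", "ci_low",
                                "ci_high", "p", "conditional_F"])

    if "bidirectional" in want:
        bidir_rows: list[dict] = []
        tags = [t for t in ("FN-BMD", "LS-BMD")
                if t in set(cohort.manifest.table["trait_tag"])]
        if not tags:
            log.append("bidirectional: no BMD-tagged instruments in manifest; skipped")
        for tag in tags:
            for site in config.sites:
                for outcome in ("BMI", "fat"):
                    try:
                        est = reverse_mr(cohort, site, tag, outcome)
                        bidir_rows.append({
                            "score": tag, "bmd_site": site, "outcome": outcome,
                            "beta_iv": est.beta_iv, "ci_low": est.ci_low,
                            "ci_high": est.ci_high, "p": est.p,
                            "f_first": est.f_first})
                    except (BonemrError, ValueError) as exc:
                        log.append(f"ERROR bidirectional/{tag}/{site}/{outcome}: "
                                   f"{exc}")
        bundle.tables["bidirectional"] = pd.DataFrame(
            bidir_rows, columns=["score", "bmd_site", "outcome", "beta_iv",
                                 "ci_low", "ci_high", "p", "f_first"])

    bundle.tables["first_stage"] = pd.DataFrame(
        first_rows, columns=["instrument_id", "exposure_name", "beta", "se",
                             "p", "F_first", "r_squared", "n", "weak",
                             "threshold"])
    bundle.tables["per_snp_iv"] = pd.DataFrame(
        per_snp_rows, columns=["exposure", "Trait", "snp_id", "beta_iv",
                               "ci_low", "ci_high", "p"])
    bundle.tables["egger_intercepts"] = pd.DataFrame(
        egger_rows, columns=["exposure", "Trait", "intercept", "intercept_se",
                             "intercept_p", "n_snps"])
    bundle.tables["funnel_data"] = pd.DataFrame(
        funnel_rows, columns=["exposure", "Trait", "snp_id", "strength",
                              "ratio_estimate"])
    bundle.tables["scatter_data"] = pd.DataFrame(
        scatter_rows, columns=["exposure", "Trait", "snp_id", "gamma",
                               "se_gamma", "Gamma", "se_Gamma", "weight"])
    log.append("done")
    return bundle


def render_plots(bundle: ReportBundle, out_dir) -> list[Path]:
    """Render funnel and scatter figures from a report bundle.

    One multi-panel figure per exposure and plot family.  The underlying
    data tables are part of the bundle regardless, so a headless or
    render-disabled environment loses nothing but the images.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scatter = bundle.tables.get("scatter_data", pd.DataFrame())
    funnel = bundle.tables.get("funnel_data", pd.DataFrame())
    if scatter.empty:
        raise BonemrError("render_plots requires the MR-Egger stage to have run")
    written = []
    for exposure in bundle.config.exposures:
        sc = scatter[scatter["exposure"] == exposure]
        traits = sorted(sc["Trait"].unique())
        fig, axes = plt.subplots(1, max(len(traits), 1),
                                 figsize=(3.2 * max(len(traits), 1), 3.2),
                                 squeeze=False)
        for ax, trait in zip(axes[0], traits):
            sub = sc[sc["Trait"] == trait]
            g, G, w = (sub["gamma"].to_numpy(), sub["Gamma"].to_numpy(),
                       sub["weight"].to_numpy())
            ax.errorbar(g, G, yerr=sub["se_Gamma"], fmt="o", ms=3, lw=0.8,
                        alpha=0.7)
            # refit the two lines from the stored per-SNP inputs
            Xe = np.column_stack([np.ones_like(g), g])
            b0, b1 = np.linalg.solve((Xe * w[:, None]).T @ Xe, (Xe * w[:, None]).T @ G)
            b_ivw = float((w * g * G).sum() / (w * g * g).sum())
            xs = np.linspace(0, g.max() * 1.05, 50)
            ax.plot(xs, b0 + b1 * xs, color="tab:blue", label="MR-Egger")
            ax.plot(xs, b_ivw * xs, color="tab:red", label="IVW")
            ax.set_title(f"{exposure} vs {trait}", fontsize=9)
            ax.set_xlabel("SNP-exposure slope")
        axes[0][0].set_ylabel("SNP-outcome slope")
        axes[0][-1].legend(fontsize=7)
        fig.tight_layout()
        path = out / f"scatter_{exposure}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

        fu = funnel[funnel["exposure"] == exposure]
        if not fu.empty:
            fig, axes = plt.subplots(1, max(len(traits), 1),
                                     figsize=(3.2 * max(len(traits), 1), 3.2),
                                     squeeze=False)
            for ax, trait in zip(axes[0], traits):
                sub = fu[fu["Trait"] == trait]
                ax.plot(sub["ratio_estimate"], sub["strength"], "o", ms=3,
                        alpha=0.7)
                ax.set_title(f"{exposure} vs {trait}", fontsize=9)
                ax.set_xlabel("per-SNP IV estimate")
            axes[0][0].set_ylabel("MAF-standardized strength")
            fig.tight_layout()
            path = out / f"funnel_{exposure}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    return written
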