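"""MR-Egger regression and summary-level diagnostics.

The Egger procedure works entirely on per-SNP summary associations computed
inside the sample: univariate age/sex-adjusted regressions of the exposure on
each SNP (slopes ``gamma``) and of the outcome on each SNP (slopes
``Gamma``).  A weighted linear regression of ``Gamma`` on ``gamma`` *with an
intercept* then separates the causal slope from directional pleiotropy: under
the InSIDE assumption (instrument strength independent of direct effects) the
slope is a consistent causal estimate even when every instrument is
pleiotropic, and the intercept estimates the average direct effect of the
instruments on the outcome.  Testing the intercept against zero is the
directional-pleiotropy test; funnel plots of MAF-standardized instrument
strength against per-SNP ratio estimates give the visual counterpart.

Orientation matters: each SNP is flipped so its exposure association is
non-negative before fitting (flipping both coordinates together), otherwise
the intercept is not identified.  A flag disables this for sensitivity runs.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._lm import add_constant, residualize, standardize, wls
from .exceptions import InsufficientInstrumentsError
from .results import EggerResult, FunnelPoint

logger = logging.getLogger("bonemr")

__all__ = ["snp_associations", "egger_regression", "funnel_data"]


def snp_associations(trait, dosages: pd.DataFrame, covariates=None, *,
                     trait_name: str = "trait",
                     standardize_trait: bool = True) -> pd.DataFrame:
    """Univariate adjusted regression of a trait on each SNP separately.

    The trait is standardized to SD units (so slopes are SD per effect-allele
    copy); each SNP enters its own regression together with the covariates.
    Monomorphic SNPs are dropped with a logged warning.  Returns a frame with
    columns ``snp_id, beta, se, p, n, maf``.

    Implemented by Frisch-Waugh-Lovell residualization so that all SNPs share
    one covariate projection; numerically identical to per-SNP OLS.
    """
    y = np.asarray(trait, dtype=float)
    if standardize_trait:
        y = standardize(y, trait_name)
    G = dosages.to_numpy(dtype=float)
    n = len(y)
    keep = G.std(axis=0) > 0
    if not keep.all():
        dropped = [s for s, k in zip(dosages.columns, keep) if not k]
        logger.warning("dropping monomorphic SNPs: %s", dropped)
        G = G[:, keep]
    snp_ids = [s for s, k in zip(dosages.columns, keep) if k]
    W = add_constant(np.asarray(covariates, dtype=float)) if covariates is not None \
        else add_constant(n=n)
    y_r = residualize(y, W)[:, 0]
    G_r = residualize(G, W)
    gss = np.einsum("ij,ij->j", G_r, G_r)
    beta = (G_r.T @ y_r) / gss
    df = n - W.shape[1] - 1
    rss = float(y_r @ y_r) - beta ** 2 * gss
    se = np.sqrt(rss / df / gss)
    p = 2 * stats.t.sf(np.abs(beta / se), df)
    return pd.DataFrame({
        "snp_id": snp_ids, "beta": beta, "se": se, "p": p, "n": n,
        "maf": G.mean(axis=0) / 2.0, "trait": trait_name,
    })


def _merge_summaries(gamma_table: pd.DataFrame,
                     Gamma_table: pd.DataFrame) -> pd.DataFrame:
    g = gamma_table.rename(columns={"beta": "gamma", "se": "se_gamma"})
    G = Gamma_table.rename(columns={"beta": "Gamma", "se": "se_Gamma"})
    merged = pd.merge(g[["snp_id", "gamma", "se_gamma"]
                        + (["maf"] if "maf" in g.columns else [])],
                      G[["snp_id", "Gamma", "se_Gamma"]],
                      on="snp_id", how="inner")
    if len(merged) < min(len(g), len(G)):
        raise InsufficientInstrumentsError(
            "gamma and Gamma tables do not share all snp_ids")
    return merged


def egger_regression(gamma_table: pd.DataFrame, Gamma_table: pd.DataFrame, *,
                     orient: bool = True, weights: str = "inverse_variance",
                     ci_level: float = 0.95,
                     exposure_name: str = "exposure",
                     outcome_name: str = "outcome") -> EggerResult:
    """Weighted regression of outcome slopes on exposure slopes, with intercept.

    ``weights='inverse_variance'`` (default) uses ``1/se(Gamma)^2``, the
    standard Egger weighting; ``'literal_se'`` uses ``1/se(Gamma)`` for
    sensitivity to the alternative reading of SE-weighting.  Inference uses
    the estimated residual scale with ``n_snps - 2`` degrees of freedom.
    """
    tab = _merge_summaries(gamma_table, Gamma_table)
    m = len(tab)
    if m < 3:
        raise InsufficientInstrumentsError(
            f"Egger regression needs >= 3 SNPs, got {m}")
    if orient:
        flip = np.sign(tab["gamma"].to_numpy())
        flip[flip == 0] = 1.0
        tab["gamma"] = tab["gamma"] * flip
        tab["Gamma"] = tab["Gamma"] * flip
    if weights == "inverse_variance":
        w = 1.0 / tab["se_Gamma"].to_numpy() ** 2
    elif weights == "literal_se":
        w = 1.0 / tab["se_Gamma"].to_numpy()
    else:
        raise ValueError("weights must be 'inverse_variance' or 'literal_se'")
    tab = tab.assign(weight=w)
    X = add_constant(tab["gamma"].to_numpy())
    fit = wls(tab["Gamma"].to_numpy(), X, w)
    (b0, b1), (se0, se1) = fit.beta, fit.se
    p0, p1 = fit.t_pvalues()
    return EggerResult(
        exposure_name=exposure_name, outcome_name=outcome_name,
        slope_beta_iv=float(b1), slope_se=float(se1), slope_p=float(p1),
        intercept_beta0=float(b0), intercept_se=float(se0), intercept_p=float(p0),
        n_snps=m, per_snp_inputs=tab, ci_level=ci_level)


def funnel_data(gamma_table: pd.DataFrame, Gamma_table: pd.DataFrame,
                mafs=None) -> list[FunnelPoint]:
    """Per-SNP funnel-plot coordinates.

    Strength is the MAF-standardized instrument-exposure association
    ``|gamma| * sqrt(2 maf (1 - maf))`` (per-allele slope rescaled to per SD
    of genotype); the ratio estimate is the per-SNP Wald ratio.  ``mafs`` may
    be a mapping/Series keyed by snp_id; otherwise the ``maf`` column of the
    gamma table is used.  SNPs with a zero exposure association have no
    defined ratio and are omitted.
    """
    tab = _merge_summaries(gamma_table, Gamma_table)
    if mafs is not None:
        maf = pd.Series(dict(mafs) if not isinstance(mafs, pd.Series) else mafs)
        tab["maf"] = tab["snp_id"].map(maf)
    if "maf" not in tab.columns or tab["maf"].isna().any():
        missing = (tab.loc[tab["maf"].isna(), "snp_id"].tolist()
                   if "maf" in tab.columns else tab["snp_id"].tolist())
        raise ValueError(f"MAF unavailable for SNPs: {missing}")
    points = []
    for row in tab.itertuples():
        if row.gamma == 0:
            continue
        strength = abs(row.gamma) * np.sqrt(2 * row.maf * (1 - row.maf))
        points.append(FunnelPoint(snp_id=row.snp_id, strength=float(strength),
                                  ratio_estimate=float(row.Gamma / row.gamma)))
    return points
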