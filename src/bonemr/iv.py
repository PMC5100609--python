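"""Observational and instrumental-variable effect estimation.

Implements the estimator family used throughout the analysis:

* :func:`observational_ols` — age/sex-adjusted OLS in SD-per-SD units;
* :func:`wald_ratio` — single-instrument ratio estimate with a first-order
  delta-method standard error;
* :func:`tsls` — two-stage least squares with covariates in both stages and
  the classical 2SLS covariance computed against the *original* (not
  projected) exposures;
* :func:`durbin_wu_hausman` — the Durbin score form of the endogeneity test
  (first-stage residuals added to the outcome regression, n R-squared-type
  statistic against chi-squared);
* :func:`ivw` — inverse-variance-weighted combination of per-SNP summary
  associations, i.e. a through-origin weighted regression of the
  instrument-outcome slopes on the instrument-exposure slopes.

Exposures and outcomes are standardized to zero mean and unit SD on the
analysis sample before fitting, so every reported effect is an SD change in
outcome per SD change in exposure; covariates enter unstandardized.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._lm import add_constant, ols, partial_f, residualize, standardize, wls
from .exceptions import (
    DegenerateDataError,
    IdentificationError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .results import AssociationEstimate, IVEstimate

__all__ = ["observational_ols", "wald_ratio", "tsls", "durbin_wu_hausman", "ivw"]


def _as_matrix(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def _covariate_block(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    W = _as_matrix(covariates)
    if W.shape[0] != n:
        raise ValueError("covariate rows do not match outcome length")
    return W


def observational_ols(outcome, exposure, covariates=None, *,
                      outcome_name: str = "outcome",
                      exposure_name: str = "exposure",
                      adjusted_for: tuple[str, ...] = ("age", "sex"),
                      standardize_variables: bool = True) -> AssociationEstimate:
    """Adjusted OLS association between one exposure and one outcome.

    With ``standardize_variables`` (the default) both variables are scaled to
    unit SD first, so ``beta`` is SD-per-SD.  Set it to ``False`` to obtain
    per-unit slopes (used for per-allele SNP associations).
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if standardize_variables:
        y = standardize(y, outcome_name)
        x = standardize(x, exposure_name)
    elif x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise DegenerateDataError("zero-variance exposure or outcome")
    W = _covariate_block(covariates, len(y))
    X = add_constant(x, W) if W.shape[1] else add_constant(x)
    fit = ols(y, X)
    return AssociationEstimate(
        predictor_id=exposure_name, trait_name=outcome_name,
        beta=float(fit.beta[1]), se=float(fit.se[1]),
        p=float(fit.t_pvalues()[1]), n=len(y),
        adjusted_for=tuple(adjusted_for) if covariates is not None else ())


def wald_ratio(gamma: AssociationEstimate, Gamma: AssociationEstimate, *,
               ci_level: float = 0.95) -> IVEstimate:
    """Ratio estimator: instrument-outcome over instrument-exposure slope.

    The standard error is first-order delta method using both slopes' SEs and
    no covariance term:  se^2 = se(G)^2/g^2 + G^2 se(g)^2 / g^4.
    """
    g, G = gamma.beta, Gamma.beta
    if g == 0:
        raise UndefinedRatioError("instrument-exposure association is zero")
    notes: list[str] = []
    if abs(g / gamma.se) < 1:
        notes.append("weak denominator: |gamma/se| < 1, ratio unstable")
        warnings.warn(notes[-1], stacklevel=2)
    beta = G / g
    se = np.sqrt(Gamma.se ** 2 / g ** 2 + G ** 2 * gamma.se ** 2 / g ** 4)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    p = 2 * stats.norm.sf(abs(beta / se))
    return IVEstimate(
        exposure_name=gamma.trait_name, outcome_name=Gamma.trait_name,
        beta_iv=float(beta), se=float(se),
        ci_low=float(beta - z * se), ci_high=float(beta + z * se),
        p=float(p), estimator_tag="wald", n=min(gamma.n, Gamma.n),
        ci_level=ci_level, warnings=tuple(notes))


@dataclass
class _TSLSCore:
    """Internal multi-exposure 2SLS fit shared by tsls() and mvmr."""

    beta: np.ndarray        # per-exposure coefficients
    se: np.ndarray
    df_resid: int
    n: int
    f_first: np.ndarray     # per-exposure partial F of the instrument block

    def p_values(self) -> np.ndarray:
        return 2 * stats.t.sf(np.abs(self.beta / self.se), self.df_resid)

    def ci(self, level: float) -> tuple[np.ndarray, np.ndarray]:
        t = stats.t.ppf(0.5 + level / 2, self.df_resid)
        return self.beta - t * self.se, self.beta + t * self.se


def _tsls_core(y: np.ndarray, X: np.ndarray, Z: np.ndarray,
               W: np.ndarray) -> _TSLSCore:
    n, k = X.shape
    if Z.shape[1] < k:
        raise IdentificationError(
            f"{Z.shape[1]} instruments cannot identify {k} exposures")
    exog_iv = add_constant(W, Z) if W.shape[1] else add_constant(Z)
    # first stage: project each exposure on instruments + covariates
    Q, R = np.linalg.qr(exog_iv)
    diag = np.abs(np.diag(R))
    if diag.min() <= 1e-10 * max(diag.max(), 1.0):
        raise IdentificationError("collinear instruments (rank-deficient first stage)")
    Xhat = Q @ (Q.T @ X)
    exog2 = add_constant(W, Xhat) if W.shape[1] else add_constant(Xhat)
    fit2 = ols(y, exog2)
    beta_all = fit2.beta
    # classical 2SLS variance: residuals against the ORIGINAL exposures
    exog_orig = add_constant(W, X) if W.shape[1] else add_constant(X)
    resid = y - exog_orig @ beta_all
    df = n - exog2.shape[1]
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(exog2.T @ exog2)
    cov = sigma2 * XtX_inv
    sl = slice(1 + W.shape[1], 1 + W.shape[1] + k)
    X_red = add_constant(W) if W.shape[1] else add_constant(n=n)
    f_first = np.array([partial_f(X[:, j], exog_iv, X_red)[0] for j in range(k)])
    return _TSLSCore(beta=beta_all[sl], se=np.sqrt(np.diag(cov)[sl]),
                     df_resid=df, n=n, f_first=f_first)


def tsls(outcome, exposures, instruments, covariates=None, *,
         outcome_name: str = "outcome", exposure_name: str = "exposure",
         ci_level: float = 0.95, standardize_variables: bool = True,
         compute_dwh: bool = True, weak_threshold: float = 10.0) -> IVEstimate:
    """Two-stage least squares for a single exposure.

    Covariates are included in both stages.  The Durbin-Wu-Hausman
    endogeneity p-value (``p_wh``) and the first-stage partial F of the
    instrument block (``f_first``) are attached to the estimate.
    """
    y = np.asarray(outcome, dtype=float)
    X = _as_matrix(exposures)
    if X.shape[1] != 1:
        raise ValueError("tsls() takes one exposure; use bonemr.mvmr for several")
    Z = _as_matrix(instruments)
    W = _covariate_block(covariates, len(y))
    if standardize_variables:
        y = standardize(y, outcome_name)
        X = np.column_stack([standardize(X[:, 0], exposure_name)])
    core = _tsls_core(y, X, Z, W)
    lo, hi = core.ci(ci_level)
    p_wh = None
    if compute_dwh:
        _, p_wh = durbin_wu_hausman(y, X, Z, covariates)
    return IVEstimate(
        exposure_name=exposure_name, outcome_name=outcome_name,
        beta_iv=float(core.beta[0]), se=float(core.se[0]),
        ci_low=float(lo[0]), ci_high=float(hi[0]),
        p=float(core.p_values()[0]), estimator_tag="tsls", n=core.n,
        p_wh=p_wh, f_first=float(core.f_first[0]),
        weak_instrument=bool(core.f_first[0] < weak_threshold),
        ci_level=ci_level)


def durbin_wu_hausman(outcome, exposures, instruments,
                      covariates=None) -> tuple[float, float]:
    """Durbin score form of the endogeneity test.

    First-stage residuals of the exposures on instruments + covariates are
    added to the outcome OLS; the statistic is the n R-squared-type score
    statistic for that residual block, referred to chi-squared with one
    degree of freedom per exposure.  Returns ``(statistic, p_wh)``.
    """
    y = np.asarray(outcome, dtype=float)
    X = _as_matrix(exposures)
    Z = _as_matrix(instruments)
    W = _covariate_block(covariates, len(y))
    n = len(y)
    exog_iv = add_constant(W, Z) if W.shape[1] else add_constant(Z)
    V = residualize(X, exog_iv)
    # a perfect instrument leaves no first-stage residual variation: the
    # score statistic is identically zero (IV and OLS coincide)
    keep = V.std(axis=0) > 1e-12 * max(X.std(axis=0).max(), 1.0)
    if not keep.any():
        return 0.0, 1.0
    V = V[:, keep]
    exog0 = add_constant(W, X) if W.shape[1] else add_constant(X)
    fit0 = ols(y, exog0)
    fit1 = ols(y, np.column_stack([exog0, V]))
    stat = n * (fit0.rss - fit1.rss) / fit0.rss
    stat = max(float(stat), 0.0)
    p = float(stats.chi2.sf(stat, X.shape[1]))
    return stat, p


def _pairs_to_frame(per_snp) -> pd.DataFrame:
    """Normalise IVW/Egger input to a (gamma, se_gamma, Gamma, se_Gamma) frame."""
    if isinstance(per_snp, pd.DataFrame):
        required = {"gamma", "se_gamma", "Gamma", "se_Gamma"}
        missing = required - set(per_snp.columns)
        if missing:
            raise ValueError(f"summary frame missing columns {sorted(missing)}")
        return per_snp.copy()
    rows = []
    for gamma, Gamma in per_snp:
        rows.append({"snp_id": gamma.predictor_id,
                     "gamma": gamma.beta, "se_gamma": gamma.se,
                     "Gamma": Gamma.beta, "se_Gamma": Gamma.se,
                     "n": min(gamma.n, Gamma.n)})
    return pd.DataFrame(rows)


def ivw(per_snp, *, ci_level: float = 0.95,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome") -> IVEstimate:
    """Inverse-variance-weighted causal estimate from per-SNP summaries.

    The slope of the through-origin weighted regression of the
    instrument-outcome slopes on the instrument-exposure slopes, with weights
    ``1 / se(Gamma)^2``; equals the precision-weighted mean of the per-SNP
    Wald ratios.  The standard error uses the estimated residual scale
    (multiplicative random-effects convention) with ``m - 1`` degrees of
    freedom.
    """
    tab = _pairs_to_frame(per_snp)
    m = len(tab)
    if m == 0:
        raise InsufficientInstrumentsError("no SNPs supplied to ivw()")
    if m == 1:
        warnings.warn("ivw() with a single SNP degenerates to the Wald ratio",
                      stacklevel=2)
        row = tab.iloc[0]
        n = int(row.get("n", 0) or 0)
        gamma = AssociationEstimate(str(row.get("snp_id", "snp")), exposure_name,
                                    row["gamma"], row["se_gamma"], 1.0, n)
        Gamma = AssociationEstimate(str(row.get("snp_id", "snp")), outcome_name,
                                    row["Gamma"], row["se_Gamma"], 1.0, n)
        est = wald_ratio(gamma, Gamma, ci_level=ci_level)
        est.estimator_tag = "ivw"
        return est
    w = 1.0 / tab["se_Gamma"].to_numpy() ** 2
    g = tab["gamma"].to_numpy()
    G = tab["Gamma"].to_numpy()
    fit = wls(G, g[:, None], w)
    beta, se = float(fit.beta[0]), float(fit.se[0])
    tcrit = stats.t.ppf(0.5 + ci_level / 2, fit.df_resid)
    # exactly proportional summaries leave zero residual scale
    p = 0.0 if se == 0 else 2 * stats.t.sf(abs(beta / se), fit.df_resid)
    n = int(tab["n"].max()) if "n" in tab.columns and tab["n"].notna().all() else 0
    return IVEstimate(
        exposure_name=exposure_name, outcome_name=outcome_name,
        beta_iv=beta, se=se, ci_low=beta - tcrit * se, ci_high=beta + tcrit * se,
        p=float(p), estimator_tag="ivw", n=n, ci_level=ci_level)
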