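"""Allelic-score construction and instrument-strength diagnostics.

The composite instrument is an *unweighted* allelic score: the per-individual
count of trait-increasing alleles across the SNPs proxying one trait.
Instrument strength is summarised by the first-stage partial F statistic of
the instrument block given the age and sex covariates; F < 10 is the
conventional weak-instrument warning threshold.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from ._lm import add_constant, ols, partial_f
from .data import InstrumentManifest
from .exceptions import DegenerateDataError, InsufficientInstrumentsError
from .results import FirstStageResult

__all__ = ["build_allelic_score", "first_stage", "WEAK_F_THRESHOLD"]

WEAK_F_THRESHOLD = 10.0


def build_allelic_score(dosages: pd.DataFrame, manifest: InstrumentManifest,
                        trait_tag: str) -> pd.Series:
    """Unweighted allelic score for one trait: sum of effect-allele dosages.

    ``dosages`` must already be oriented to the manifest's effect alleles
    (the contract of :func:`bonemr.cohort_io.read_genotypes` and of simulated
    cohorts).  SNPs whose ``published_effect`` is negative are counted on the
    opposite allele (``2 - dosage``) so the score counts trait-increasing
    alleles throughout.
    """
    sub = manifest.for_tag(trait_tag)
    if len(sub) == 0:
        raise InsufficientInstrumentsError(
            f"no manifest SNPs carry trait_tag {trait_tag!r}")
    missing = [s for s in sub.snp_ids if s not in dosages.columns]
    if missing:
        raise InsufficientInstrumentsError(
            f"manifest SNPs absent from dosage matrix: {missing}")
    block = dosages.loc[:, sub.snp_ids].to_numpy(dtype=float)
    if "published_effect" in sub.table.columns:
        signs = np.sign(sub.table["published_effect"].fillna(1.0).to_numpy())
        flip = signs < 0
        block = np.where(flip[None, :], 2.0 - block, block)
    score = pd.Series(block.sum(axis=1), index=dosages.index,
                      name=f"score_{trait_tag}")
    return score


def first_stage(exposure, instrument, covariates=None, *,
                instrument_id: str = "instrument",
                exposure_name: str = "exposure",
                weak_threshold: float = WEAK_F_THRESHOLD) -> FirstStageResult:
    """First-stage regression of an exposure on an instrument block.

    ``instrument`` may be one column (a SNP or an allelic score) or a matrix
    of columns; ``F_first`` is the partial F of the whole block given the
    covariates, which for a single instrument equals the squared t statistic
    of its coefficient.
    """
    y = np.asarray(exposure, dtype=float)
    Z = np.asarray(instrument, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if np.allclose(Z.std(axis=0), 0):
        raise DegenerateDataError("constant (zero-variance) instrument")
    W = (np.empty((len(y), 0)) if covariates is None
         else np.atleast_2d(np.asarray(covariates, dtype=float)))
    if W.ndim == 1:
        W = W[:, None]
    X_red = add_constant(W) if W.shape[1] else add_constant(n=len(y))
    X_full = np.column_stack([X_red, Z])
    F, p_f, inc_r2 = partial_f(y, X_full, X_red)
    fit = ols(y, X_full)
    j = X_red.shape[1]  # first instrument column in the full design
    beta, se = float(fit.beta[j]), float(fit.se[j])
    p = fit.t_pvalues()[j] if Z.shape[1] == 1 else p_f
    return FirstStageResult(
        instrument_id=instrument_id, exposure_name=exposure_name,
        beta=beta, se=se, p=float(p), F_first=float(F),
        r_squared=float(inc_r2), n=len(y),
        weak=bool(F < weak_threshold), threshold=weak_threshold)
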