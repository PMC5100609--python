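"""Reverse-direction MR: does bone density causally affect adiposity?

Bidirectional MR re-runs the instrumental-variable analysis with the causal
arrow reversed: an allelic score of BMD-associated SNPs (femoral-neck or
lumbar-spine discovery panels) instruments site-specific BMD, with BMI or
total fat mass as the outcome.  Because adiposity measures are right-skewed,
the outcome is log-transformed to approximate normality and then
standardized; the log base is immaterial after standardization.
"""
from __future__ import annotations

import numpy as np

from .data import SITES, Cohort
from .exceptions import TransformError
from .instruments import build_allelic_score
from .iv import tsls
from .results import IVEstimate

__all__ = ["reverse_mr"]

_OUTCOME_COLUMNS = {"BMI": "bmi", "fat": "fat_mass"}


def reverse_mr(cohort: Cohort, bmd_site: str, bmd_score_tag: str = "FN-BMD",
               outcome: str = "fat", *, ci_level: float = 0.95) -> IVEstimate:
    """Estimate the causal effect of one site's BMD on BMI or fat mass.

    ``bmd_score_tag`` selects which BMD allelic score (``FN-BMD`` or
    ``LS-BMD`` manifest tag) instruments the exposure; FN and LS scores are
    intended as separate runs.  The outcome must be strictly positive for the
    log transform.
    """
    if bmd_site not in SITES:
        raise ValueError(f"unknown BMD site {bmd_site!r}; sites are {SITES}")
    if outcome not in _OUTCOME_COLUMNS:
        raise ValueError(f"outcome must be one of {sorted(_OUTCOME_COLUMNS)}")
    phen = cohort.phenotypes
    y_raw = phen[_OUTCOME_COLUMNS[outcome]].to_numpy(dtype=float)
    bad = y_raw <= 0
    if bad.any():
        ids = phen.index[bad].tolist()
        raise TransformError(
            f"log transform undefined for non-positive {outcome} values in "
            f"individuals {ids[:10]}{'...' if len(ids) > 10 else ''}")
    y = np.log(y_raw)
    score = build_allelic_score(cohort.dosages, cohort.manifest, bmd_score_tag)
    est = tsls(
        y, phen[f"bmd_{bmd_site}"].to_numpy(dtype=float),
        score.to_numpy(), cohort.covariates(),
        outcome_name=f"log_{outcome}", exposure_name=f"bmd_{bmd_site}",
        ci_level=ci_level)
    est.estimator_tag = "tsls"
    return est
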