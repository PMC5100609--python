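"""Multivariable MR: direct effects of fat and lean mass estimated jointly.

Multivariable two-stage least squares regresses several exposures on the
genetic instruments in a multivariate first stage, then regresses the outcome
on all the first-stage predictions at once.  With instruments that affect
both exposures, the per-exposure coefficients are *direct* effects — the fat
coefficient holds lean mass fixed — which is what separates a mediated from
a genuinely independent adiposity effect on bone.

Because multivariable MR is especially prone to weak-instrument bias, the
module also provides the strong-instrument selection rule used in practice
(keep SNPs whose best first-stage F across the exposures clears a threshold,
10 by convention) and reports Sanderson-Windmeijer-style conditional F
statistics as an advisory diagnostic of per-exposure conditional strength.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._lm import add_constant, partial_f
from .iv import _as_matrix, _covariate_block, _tsls_core
from ._lm import standardize
from .exceptions import InsufficientInstrumentsError
from .results import FirstStageResult, MVMRResult

__all__ = ["mvmr_tsls", "select_strong_instruments", "conditional_f_stats"]


def conditional_f_stats(X: np.ndarray, Z: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Sanderson-Windmeijer conditional instrument-strength F per exposure.

    For exposure ``j``: regress ``x_j`` on the *other* exposures by 2SLS
    (instrumented by ``Z``), then take the partial F of ``Z`` for the
    residual, rescaled by ``kz / (kz - (k - 1))`` degrees of freedom.  With a
    single exposure this reduces to the ordinary partial F.
    """
    n, k = X.shape
    kz = Z.shape[1]
    exog_iv = add_constant(W, Z) if W.shape[1] else add_constant(Z)
    X_red = add_constant(W) if W.shape[1] else add_constant(n=n)
    out = np.empty(k)
    for j in range(k):
        if k == 1:
            out[j] = partial_f(X[:, 0], exog_iv, X_red)[0]
            continue
        others = np.delete(X, j, axis=1)
        core = _tsls_core(X[:, j], others, Z, W)
        resid = X[:, j] - others @ core.beta
        F, _, _ = partial_f(resid, exog_iv, X_red)
        out[j] = F * kz / (kz - (k - 1))
    return out


def mvmr_tsls(outcome, exposures, instruments, covariates=None, *,
              exposure_names: tuple[str, ...] | None = None,
              outcome_name: str = "outcome",
              instrument_ids: tuple[str, ...] | None = None,
              ci_level: float = 0.95,
              standardize_variables: bool = True) -> MVMRResult:
    """Multi-exposure two-stage least squares.

    ``exposures`` may be a DataFrame (column names become exposure names) or
    an (n, k) array.  Requires at least as many instruments as exposures;
    standard errors come from the 2SLS covariance computed against the
    original exposures, not naive second-stage OLS.
    """
    if isinstance(exposures, pd.DataFrame):
        if exposure_names is None:
            exposure_names = tuple(exposures.columns)
        X = exposures.to_numpy(dtype=float)
    else:
        X = _as_matrix(exposures)
        if exposure_names is None:
            exposure_names = tuple(f"exposure_{j}" for j in range(X.shape[1]))
    if isinstance(instruments, pd.DataFrame):
        if instrument_ids is None:
            instrument_ids = tuple(instruments.columns)
        Z = instruments.to_numpy(dtype=float)
    else:
        Z = _as_matrix(instruments)
        if instrument_ids is None:
            instrument_ids = tuple(f"iv_{j}" for j in range(Z.shape[1]))
    y = np.asarray(outcome, dtype=float)
    W = _covariate_block(covariates, len(y))
    if standardize_variables:
        y = standardize(y, outcome_name)
        X = np.column_stack([standardize(X[:, j], exposure_names[j])
                             for j in range(X.shape[1])])
    core = _tsls_core(y, X, Z, W)
    lo, hi = core.ci(ci_level)
    table = pd.DataFrame({
        "exposure": list(exposure_names),
        "beta_iv": core.beta, "se": core.se,
        "ci_low": lo, "ci_high": hi, "p": core.p_values(),
        "f_first": core.f_first,
    })
    cond = conditional_f_stats(X, Z, W)
    return MVMRResult(
        outcome_name=outcome_name, exposures=table,
        instrument_ids=tuple(instrument_ids),
        conditional_f={name: float(f) for name, f in zip(exposure_names, cond)},
        n=core.n, ci_level=ci_level)


def select_strong_instruments(first_stage_results, threshold: float = 10.0
                              ) -> tuple[list[str], pd.DataFrame]:
    """Keep instruments whose best first-stage F across exposures clears ``threshold``.

    ``first_stage_results`` is an iterable of
    :class:`~bonemr.results.FirstStageResult` covering every candidate
    against every exposure.  Returns ``(kept_ids, audit)`` where the audit
    frame records each candidate's best F and the decision.
    """
    rows = []
    for r in first_stage_results:
        if not isinstance(r, FirstStageResult):
            raise TypeError("expected FirstStageResult entries")
        rows.append({"instrument_id": r.instrument_id,
                     "exposure": r.exposure_name, "F_first": r.F_first})
    if not rows:
        raise InsufficientInstrumentsError("no first-stage results supplied")
    frame = pd.DataFrame(rows)
    best = frame.groupby("instrument_id", sort=False)["F_first"].max()
    audit = best.rename("best_F").to_frame()
    audit["kept"] = audit["best_F"] >= threshold
    kept = audit.index[audit["kept"]].tolist()
    if not kept:
        raise InsufficientInstrumentsError(
            f"no instrument reaches F >= {threshold}; lower the threshold or "
            "strengthen the instrument set")
    return kept, audit.reset_index()
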