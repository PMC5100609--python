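"""Result containers shared across the estimation modules."""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class AssociationEstimate:
    """A (beta, se, p) triple from one adjusted linear regression.

    Houses both instrument-exposure slopes (conventionally written gamma-hat)
    and instrument-outcome slopes (Gamma-hat) as well as observational
    exposure-outcome associations.
    """

    predictor_id: str
    trait_name: str
    beta: float
    se: float
    p: float
    n: int
    adjusted_for: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")


@dataclass
class IVEstimate:
    """A causal effect estimate in SD-outcome per SD-exposure units."""

    exposure_name: str
    outcome_name: str
    beta_iv: float
    ci_low: float
    ci_high: float
    p: float
    estimator_tag: str            # wald | tsls | ivw | mvmr
    n: int
    se: float | None = None
    p_wh: float | None = None     # Durbin-Wu-Hausman endogeneity p
    f_first: float | None = None  # first-stage (partial) F of the instrument block
    weak_instrument: bool | None = None
    ci_level: float = 0.95
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta_iv <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass
class FirstStageResult:
    """Strength of one instrument (SNP or allelic score) for one exposure."""

    instrument_id: str
    exposure_name: str
    beta: float
    se: float
    p: float
    F_first: float
    r_squared: float              # incremental R^2 of the instrument block
    n: int
    weak: bool = False
    threshold: float = 10.0


@dataclass
class EggerResult:
    """MR-Egger weighted regression: slope (causal) and intercept (pleiotropy)."""

    exposure_name: str
    outcome_name: str
    slope_beta_iv: float
    slope_se: float
    slope_p: float
    intercept_beta0: float
    intercept_se: float
    intercept_p: float
    n_snps: int
    per_snp_inputs: pd.DataFrame = field(repr=False, default=None)
    ci_level: float = 0.95

    @property
    def slope_ci(self) -> tuple[float, float]:
        from scipy import stats

        tcrit = stats.t.ppf(0.5 + self.ci_level / 2, self.n_snps - 2)
        return (self.slope_beta_iv - tcrit * self.slope_se,
                self.slope_beta_iv + tcrit * self.slope_se)


@dataclass
class MVMRResult:
    """Multivariable MR: direct effects of several exposures on one outcome."""

    outcome_name: str
    exposures: pd.DataFrame       # columns: exposure, beta_iv, se, ci_low, ci_high, p
    instrument_ids: tuple[str, ...]
    conditional_f: dict[str, float]
    n: int
    ci_level: float = 0.95

    def effect(self, exposure: str) -> float:
        row = self.exposures.set_index("exposure").loc[exposure]
        return float(row["beta_iv"])


@dataclass
class FunnelPoint:
    """One SNP in a funnel plot: MAF-standardized strength vs its Wald ratio."""

    snp_id: str
    strength: float
    ratio_estimate: float
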