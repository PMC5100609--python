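"""Core data containers: instrument manifests and aligned cohorts.

A *cohort* is the package's in-memory analysis unit: a genotype dosage matrix
(individuals x SNPs, each entry counting copies of the manifest's effect
allele, in [0, 2]) aligned row-for-row with a phenotype/covariate table.  The
*instrument manifest* declares, per SNP, which allele is the trait-increasing
(effect) allele and which exposure the SNP proxies (BMI for the forward
analyses, FN-BMD / LS-BMD scores for the reverse direction).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import SimulationConfig

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Skeletal sites measured by whole-body DXA, in report order.
SITES = ("SK", "UL", "LL", "SP", "PE")

#: Recognised instrument trait tags.
TRAIT_TAGS = ("BMI", "FN-BMD", "LS-BMD", "custom")


def complement(allele: str) -> str:
    """Watson-Crick complement of a single base."""
    return _COMPLEMENT[allele]


@dataclass
class InstrumentManifest:
    """Per-SNP effect-allele orientation and trait assignment.

    Parameters
    ----------
    table
        DataFrame with columns ``snp_id``, ``effect_allele``, ``other_allele``,
        ``trait_tag`` and optionally ``maf`` and ``published_effect``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp_id", "effect_allele", "other_allele", "trait_tag"}
        missing = required - set(self.table.columns)
        if missing:
            raise InvalidConfigError(f"manifest missing columns: {sorted(missing)}")
        t = self.table
        if t["snp_id"].duplicated().any():
            dups = t.loc[t["snp_id"].duplicated(), "snp_id"].tolist()
            raise InvalidConfigError(f"duplicate snp_ids in manifest: {dups}")
        for col in ("effect_allele", "other_allele"):
            bad = ~t[col].isin(VALID_ALLELES)
            if bad.any():
                raise InvalidConfigError(
                    f"invalid alleles in {col}: {t.loc[bad, col].unique().tolist()}")
        same = t["effect_allele"] == t["other_allele"]
        if same.any():
            raise InvalidConfigError(
                f"effect and other allele identical for {t.loc[same, 'snp_id'].tolist()}")
        bad_tag = ~t["trait_tag"].isin(TRAIT_TAGS)
        if bad_tag.any():
            raise InvalidConfigError(
                f"unknown trait tags {t.loc[bad_tag, 'trait_tag'].unique().tolist()}; "
                f"valid tags are {TRAIT_TAGS}")
        self.table = t.reset_index(drop=True)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def for_tag(self, trait_tag: str) -> "InstrumentManifest":
        """Subset of SNPs proxying one trait."""
        sub = self.table[self.table["trait_tag"] == trait_tag]
        return InstrumentManifest(sub.copy())

    def palindromic_ids(self) -> list[str]:
        """SNPs whose allele pair is strand-ambiguous (A/T or C/G)."""
        t = self.table
        mask = t.apply(
            lambda r: complement(r["effect_allele"]) == r["other_allele"], axis=1)
        return t.loc[mask, "snp_id"].tolist() if len(t) else []

    def drop(self, snp_ids) -> "InstrumentManifest":
        keep = ~self.table["snp_id"].isin(set(snp_ids))
        return InstrumentManifest(self.table[keep].copy())

    def flipped(self) -> "InstrumentManifest":
        """Manifest with every effect/other allele label swapped (sensitivity)."""
        t = self.table.copy()
        t[["effect_allele", "other_allele"]] = t[["other_allele", "effect_allele"]].values
        if "published_effect" in t.columns:
            t["published_effect"] = -t["published_effect"]
        return InstrumentManifest(t)


@dataclass
class ExclusionLog:
    """Book-keeping for the complete-case rule applied during alignment."""

    n_genotyped: int
    n_phenotyped: int
    n_shared: int
    n_incomplete: int
    n_final: int
    dropped_ids: tuple[str, ...] = ()

    def summary(self) -> str:
        return (f"{self.n_genotyped} genotyped, {self.n_phenotyped} phenotyped, "
                f"{self.n_shared} shared ids, {self.n_incomplete} incomplete "
                f"dropped -> {self.n_final} complete cases")


@dataclass
class Cohort:
    """Aligned dosage matrix + phenotype table (one row per individual).

    ``dosages`` columns are SNP ids oriented to the manifest effect allele;
    ``phenotypes`` holds exposures, outcomes and the age/sex covariates.  For
    simulated cohorts ``config`` retains the generating truth and ``latent``
    the standardized structural-equation variables the natural-unit
    phenotypes were mapped from.
    """

    dosages: pd.DataFrame
    phenotypes: pd.DataFrame
    manifest: InstrumentManifest | None = None
    config: "SimulationConfig | None" = None
    latent: pd.DataFrame | None = field(default=None, repr=False)
    exclusions: ExclusionLog | None = None

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.phenotypes.index):
            raise InvalidConfigError("dosage and phenotype rows are not aligned")

    @property
    def n(self) -> int:
        return len(self.phenotypes)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def sample_mafs(self) -> pd.Series:
        """Effect-allele frequencies observed in the dosage matrix."""
        return self.dosages.mean(axis=0) / 2.0

    def covariates(self, names=("age", "sex")) -> np.ndarray:
        return self.phenotypes.loc[:, list(names)].to_numpy(dtype=float)
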