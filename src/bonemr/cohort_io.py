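"""Reading, writing and aligning the package's external data formats.

Formats are deliberately desk-scale and text-only:

* dosage TSV — header row of SNP ids, first column ``individual_id``, values
  in [0, 2] counting copies of the manifest's effect allele;
* VCF — dosages taken from the ``DS`` FORMAT field when present, otherwise
  from hard ``GT`` calls, harmonized to the manifest's effect allele
  (flipping ``2 - dosage`` when REF carries the effect allele, with strand
  complements recognised and palindromic A/T, C/G sites flagged);
* phenotype TSV — one row per ``individual_id`` with named numeric columns;
* manifest TSV — one row per SNP.

Alignment applies the complete-case rule: individuals missing any analysis
variable are dropped and counted, never imputed.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .data import Cohort, ExclusionLog, InstrumentManifest, complement
from .exceptions import (
    AlignmentError,
    HarmonizationError,
    MissingInstrumentError,
)

logger = logging.getLogger("bonemr")

__all__ = [
    "read_manifest", "write_manifest",
    "read_phenotypes", "write_phenotypes",
    "read_genotypes", "write_dosages", "write_vcf",
    "align_cohort",
]

_FLOAT_FMT = "%.10g"


def read_manifest(path) -> InstrumentManifest:
    """Read an instrument manifest TSV."""
    return InstrumentManifest(pd.read_csv(path, sep="\t", dtype={"snp_id": str}))


def write_manifest(manifest: InstrumentManifest, path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV -> DataFrame indexed by individual_id."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if "individual_id" not in df.columns:
        raise AlignmentError("phenotype table lacks an individual_id column")
    return df.set_index("individual_id")


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.rename_axis("individual_id").to_csv(
        path, sep="\t", float_format=_FLOAT_FMT)


def write_dosages(dosages: pd.DataFrame, path) -> None:
    """Write the dosage-TSV dialect (individual_id + one column per SNP)."""
    dosages.rename_axis("individual_id").to_csv(
        path, sep="\t", float_format=_FLOAT_FMT)


def _read_dosage_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if "individual_id" not in df.columns:
        raise AlignmentError("dosage table lacks an individual_id column")
    df = df.set_index("individual_id").astype(float)
    bad = ((df < 0) | (df > 2)).any().any()
    if bad:
        raise HarmonizationError("dosage values outside [0, 2]")
    return df


def _vcf_record_dosage(rec, n_samples: int) -> np.ndarray:
    """Per-sample ALT dosage from DS when present, else from GT."""
    dosage = np.full(n_samples, np.nan)
    for i, sample in enumerate(rec.samples.values()):
        ds = sample.get("DS") if "DS" in rec.format else None
        if ds is not None:
            dosage[i] = float(ds if np.isscalar(ds) else ds[0])
        else:
            gt = sample.get("GT")
            if gt is not None and not any(a is None for a in gt):
                dosage[i] = float(sum(1 for a in gt if a == 1))
    return dosage


def _orient(rec_ref: str, rec_alt: str, effect: str, other: str) -> tuple[bool, bool]:
    """Match a VCF REF/ALT pair to the manifest alleles.

    Returns ``(flip, strand_swapped)`` where ``flip`` means the effect allele
    is the REF allele (dosage <- 2 - ALT dosage).  Raises on incompatible
    allele pairs.
    """
    if (rec_alt, rec_ref) == (effect, other):
        return False, False
    if (rec_ref, rec_alt) == (effect, other):
        return True, False
    c_ref, c_alt = complement(rec_ref), complement(rec_alt)
    if (c_alt, c_ref) == (effect, other):
        return False, True
    if (c_ref, c_alt) == (effect, other):
        return True, True
    raise HarmonizationError(
        f"allele pair {rec_ref}/{rec_alt} incompatible with manifest "
        f"{effect}/{other}")


def _read_vcf(path, manifest: InstrumentManifest) -> pd.DataFrame:
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        wanted = {r.snp_id: r for r in manifest.table.itertuples()}
        cols: dict[str, np.ndarray] = {}
        for rec in vcf:
            if rec.id not in wanted:
                continue
            row = wanted[rec.id]
            if len(rec.alts or ()) != 1:
                raise HarmonizationError(
                    f"{rec.id}: expected a biallelic site, got alts {rec.alts}")
            flip, swapped = _orient(rec.ref, rec.alts[0],
                                    row.effect_allele, row.other_allele)
            if swapped:
                logger.warning("%s: strand-swapped alleles %s/%s harmonized to "
                               "manifest %s/%s", rec.id, rec.ref, rec.alts[0],
                               row.effect_allele, row.other_allele)
            dose = _vcf_record_dosage(rec, len(samples))
            cols[rec.id] = 2.0 - dose if flip else dose
    return pd.DataFrame(cols, index=pd.Index(samples, name="individual_id"))


def read_genotypes(path, format: str, manifest: InstrumentManifest,
                   drop_palindromic: bool = False) -> pd.DataFrame:
    """Read a dosage matrix oriented to the manifest's effect alleles.

    Dosage-TSV input is taken at face value (its dialect already stores
    effect-allele dosages); VCF input is harmonized per record.  Palindromic
    (A/T, C/G) SNPs are flagged with a warning, or removed when
    ``drop_palindromic`` is set.  Missing manifest SNPs raise
    :class:`MissingInstrumentError`.
    """
    if format == "dosage_tsv":
        dosages = _read_dosage_tsv(path)
    elif format == "vcf":
        dosages = _read_vcf(path, manifest)
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    missing = [s for s in manifest.snp_ids if s not in dosages.columns]
    if missing:
        raise MissingInstrumentError(missing)
    dosages = dosages.loc[:, manifest.snp_ids]

    palindromic = manifest.palindromic_ids()
    if palindromic:
        if drop_palindromic:
            logger.warning("dropping palindromic SNPs: %s", palindromic)
            dosages = dosages.drop(columns=palindromic)
        else:
            logger.warning("palindromic SNPs retained (flagged): %s", palindromic)
    return dosages


def write_vcf(dosages: pd.DataFrame, manifest: InstrumentManifest, path) -> None:
    """Write dosages as a plain-text VCF with GT and DS fields.

    The ALT allele carries the manifest's effect allele, so a round trip
    through :func:`read_genotypes` reproduces the matrix without flips.
    Hard GT calls are written only for integral dosages.
    """
    rows = manifest.table.set_index("snp_id").loc[list(dosages.columns)]
    samples = list(dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description='
                 '"Dosage of the ALT allele">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for pos, (snp_id, row) in enumerate(rows.iterrows(), start=1):
            fields = ["1", str(1000 * pos), snp_id, row["other_allele"],
                      row["effect_allele"], ".", "PASS", ".", "GT:DS"]
            for d in dosages[snp_id].to_numpy(dtype=float):
                if float(d).is_integer():
                    k = int(d)
                    gt = "/".join(["1"] * k + ["0"] * (2 - k)) if k else "0/0"
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[k]
                else:
                    gt = "./."
                fields.append(f"{gt}:{d:.6g}")
            fh.write("\t".join(fields) + "\n")


def align_cohort(genotypes: pd.DataFrame, phenotypes: pd.DataFrame,
                 manifest: InstrumentManifest | None = None,
                 analysis_columns: list[str] | None = None) -> Cohort:
    """Inner-join genotypes and phenotypes and apply the complete-case rule.

    Individuals missing any analysis variable (by default every phenotype
    column and every dosage) are dropped and recorded in the cohort's
    :class:`~bonemr.data.ExclusionLog`.  Duplicated ids raise rather than
    silently de-duplicate.
    """
    for name, frame in (("genotype", genotypes), ("phenotype", phenotypes)):
        if frame.index.duplicated().any():
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise AlignmentError(f"duplicated individual_id in {name} table: {dups}")
    shared = genotypes.index.intersection(phenotypes.index)
    if len(shared) == 0:
        raise AlignmentError("no shared individual_ids between genotypes and "
                             "phenotypes")
    g = genotypes.loc[shared]
    p = phenotypes.loc[shared]
    cols = analysis_columns if analysis_columns is not None else list(p.columns)
    complete = p[cols].notna().all(axis=1) & g.notna().all(axis=1)
    dropped = shared[~complete]
    log = ExclusionLog(
        n_genotyped=len(genotypes), n_phenotyped=len(phenotypes),
        n_shared=len(shared), n_incomplete=int((~complete).sum()),
        n_final=int(complete.sum()), dropped_ids=tuple(dropped))
    if log.n_final == 0:
        raise AlignmentError("no complete cases after alignment")
    logger.info("alignment: %s", log.summary())
    return Cohort(dosages=g.loc[complete], phenotypes=p.loc[complete],
                  manifest=manifest, exclusions=log)
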