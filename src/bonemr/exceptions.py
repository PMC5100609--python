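"""Exception hierarchy for bonemr.

All errors raised by the package derive from :class:`BonemrError` so callers
can catch everything from one place; the concrete subclasses mirror the
failure modes of each analysis stage (configuration, data alignment,
harmonization, identification, degeneracy).
"""


class BonemrError(Exception):
    """Base class for all bonemr errors."""


class InvalidConfigError(BonemrError):
    """A simulation or analysis configuration violates its invariants."""


class CyclicConfigError(InvalidConfigError):
    """A structural-equation config requests a causal cycle (X->Y and Y->X)."""


class HarmonizationError(BonemrError):
    """Allele pair in a genotype file is incompatible with the manifest."""


class MissingInstrumentError(BonemrError):
    """Manifest SNPs absent from the genotype source."""

    def __init__(self, snp_ids):
        self.snp_ids = list(snp_ids)
        super().__init__(f"instruments missing from genotype source: {self.snp_ids}")


class AlignmentError(BonemrError):
    """Genotype and phenotype tables cannot be joined."""


class DegenerateDataError(BonemrError):
    """Zero-variance variable (constant instrument, exposure or outcome)."""


class IdentificationError(BonemrError):
    """Fewer instruments than endogenous exposures, or rank-deficient design."""


class InsufficientInstrumentsError(BonemrError):
    """Too few SNPs for a summary-statistic estimator (IVW needs >=2, Egger >=3)."""


class UndefinedRatioError(BonemrError):
    """Wald ratio with a zero instrument-exposure association."""


class TransformError(BonemrError):
    """A requested variable transform is undefined (e.g. log of non-positive)."""
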