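"""Exception hierarchy for flaxmark.

Every error raised deliberately by the package derives from
:class:`FlaxmarkError`, so callers (and the CLI) can distinguish
domain errors from programming mistakes.
"""


class FlaxmarkError(Exception):
    """Base class for all flaxmark errors."""


class FastaParseError(FlaxmarkError):
    """Malformed FASTA input (empty file, duplicate ids, illegal characters)."""


class VariantTableError(FlaxmarkError):
    """Malformed or unsupported row in a variant table."""


class UnsupportedVariantError(VariantTableError):
    """Multi-base, multi-allelic or indel variant — only single-base SNPs are handled."""


class PrimerError(FlaxmarkError):
    """Base class for in-silico PCR failures."""


class NoProductError(PrimerError):
    """A primer has no binding site, or the pair yields no product."""


class MultiProductError(PrimerError):
    """A primer binds more than once; the product is not unique."""


class DesignError(FlaxmarkError):
    """Assay-geometry problem, e.g. the target SNP lies outside the amplicon."""


class ReferenceMismatchError(FlaxmarkError):
    """Sequence base at the variant offset does not equal the declared reference allele."""


class NotACapsCandidateError(FlaxmarkError):
    """The SNP does not create or destroy any recognition site of the tested enzyme."""


class UndefinedPatternError(FlaxmarkError):
    """A band pattern was requested for a genotype that has none (MISSING/AMBIGUOUS)."""


class DegenerateCurveError(FlaxmarkError):
    """A melt curve with zero dynamic range cannot be normalized."""


class GridMismatchError(FlaxmarkError):
    """Two melt curves do not share the same temperature grid."""


class AmbiguousBaseError(FlaxmarkError):
    """IUPAC-ambiguous base where an unambiguous A/C/G/T is required."""


class ConfigurationError(FlaxmarkError):
    """Inconsistent inputs, e.g. a variant not covered by any amplicon."""


class IndeterminateGenotypeError(FlaxmarkError):
    """A decision rule cannot be evaluated because a decisive locus is missing."""
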