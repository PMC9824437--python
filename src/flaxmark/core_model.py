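"""Sequence and variant data model.

Reference sequences, single-base variants, PCR amplicons and per-locus
genotype states, together with I/O for the standard flat formats the
toolkit consumes (FASTA via Biopython, a minimal five-column variant
table, a primer TSV).

Coordinates are 1-based and inclusive throughout, following the GenBank
convention used for the flax *FAD3* mutation coordinates
(e.g. CP027631.1:16092348).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import (
    AmbiguousBaseError,
    DesignError,
    FastaParseError,
    MultiProductError,
    NoProductError,
    ReferenceMismatchError,
    UnsupportedVariantError,
    VariantTableError,
)

# IUPAC nucleotide alphabet; ambiguity codes are legal in references,
# but a variant site itself must be an unambiguous A/C/G/T.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS_DNA = frozenset("ACGT")

IUPAC_EXPANSION: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string (case preserved as upper)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _validate_dna(bases: str, *, where: str) -> str:
    bases = bases.upper()
    for i, b in enumerate(bases, start=1):
        if b not in IUPAC_DNA:
            raise FastaParseError(
                f"{where}: illegal character {b!r} at position {i} (not an IUPAC DNA code)"
            )
    return bases


class Genotype(Enum):
    """Diploid genotype state at a single biallelic locus."""

    REF_HOM = "RR"
    HET = "RA"
    ALT_HOM = "AA"
    MISSING = "NN"
    AMBIGUOUS = "XX"

    @property
    def code(self) -> str:
        return self.value

    @classmethod
    def from_code(cls, code: str) -> "Genotype":
        code = code.strip().upper()
        for g in cls:
            if g.value == code:
                return g
        raise ValueError(f"unknown genotype code {code!r} (expected RR/RA/AA/NN/XX)")


@dataclass(frozen=True)
class ReferenceSequence:
    """A named DNA sequence (a chromosome, contig or amplicon template)."""

    id: str
    bases: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaParseError("sequence id must be non-empty")
        if not self.bases:
            raise FastaParseError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "bases", _validate_dna(self.bases, where=f"sequence {self.id!r}"))

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class SnpVariant:
    """A single-base substitution at a 1-based genomic coordinate."""

    locus_id: str
    chrom_id: str
    position: int
    ref_allele: str
    alt_allele: str
    gene: str = ""
    exon: int = 0
    effect: str = ""

    def __post_init__(self) -> None:
        ref = self.ref_allele.upper()
        alt = self.alt_allele.upper()
        if len(ref) != 1 or len(alt) != 1:
            raise UnsupportedVariantError(
                f"{self.locus_id}: only single-base substitutions are supported "
                f"(got REF={ref!r}, ALT={alt!r})"
            )
        if ref not in UNAMBIGUOUS_DNA or alt not in UNAMBIGUOUS_DNA:
            raise UnsupportedVariantError(
                f"{self.locus_id}: alleles must be unambiguous A/C/G/T "
                f"(got REF={ref!r}, ALT={alt!r})"
            )
        if ref == alt:
            raise VariantTableError(f"{self.locus_id}: REF and ALT alleles are identical ({ref})")
        if self.position < 1:
            raise VariantTableError(f"{self.locus_id}: position must be >= 1")
        object.__setattr__(self, "ref_allele", ref)
        object.__setattr__(self, "alt_allele", alt)


@dataclass(frozen=True)
class Amplicon:
    """A PCR product on a reference, with its primer footprints.

    ``start``/``end`` are 1-based inclusive coordinates on ``source_id``;
    ``variant_offset`` is the 1-based offset of the target SNP within
    ``bases``.
    """

    locus_id: str
    source_id: str
    start: int
    end: int
    bases: str
    primer_fwd: str
    primer_rev: str
    variant_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        object.__setattr__(self, "primer_fwd", self.primer_fwd.upper())
        object.__setattr__(self, "primer_rev", self.primer_rev.upper())
        if self.end - self.start + 1 != len(self.bases):
            raise DesignError(
                f"{self.locus_id}: coordinate span {self.start}-{self.end} "
                f"does not match sequence length {len(self.bases)}"
            )
        if not (1 <= self.variant_offset <= len(self.bases)):
            raise DesignError(
                f"{self.locus_id}: variant offset {self.variant_offset} outside "
                f"amplicon of length {len(self.bases)}"
            )
        if not self.bases.startswith(self.primer_fwd):
            raise DesignError(f"{self.locus_id}: forward primer does not match amplicon 5' end")
        if not self.bases.endswith(reverse_complement(self.primer_rev)):
            raise DesignError(f"{self.locus_id}: reverse primer does not match amplicon 3' end")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class MultiLocusGenotype:
    """Per-locus genotype states keyed by locus id."""

    calls: dict[str, Genotype] = field(default_factory=dict)

    def __getitem__(self, locus_id: str) -> Genotype:
        return self.calls[locus_id]

    def get(self, locus_id: str, default: Genotype = Genotype.MISSING) -> Genotype:
        return self.calls.get(locus_id, default)


# ---------------------------------------------------------------------------
# The three low-linolenic FAD3 mutations the toolkit targets.
# FAD3A can be inactivated by either a Trp->stop (exon 1) or an Arg->stop
# (exon 5) nonsense mutation; FAD3B by a His->Tyr substitution (exon 2).
# ---------------------------------------------------------------------------

FAD3A_EX1 = SnpVariant(
    locus_id="fad3a_ex1", chrom_id="CP027631.1", position=16092348,
    ref_allele="G", alt_allele="A", gene="FAD3A", exon=1, effect="Trp->stop",
)
FAD3B_EX2 = SnpVariant(
    locus_id="fad3b_ex2", chrom_id="CP027622.1", position=1035655,
    ref_allele="C", alt_allele="T", gene="FAD3B", exon=2, effect="His->Tyr",
)
FAD3A_EX5 = SnpVariant(
    locus_id="fad3a_ex5", chrom_id="CP027631.1", position=16090340,
    ref_allele="C", alt_allele="T", gene="FAD3A", exon=5, effect="Arg->stop",
)

FAD3_MUTATIONS: tuple[SnpVariant, ...] = (FAD3A_EX1, FAD3B_EX2, FAD3A_EX5)

#: Canonical locus ordering used in genotype tables and reports.
FAD3_LOCI: tuple[str, ...] = ("fad3a_ex1", "fad3a_ex5", "fad3b_ex2")


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read a multi-record FASTA file into :class:`ReferenceSequence` objects.

    Sequences are upper-cased; duplicate ids, empty files and non-IUPAC
    characters raise :class:`FastaParseError`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    out: list[ReferenceSequence] = []
    for rec in records:
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        out.append(ReferenceSequence(id=rec.id, bases=str(rec.seq), description=desc))
    return out


def write_fasta(sequences: Iterable[ReferenceSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA, wrapped at ``width`` columns."""
    records = [
        SeqRecord(Seq(s.bases), id=s.id, description=s.description)
        for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Variant-table I/O (minimal 5-column dialect: CHROM POS ID REF ALT)
# ---------------------------------------------------------------------------

def read_variant_table(path: str | Path) -> list[SnpVariant]:
    """Parse a minimal tab-separated variant table.

    Columns: CHROM, POS, ID, REF, ALT. Lines starting with ``#`` are
    headers. Multi-base or multi-allelic rows raise
    :class:`UnsupportedVariantError`. Known *FAD3* locus ids are
    annotated with gene/exon/effect from the bundled constants.
    """
    path = Path(path)
    known = {v.locus_id: v for v in FAD3_MUTATIONS}
    out: list[SnpVariant] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise VariantTableError(f"{path}:{lineno}: expected 5 tab-separated columns")
            chrom, pos, vid, ref, alt = fields[:5]
            if "," in alt:
                raise UnsupportedVariantError(f"{path}:{lineno}: multi-allelic ALT {alt!r}")
            try:
                position = int(pos)
            except ValueError as exc:
                raise VariantTableError(f"{path}:{lineno}: POS {pos!r} is not an integer") from exc
            anno = known.get(vid)
            out.append(
                SnpVariant(
                    locus_id=vid, chrom_id=chrom, position=position,
                    ref_allele=ref, alt_allele=alt,
                    gene=anno.gene if anno else "",
                    exon=anno.exon if anno else 0,
                    effect=anno.effect if anno else "",
                )
            )
    return out


def write_variant_table(variants: Iterable[SnpVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\tID\tREF\tALT\n")
        for v in variants:
            fh.write(f"{v.chrom_id}\t{v.position}\t{v.locus_id}\t{v.ref_allele}\t{v.alt_allele}\n")


def read_primer_table(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a primer TSV (locus_id, fwd, rev) into a dict."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise VariantTableError(f"{path}:{lineno}: expected 3 columns (locus_id, fwd, rev)")
            out[fields[0]] = (fields[1].upper(), fields[2].upper())
    return out


def write_primer_table(primers: Mapping[str, tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#locus_id\tfwd\trev\n")
        for locus_id, (fwd, rev) in primers.items():
            fh.write(f"{locus_id}\t{fwd}\t{rev}\n")


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

def _primer_sites(
    haystack: str,
    primer: str,
    *,
    max_mismatches: int = 0,
    protect_3prime: int = 5,
    three_prime_left: bool = False,
) -> list[int]:
    """0-based start positions where ``primer`` binds ``haystack``.

    With ``max_mismatches`` > 0 a site may carry that many mismatches,
    but none within the ``protect_3prime`` bases at the primer's 3' end
    (extension end). ``three_prime_left`` marks primers laid on the plus
    strand whose 3' end is the leftmost base (a reverse primer's
    reverse complement).
    """
    n, m = len(haystack), len(primer)
    if m == 0 or m > n:
        return []
    if max_mismatches == 0:
        sites, start = [], 0
        while True:
            i = haystack.find(primer, start)
            if i < 0:
                return sites
            sites.append(i)
            start = i + 1
    protected = (
        range(0, min(protect_3prime, m)) if three_prime_left
        else range(max(0, m - protect_3prime), m)
    )
    protected = set(protected)
    sites = []
    for i in range(n - m + 1):
        mism = 0
        ok = True
        for j in range(m):
            if haystack[i + j] != primer[j]:
                if j in protected:
                    ok = False
                    break
                mism += 1
                if mism > max_mismatches:
                    ok = False
                    break
        if ok:
            sites.append(i)
    return sites


def extract_amplicon(
    ref: ReferenceSequence,
    fwd: str,
    rev: str,
    variant: SnpVariant,
    *,
    max_mismatches: int = 0,
    protect_3prime: int = 5,
) -> Amplicon:
    """Extract the unique PCR product defined by a primer pair.

    The forward primer must bind the plus strand exactly once; the
    reverse primer (given 5'->3' on the minus strand) must bind exactly
    once downstream. The product spans from the forward primer's first
    base to the reverse primer's binding end, inclusive. The variant
    must fall inside the product.
    """
    fwd, rev = fwd.upper(), rev.upper()
    seq = ref.bases
    fwd_sites = _primer_sites(seq, fwd, max_mismatches=max_mismatches, protect_3prime=protect_3prime)
    if not fwd_sites:
        raise NoProductError(f"{variant.locus_id}: forward primer has no binding site on {ref.id}")
    if len(fwd_sites) > 1:
        raise MultiProductError(f"{variant.locus_id}: forward primer binds {len(fwd_sites)} times on {ref.id}")
    rc_rev = reverse_complement(rev)
    rev_sites = _primer_sites(
        seq, rc_rev, max_mismatches=max_mismatches, protect_3prime=protect_3prime, three_prime_left=True
    )
    f0 = fwd_sites[0]
    rev_sites = [r for r in rev_sites if r >= f0 + len(fwd)]
    if not rev_sites:
        raise NoProductError(f"{variant.locus_id}: reverse primer has no binding site downstream of the forward primer")
    if len(rev_sites) > 1:
        raise MultiProductError(f"{variant.locus_id}: reverse primer binds {len(rev_sites)} times downstream")
    r0 = rev_sites[0]
    start = f0 + 1                      # 1-based inclusive
    end = r0 + len(rc_rev)              # 1-based inclusive
    offset = variant.position - start + 1
    if not (1 <= offset <= end - start + 1):
        raise DesignError(
            f"{variant.locus_id}: SNP at {variant.chrom_id}:{variant.position} "
            f"lies outside the product {ref.id}:{start}-{end}"
        )
    # The PCR product carries the primer sequences themselves: with
    # mismatch-tolerant binding the primers overwrite their footprints.
    product = fwd + seq[f0 + len(fwd) : r0] + rc_rev
    return Amplicon(
        locus_id=variant.locus_id, source_id=ref.id, start=start, end=end,
        bases=product, primer_fwd=fwd, primer_rev=rev,
        variant_offset=offset,
    )


def apply_allele(amp: Amplicon, variant: SnpVariant, allele: str) -> str:
    """Return the amplicon sequence carrying the REF or ALT allele.

    The amplicon base at ``variant_offset`` must equal the variant's
    reference allele; otherwise :class:`ReferenceMismatchError`.
    """
    allele = allele.upper()
    if allele not in {"REF", "ALT"}:
        raise ValueError(f"allele must be 'REF' or 'ALT', got {allele!r}")
    i = amp.variant_offset - 1
    if amp.bases[i] != variant.ref_allele:
        raise ReferenceMismatchError(
            f"{variant.locus_id}: amplicon base {amp.bases[i]!r} at offset "
            f"{amp.variant_offset} does not match reference allele {variant.ref_allele!r}"
        )
    if allele == "REF":
        return amp.bases
    return amp.bases[:i] + variant.alt_allele + amp.bases[i + 1 :]


def iupac_to_regex(motif: str) -> re.Pattern[str]:
    """Compile an IUPAC motif into a plus-strand regex (no capture)."""
    parts = []
    for b in motif.upper():
        exp = IUPAC_EXPANSION.get(b)
        if exp is None:
            raise AmbiguousBaseError(f"illegal IUPAC code {b!r} in motif {motif!r}")
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return re.compile("".join(parts))
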