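"""Targeted amplicon-sequencing engine.

Minimal read processing for deep-sequenced PCR amplicons: ungapped
best-offset read assignment, allele pileup at the target SNPs,
per-individual genotype calls from allele fractions, and pooled
plant-fraction estimation.

Pooled estimation exploits that flax is self-pollinating: plants of a
variety are essentially fully homozygous, so the mutant-allele read
fraction in a DNA pool of many plants directly estimates the fraction
of plants carrying the mutation. A Hardy-Weinberg mode is provided for
outbred material, where carriers (hetero- or homozygous) occur at
1 - (1-p)^2 for allele frequency p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from statsmodels.stats.proportion import proportion_confint

from .core_model import Amplicon, Genotype, SnpVariant, reverse_complement
from .exceptions import ConfigurationError


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class Read:
    """One sequencing read; qualities are Phred scores (None = all-pass)."""

    id: str
    bases: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValueError(f"read {self.id!r}: quality string length mismatch")


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ValueError("read ids are not unique")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


@dataclass(frozen=True)
class ReadAssignment:
    locus_id: str
    offset: int          # 0-based start of the read on the amplicon plus strand
    strand: str          # '+' if the read matches the plus strand as given
    identity: float


@dataclass
class PileupCounts:
    """Allele evidence at one variant site."""

    locus_id: str
    depth: int = 0
    ref_count: int = 0
    alt_count: int = 0
    other_count: int = 0

    def __post_init__(self) -> None:
        if self.ref_count + self.alt_count + self.other_count != self.depth:
            raise ValueError(f"{self.locus_id}: pileup counts do not sum to depth")


class PoolAssumption(Enum):
    INBRED_HOMOZYGOUS = "inbred_homozygous"
    HARDY_WEINBERG = "hardy_weinberg"


@dataclass
class PoolEstimate:
    locus_id: str
    plant_fraction_percent: float
    ci_low: float
    ci_high: float
    assumption: PoolAssumption
    allele_frequency: float
    informative_depth: int


class AmpliconIndex:
    """Pre-encoded amplicons for fast ungapped sliding-window matching."""

    def __init__(self, amplicons: Iterable[Amplicon]):
        self.amplicons: dict[str, Amplicon] = {}
        self._encoded: dict[tuple[str, str], np.ndarray] = {}
        self._windows: dict[tuple[str, str, int], np.ndarray] = {}
        for amp in amplicons:
            if amp.locus_id in self.amplicons:
                raise ConfigurationError(f"duplicate amplicon locus id {amp.locus_id!r}")
            self.amplicons[amp.locus_id] = amp
            self._encoded[(amp.locus_id, "+")] = _encode(amp.bases)
            self._encoded[(amp.locus_id, "-")] = _encode(reverse_complement(amp.bases))
        if not self.amplicons:
            raise ConfigurationError("amplicon set is empty")

    def windows(self, locus_id: str, strand: str, read_len: int) -> np.ndarray | None:
        """(n_offsets, read_len) view of every ungapped placement, or None if too long."""
        key = (locus_id, strand, read_len)
        if key not in self._windows:
            enc = self._encoded[(locus_id, strand)]
            if read_len > enc.size:
                self._windows[key] = None
            else:
                self._windows[key] = np.lib.stride_tricks.sliding_window_view(enc, read_len)
        return self._windows[key]


def assign_read(
    read: Read,
    index: AmpliconIndex,
    min_identity: float = 0.9,
) -> ReadAssignment | None:
    """Place a read on its best amplicon by ungapped sliding.

    The read (or its reverse complement) is laid at every offset of
    every amplicon; the placement maximizing exact base matches wins,
    with deterministic ties broken by locus id, plus strand first, then
    smallest offset. Reads below ``min_identity`` are unassigned.
    """
    enc = _encode(read.bases)
    n = enc.size
    best: tuple[float, str, str, int] | None = None
    for locus_id in sorted(index.amplicons):
        for strand in ("+", "-"):
            windows = index.windows(locus_id, strand, n)
            if windows is None:
                continue
            scores = (windows == enc).sum(axis=1)
            off = int(scores.argmax())
            ident = float(scores[off]) / n
            if strand == "-":
                # offset of rc(read) on the minus-strand encoding -> plus-strand offset
                amp_len = len(index.amplicons[locus_id])
                off = amp_len - n - off
            cand = (ident, locus_id, strand, off)
            if best is None or cand[0] > best[0]:
                best = cand
    if best is None or best[0] < min_identity:
        return None
    ident, locus_id, strand, off = best
    return ReadAssignment(locus_id=locus_id, offset=off, strand=strand, identity=ident)


def count_alleles(
    readset: ReadSet,
    amplicons: Sequence[Amplicon],
    variants: Sequence[SnpVariant],
    min_base_quality: int = 20,
    min_identity: float = 0.9,
) -> dict[str, PileupCounts]:
    """Pile up ref/alt/other evidence at every variant site.

    Each assigned read covering a variant's amplicon offset contributes
    the base it carries there, provided the base quality passes the
    threshold (reads without qualities always pass). The three counts
    always sum to the reported depth.
    """
    index = AmpliconIndex(amplicons)
    by_locus = {a.locus_id: a for a in amplicons}
    targets: dict[str, SnpVariant] = {}
    for v in variants:
        if v.locus_id not in by_locus:
            raise ConfigurationError(f"variant {v.locus_id!r} is not covered by any amplicon")
        targets[v.locus_id] = v
    piles = {lid: {"depth": 0, "ref": 0, "alt": 0, "other": 0} for lid in targets}
    for read in readset:
        asn = assign_read(read, index, min_identity=min_identity)
        if asn is None or asn.locus_id not in targets:
            continue
        amp = by_locus[asn.locus_id]
        var = targets[asn.locus_id]
        site0 = amp.variant_offset - 1
        j = site0 - asn.offset            # position within the plus-oriented read
        if not (0 <= j < len(read.bases)):
            continue
        if asn.strand == "+":
            base = read.bases[j]
            q = read.qualities[j] if read.qualities is not None else None
        else:
            # read matched as reverse complement: index from the read's 3' end
            k = len(read.bases) - 1 - j
            base = reverse_complement(read.bases[k])
            q = read.qualities[k] if read.qualities is not None else None
        if q is not None and q < min_base_quality:
            continue
        p = piles[asn.locus_id]
        p["depth"] += 1
        if base == var.ref_allele:
            p["ref"] += 1
        elif base == var.alt_allele:
            p["alt"] += 1
        else:
            p["other"] += 1
    return {
        lid: PileupCounts(
            locus_id=lid, depth=p["depth"], ref_count=p["ref"],
            alt_count=p["alt"], other_count=p["other"],
        )
        for lid, p in piles.items()
    }


@dataclass(frozen=True)
class CallThresholds:
    """Allele-fraction bands mapping a pileup to a diploid genotype call.

    Conservative defaults for inbred-line material: calls outside the
    homozygote tails and the heterozygote band are AMBIGUOUS rather
    than forced.
    """

    min_depth: int = 50
    t_ref: float = 0.10
    t_alt: float = 0.90
    t_het_lo: float = 0.35
    t_het_hi: float = 0.65


def call_individual_genotype(
    counts: PileupCounts,
    thresholds: CallThresholds = CallThresholds(),
) -> Genotype:
    """Threshold the alt-allele fraction of one individual's pileup."""
    informative = counts.ref_count + counts.alt_count
    if counts.depth < thresholds.min_depth or informative == 0:
        return Genotype.MISSING
    frac = counts.alt_count / informative
    if frac <= thresholds.t_ref:
        return Genotype.REF_HOM
    if frac >= thresholds.t_alt:
        return Genotype.ALT_HOM
    if thresholds.t_het_lo <= frac <= thresholds.t_het_hi:
        return Genotype.HET
    return Genotype.AMBIGUOUS


def estimate_pool_fraction(
    counts: PileupCounts,
    assumption: PoolAssumption = PoolAssumption.INBRED_HOMOZYGOUS,
    confidence: float = 0.95,
) -> PoolEstimate:
    """Estimate the percentage of mutation-carrying plants in a DNA pool.

    The alt-allele frequency ``p`` is the alt fraction of informative
    (ref+alt) reads, with a Wilson score confidence interval. Under the
    inbred-homozygous assumption the carrier fraction equals ``p``;
    under Hardy-Weinberg it is ``1 - (1-p)^2``, with the CI endpoints
    mapped through the same monotone transform.
    """
    informative = counts.ref_count + counts.alt_count
    if informative == 0:
        raise ConfigurationError(f"{counts.locus_id}: no informative (ref/alt) reads in pool")
    p = counts.alt_count / informative
    lo, hi = proportion_confint(counts.alt_count, informative, alpha=1 - confidence, method="wilson")
    lo, hi = max(0.0, float(lo)), min(1.0, float(hi))
    # statsmodels leaves float dust at the boundaries (e.g. 2e-17 at x=0)
    if counts.alt_count == 0:
        lo = 0.0
    if counts.alt_count == informative:
        hi = 1.0
    lo, hi = min(lo, p), max(hi, p)
    if assumption is PoolAssumption.INBRED_HOMOZYGOUS:
        frac, flo, fhi = p, lo, hi
    else:
        frac, flo, fhi = (1 - (1 - x) ** 2 for x in (p, lo, hi))
    return PoolEstimate(
        locus_id=counts.locus_id,
        plant_fraction_percent=100.0 * frac,
        ci_low=100.0 * flo,
        ci_high=100.0 * fhi,
        assumption=assumption,
        allele_frequency=p,
        informative_depth=informative,
    )


# ---------------------------------------------------------------------------
# FASTQ I/O (Sanger/Phred+33 encoding, via Biopython)
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> ReadSet:
    reads = [
        Read(
            id=rec.id,
            bases=str(rec.seq).upper(),
            qualities=tuple(rec.letter_annotations["phred_quality"])
            if "phred_quality" in rec.letter_annotations
            else None,
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]
    return ReadSet(reads=reads)


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    records = []
    for r in readset:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(
            r.qualities if r.qualities is not None else [40] * len(r.bases)
        )
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
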