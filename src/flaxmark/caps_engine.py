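"""CAPS (cleaved amplified polymorphic sequences) marker engine.

A CAPS marker exploits a SNP that creates or destroys a restriction
site inside a PCR amplicon: digestion of the amplicon then yields an
allele-diagnostic gel band pattern. Homozygotes show the pattern of
their single allele; heterozygotes show the union of both patterns —
for the flax *FAD3* markers, three bands (the uncut amplicon plus its
two restriction fragments).

This module models restriction enzymes as (IUPAC recognition motif,
top-strand cut offset) pairs, scans both strands for sites, simulates
digestion, validates and designs markers, and calls genotypes from
observed band lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .core_model import Amplicon, Genotype, SnpVariant, apply_allele, iupac_to_regex, reverse_complement
from .exceptions import (
    DesignError,
    NotACapsCandidateError,
    UndefinedPatternError,
    VariantTableError,
)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type-II restriction enzyme.

    ``cut_offset`` is the number of motif bases 5' (left) of the
    top-strand cleavage point: HaeIII GG^CC -> 2, BstMBI ^GATC -> 0.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", self.recognition.upper())
        if len(self.recognition) < 4:
            raise ValueError(f"{self.name}: recognition motif must be >= 4 bases")
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ValueError(f"{self.name}: cut offset {self.cut_offset} outside motif bounds")

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition


HAEIII = RestrictionEnzyme(name="HaeIII", recognition="GGCC", cut_offset=2)
BSTMBI = RestrictionEnzyme(name="BstMBI", recognition="GATC", cut_offset=0)

#: Enzymes always available without an external library file.
BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {e.name: e for e in (HAEIII, BSTMBI)}


@dataclass(frozen=True)
class RecognitionSite:
    """One motif occurrence: 1-based inclusive span and top-strand cut position."""

    start: int
    end: int
    strand: str          # '+' or '-'
    cut_position: int    # bases of the top strand left of the cut

    def overlaps(self, offset: int) -> bool:
        return self.start <= offset <= self.end


@dataclass(frozen=True)
class DigestResult:
    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]   # sorted descending


@dataclass(frozen=True)
class BandPattern:
    """Multiset of fragment lengths; distinct lengths define the band count."""

    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("band pattern must be non-empty")
        object.__setattr__(self, "lengths", tuple(sorted(self.lengths, reverse=True)))

    @property
    def bands(self) -> tuple[int, ...]:
        """Distinct band lengths, longest first (what a gel resolves)."""
        return tuple(sorted(set(self.lengths), reverse=True))

    @property
    def band_count(self) -> int:
        return len(self.bands)

    def union(self, other: "BandPattern") -> "BandPattern":
        return BandPattern(lengths=tuple(set(self.lengths) | set(other.lengths)))


@dataclass
class CapsMarker:
    locus_id: str
    enzyme: RestrictionEnzyme
    amplicon: Amplicon
    variant: SnpVariant
    allele_with_site: str               # 'REF' or 'ALT'
    pattern_ref_hom: BandPattern
    pattern_alt_hom: BandPattern
    pattern_het: BandPattern
    valid: bool = True
    confounded_extra_sites: bool = False
    unresolvable_bands: bool = False


def find_site_spans(seq: str, enzyme: RestrictionEnzyme) -> list[RecognitionSite]:
    """All recognition-site occurrences on either strand, as plus-strand spans.

    Minus-strand occurrences are located by scanning the plus strand for
    the motif's reverse complement; their top-strand cut falls
    ``len(motif) - cut_offset`` bases into the span. Palindromic motifs
    are counted once (both strands give the same span; blunt cutters
    give the same cut, and for staggered cutters the top-strand cut is
    taken from the plus-strand reading). Overlapping occurrences are
    all reported.
    """
    seq = seq.upper()
    n = len(seq)
    motif = enzyme.recognition
    m = len(motif)
    sites: dict[tuple[int, int], RecognitionSite] = {}
    plus_re = iupac_to_regex(motif)
    # re.finditer skips overlapping hits, so anchor-match at every offset.
    for i in range(n - m + 1):
        if plus_re.match(seq, i, i + m):
            span = (i + 1, i + m)
            sites[span] = RecognitionSite(
                start=span[0], end=span[1], strand="+", cut_position=i + enzyme.cut_offset
            )
    if not enzyme.is_palindromic:
        minus_re = iupac_to_regex(reverse_complement(motif))
        for i in range(n - m + 1):
            if minus_re.match(seq, i, i + m):
                span = (i + 1, i + m)
                if span not in sites:
                    sites[span] = RecognitionSite(
                        start=span[0], end=span[1], strand="-",
                        cut_position=i + (m - enzyme.cut_offset),
                    )
    return sorted(sites.values(), key=lambda s: (s.start, s.strand))


def find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Sorted top-strand cut positions strictly inside the sequence.

    A cut position ``p`` means the top strand is severed after base ``p``
    (1-based); cuts at 0 or at the sequence end produce no new fragment
    and are dropped.
    """
    if not seq:
        raise ValueError("cannot scan an empty sequence")
    n = len(seq)
    cuts = {s.cut_position for s in find_site_spans(seq, enzyme)}
    return sorted(p for p in cuts if 0 < p < n)


def digest(seq: str, enzyme: RestrictionEnzyme) -> DigestResult:
    """Simulate a complete digest; fragments are the inter-cut intervals."""
    cuts = find_sites(seq, enzyme)
    bounds = [0, *cuts, len(seq)]
    fragments = tuple(sorted((b - a for a, b in zip(bounds, bounds[1:])), reverse=True))
    return DigestResult(cut_positions=tuple(cuts), fragment_lengths=fragments)


def predict_band_pattern(marker: CapsMarker, genotype: Genotype) -> BandPattern:
    """Expected gel pattern for a genotype: allele digest, or their union for HET."""
    if genotype is Genotype.REF_HOM:
        return marker.pattern_ref_hom
    if genotype is Genotype.ALT_HOM:
        return marker.pattern_alt_hom
    if genotype is Genotype.HET:
        return marker.pattern_het
    raise UndefinedPatternError(f"no band pattern is defined for genotype {genotype.name}")


#: Two expected bands closer than max(10 bp, 8% of the larger) cannot be
#: told apart on a 2% agarose gel and make the marker unreliable.
def bands_resolvable(a: int, b: int, *, min_sep_bp: int = 10, min_sep_rel: float = 0.08) -> bool:
    hi, lo = max(a, b), min(a, b)
    return (hi - lo) >= max(min_sep_bp, min_sep_rel * hi)


def _has_unresolvable_pair(pattern: BandPattern) -> bool:
    bands = pattern.bands
    return any(
        not bands_resolvable(bands[i], bands[j])
        for i in range(len(bands))
        for j in range(i + 1, len(bands))
    )


def validate_caps_marker(
    amp: Amplicon,
    variant: SnpVariant,
    enzyme: RestrictionEnzyme,
) -> CapsMarker:
    """Build a marker for an amplicon/variant/enzyme combination.

    The SNP must change the enzyme's site content (create or destroy at
    least one recognition site); otherwise
    :class:`NotACapsCandidateError`. The marker is flagged
    ``confounded_extra_sites`` when sites not overlapping the SNP exist
    (every genotype is cut, so patterns blur) and ``unresolvable_bands``
    when any two expected bands are too close to separate on a gel.
    ``valid`` requires exactly one allele to carry a single,
    SNP-overlapping site and the other allele none.
    """
    ref_seq = apply_allele(amp, variant, "REF")
    alt_seq = apply_allele(amp, variant, "ALT")
    ref_sites = find_site_spans(ref_seq, enzyme)
    alt_sites = find_site_spans(alt_seq, enzyme)
    ref_cuts = {s.cut_position for s in ref_sites}
    alt_cuts = {s.cut_position for s in alt_sites}
    if ref_cuts == alt_cuts:
        raise NotACapsCandidateError(
            f"{variant.locus_id}: {enzyme.name} site content is identical for both alleles"
        )
    off = amp.variant_offset
    ref_overlap = any(s.overlaps(off) for s in ref_sites)
    alt_overlap = any(s.overlaps(off) for s in alt_sites)
    if ref_overlap and not alt_overlap:
        allele_with_site = "REF"
    elif alt_overlap and not ref_overlap:
        allele_with_site = "ALT"
    else:
        # Both or neither overlap but cut sets differ (e.g. SNP shifts a cut).
        allele_with_site = "REF" if len(ref_cuts) > len(alt_cuts) else "ALT"
    confounded = any(not s.overlaps(off) for s in ref_sites) or any(
        not s.overlaps(off) for s in alt_sites
    )
    p_ref = BandPattern(lengths=digest(ref_seq, enzyme).fragment_lengths)
    p_alt = BandPattern(lengths=digest(alt_seq, enzyme).fragment_lengths)
    p_het = p_ref.union(p_alt)
    unresolvable = any(map(_has_unresolvable_pair, (p_ref, p_alt, p_het)))
    cutting = ref_sites if allele_with_site == "REF" else alt_sites
    valid = (not confounded) and (not unresolvable) and len(cutting) == 1
    return CapsMarker(
        locus_id=variant.locus_id, enzyme=enzyme, amplicon=amp, variant=variant,
        allele_with_site=allele_with_site,
        pattern_ref_hom=p_ref, pattern_alt_hom=p_alt, pattern_het=p_het,
        valid=valid, confounded_extra_sites=confounded, unresolvable_bands=unresolvable,
    )


@dataclass(frozen=True)
class DesignConstraints:
    """Amplicon-geometry constraints for marker design.

    Defaults keep products in the 250-300 bp range: short amplicons
    tolerate degraded template DNA and amplify robustly.
    """

    min_len: int = 250
    max_len: int = 300
    min_band_sep: int = 10
    primer_len: int = 20


def design_caps(
    ref,
    variant: SnpVariant,
    enzyme_library: Iterable[RestrictionEnzyme],
    constraints: DesignConstraints = DesignConstraints(),
) -> list[CapsMarker]:
    """Enumerate candidate CAPS markers for a SNP on a reference.

    For each enzyme whose recognition motif overlaps the SNP in exactly
    one allele, an amplicon window roughly centered on the SNP and
    satisfying the length constraints is cut out of the reference, its
    terminal ``primer_len``-mers taken as primer footprints (candidates
    whose footprints are not unique on the reference are dropped), and
    the resulting marker validated. Candidates are returned sorted
    valid-first, then by fewer bands, shorter amplicon and enzyme name.
    """
    seq = ref.bases
    n = len(seq)
    pos0 = variant.position - 1
    if not (0 <= pos0 < n) or seq[pos0] != variant.ref_allele:
        raise DesignError(
            f"{variant.locus_id}: reference base at {variant.chrom_id}:{variant.position} "
            f"does not match {variant.ref_allele!r}"
        )
    candidates: list[CapsMarker] = []
    for enzyme in enzyme_library:
        m = len(enzyme.recognition)
        # Local window large enough to see every motif occurrence over the SNP.
        lo = max(0, pos0 - (m - 1))
        hi = min(n, pos0 + m)
        local_ref = seq[lo:hi]
        local_alt = local_ref[: pos0 - lo] + variant.alt_allele + local_ref[pos0 - lo + 1 :]
        snp_local = pos0 - lo + 1
        ref_over = [s for s in find_site_spans(local_ref, enzyme) if s.overlaps(snp_local)]
        alt_over = [s for s in find_site_spans(local_alt, enzyme) if s.overlaps(snp_local)]
        if bool(ref_over) == bool(alt_over):
            continue
        target_len = min(constraints.max_len, n)
        if target_len < constraints.min_len:
            continue
        # A SNP dead-center would split the amplicon into two nearly equal
        # (gel-unresolvable) fragments, so several off-center placements of
        # the cut site are tried.
        seen_starts: set[int] = set()
        for frac in (0.65, 0.35, 0.5, 0.75, 0.25):
            start0 = min(max(0, pos0 - int(frac * target_len)), n - target_len)
            if start0 in seen_starts or not (start0 <= pos0 < start0 + target_len):
                continue
            seen_starts.add(start0)
            window = seq[start0 : start0 + target_len]
            fwd = window[: constraints.primer_len]
            rev = reverse_complement(window[-constraints.primer_len :])
            if seq.count(fwd) != 1 or seq.count(reverse_complement(rev)) != 1:
                continue
            amp = Amplicon(
                locus_id=variant.locus_id, source_id=ref.id,
                start=start0 + 1, end=start0 + target_len, bases=window,
                primer_fwd=fwd, primer_rev=rev,
                variant_offset=pos0 - start0 + 1,
            )
            try:
                marker = validate_caps_marker(amp, variant, enzyme)
            except NotACapsCandidateError:
                continue
            candidates.append(marker)
    candidates.sort(
        key=lambda mk: (
            not mk.valid,
            mk.pattern_het.band_count,
            len(mk.amplicon),
            mk.enzyme.name,
        )
    )
    return candidates


def call_genotype_from_bands(
    observed: Sequence[float],
    marker: CapsMarker,
    tol: float = 0.05,
    reject_tol: float = 0.15,
) -> Genotype:
    """Call a genotype from measured gel band lengths.

    Observed lengths are matched against the three expected patterns
    under a relative length tolerance ``tol``: every observed band must
    match a distinct expected band and every expected band must be
    observed. Exactly one matching pattern yields its genotype; several
    yield AMBIGUOUS.

    When no pattern passes the strict tolerance, the band *count* — the
    primary diagnostic on a gel, where a heterozygote shows three bands
    — decides: if exactly one pattern has the observed band count and
    its sizes all sit within the looser ``reject_tol``, that genotype
    is called; anything further off is AMBIGUOUS. Gel sizing is
    approximate, so a mildly mis-sized but count-consistent pattern is
    still diagnostic, while a wildly wrong fragment is not.
    """
    if not observed:
        raise ValueError("observed band list is empty")
    obs = sorted(observed, reverse=True)

    def deviation(pattern: BandPattern) -> float | None:
        """Worst relative size error under the sorted 1:1 assignment."""
        exp = pattern.bands
        if len(obs) != len(exp):
            return None
        return max(abs(o - e) / e for o, e in zip(obs, exp))

    scored = [
        (g, deviation(p))
        for g, p in (
            (Genotype.REF_HOM, marker.pattern_ref_hom),
            (Genotype.HET, marker.pattern_het),
            (Genotype.ALT_HOM, marker.pattern_alt_hom),
        )
    ]
    strict = [g for g, d in scored if d is not None and d <= tol]
    if len(strict) == 1:
        return strict[0]
    if len(strict) > 1:
        return Genotype.AMBIGUOUS
    loose = [g for g, d in scored if d is not None and d <= reject_tol]
    return loose[0] if len(loose) == 1 else Genotype.AMBIGUOUS


# ---------------------------------------------------------------------------
# Enzyme-library and observed-band I/O
# ---------------------------------------------------------------------------

def read_enzyme_library(path: str | Path | None = None) -> dict[str, RestrictionEnzyme]:
    """Load enzymes from a TSV (name, recognition, cut_offset); built-ins always included."""
    enzymes = dict(BUILTIN_ENZYMES)
    if path is None:
        return enzymes
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise VariantTableError(f"{path}:{lineno}: expected name, recognition, cut_offset")
            enzymes[fields[0]] = RestrictionEnzyme(
                name=fields[0], recognition=fields[1], cut_offset=int(fields[2])
            )
    return enzymes


def read_observed_bands(path: str | Path) -> list[tuple[str, str, list[float]]]:
    """Read an observed-band TSV: sample_id, locus_id, comma-separated lengths."""
    rows: list[tuple[str, str, list[float]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise VariantTableError(f"{path}:{lineno}: expected sample_id, locus_id, lengths")
            lengths = [float(x) for x in fields[2].split(",") if x.strip()]
            rows.append((fields[0], fields[1], lengths))
    return rows
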