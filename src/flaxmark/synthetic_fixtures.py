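"""Deterministic synthetic test substrate for the three *FAD3* markers.

The real flax genome and primer sequences are not bundled; instead this
module generates loci whose assay geometry reproduces the published
marker outputs exactly. The geometry is back-calculated from the gel
fragment lengths: e.g. the FAD3A exon-1 marker yields 195 + 107 bp
fragments from a 302 bp amplicon, so with HaeIII cutting GG^CC the
motif must sit at amplicon offsets 194-197 and the G-to-A mutation on
the motif base at offset 195 (where it destroys the site). This is a
modeling choice about the synthetic loci, not a claim about the real
genome's motif phasing.

Also provided: seeded simulators for plant populations (heterogeneous
varieties and selfed crosses), amplicon sequencing reads, gel length
measurements and HRM sample curves — with full bookkeeping of the
planted ground truth so downstream callers can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from . import hrm_engine
from .core_model import (
    FAD3_LOCI,
    Amplicon,
    Genotype,
    MultiLocusGenotype,
    ReferenceSequence,
    SnpVariant,
    apply_allele,
    reverse_complement,
    write_fasta,
    write_primer_table,
    write_variant_table,
)
from .caps_engine import BSTMBI, HAEIII, RestrictionEnzyme
from .ampseq_engine import Read, ReadSet
from .genetics import PlantRecord
from .hrm_engine import MeltCurve, ThermoModel

_BASES = np.frombuffer(b"ACGT", dtype="S1")

PRIMER_LEN = 20
FLANK_LEN = 300


@dataclass(frozen=True)
class LocusGeometry:
    """Back-calculated assay geometry of one fixture marker locus."""

    locus_id: str
    amplicon_length: int
    enzyme: RestrictionEnzyme
    motif_start: int     # 1-based offset of the recognition motif in the amplicon
    snp_offset: int      # 1-based offset of the SNP (inside the motif span)
    ref_allele: str
    alt_allele: str
    gene: str
    exon: int
    effect: str


#: The three marker loci. Motif offsets follow from (fragment lengths,
#: enzyme cut offset); the SNP sits on the motif base whose printed
#: substitution destroys the site:
#:   fad3a_ex1: 302 bp, HaeIII cut after 195 -> GGCC at 194-197, G->A at 195
#:   fad3b_ex2: 260 bp, HaeIII cut after 157 -> GGCC at 156-159, C->T at 158
#:   fad3a_ex5: 272 bp, BstMBI cut after 163 -> GATC at 164-167, C->T at 167
FIXTURE_GEOMETRIES: tuple[LocusGeometry, ...] = (
    LocusGeometry("fad3a_ex1", 302, HAEIII, 194, 195, "G", "A", "FAD3A", 1, "Trp->stop"),
    LocusGeometry("fad3b_ex2", 260, HAEIII, 156, 158, "C", "T", "FAD3B", 2, "His->Tyr"),
    LocusGeometry("fad3a_ex5", 272, BSTMBI, 164, 167, "C", "T", "FAD3A", 5, "Arg->stop"),
)

@dataclass
class FixtureLocus:
    geometry: LocusGeometry
    amplicon: Amplicon
    variant: SnpVariant

    @property
    def locus_id(self) -> str:
        return self.geometry.locus_id

    @property
    def enzyme(self) -> RestrictionEnzyme:
        return self.geometry.enzyme

    def allele_sequence(self, allele: str) -> str:
        return apply_allele(self.amplicon, self.variant, allele)


@dataclass
class FixtureSet:
    """One synthetic chromosome carrying the three marker amplicons."""

    seed: int
    reference: ReferenceSequence
    loci: dict[str, FixtureLocus]
    primers: dict[str, tuple[str, str]]

    @property
    def variants(self) -> list[SnpVariant]:
        return [self.loci[l].variant for l in FAD3_LOCI]

    @property
    def amplicons(self) -> list[Amplicon]:
        return [self.loci[l].amplicon for l in FAD3_LOCI]

    def write(self, outdir: str | Path) -> None:
        """Write reference FASTA, variant table, primer TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([self.reference], outdir / "reference.fasta")
        write_variant_table(self.variants, outdir / "variants.vcf")
        write_primer_table(self.primers, outdir / "primers.tsv")


_FORBIDDEN_MOTIFS = ("GGCC", "GATC")


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)].copy()


def _scrub_motifs(
    arr: np.ndarray,
    rng: np.random.Generator,
    protected: set[int],
    motifs: Sequence[str] = _FORBIDDEN_MOTIFS,
) -> None:
    """Re-randomize bases until no forbidden motif remains outside protected spans.

    Both motifs are palindromic, so a plus-strand scan covers both
    strands. Mutates ``arr`` in place; deterministic given the rng.
    """
    n = arr.size
    for _ in range(10_000):
        s = arr.tobytes().decode()
        hit = None
        for motif in motifs:
            start = 0
            while True:
                i = s.find(motif, start)
                if i < 0:
                    break
                span = set(range(i, i + len(motif)))
                if span - protected:
                    hit = sorted(span - protected)
                    break
                start = i + 1
            if hit:
                break
        if hit is None:
            return
        j = hit[rng.integers(0, len(hit))]
        arr[j] = _BASES[rng.integers(0, 4)]
    raise RuntimeError("motif scrubbing did not converge")  # pragma: no cover


def _build_amplicon_bases(rng: np.random.Generator, geom: LocusGeometry) -> str:
    arr = _random_bases(rng, geom.amplicon_length)
    m0 = geom.motif_start - 1
    for k, b in enumerate(geom.enzyme.recognition):
        arr[m0 + k] = b.encode()
    assert arr[geom.snp_offset - 1] == geom.ref_allele.encode()
    protected = set(range(m0, m0 + len(geom.enzyme.recognition)))
    _scrub_motifs(arr, rng, protected)
    # The mutant allele must carry no site at all: the substitution breaks
    # the planted motif and scrubbing already removed every other one.
    alt = arr.copy()
    alt[geom.snp_offset - 1] = geom.alt_allele.encode()
    alt_s = alt.tobytes().decode()
    if any(m in alt_s for m in _FORBIDDEN_MOTIFS):
        raise RuntimeError("mutant allele unexpectedly contains a recognition motif")  # pragma: no cover
    return arr.tobytes().decode()


def build_fixture_loci(seed: int = 7) -> FixtureSet:
    """Generate the synthetic chromosome and the three marker loci.

    Deterministic per seed. Amplicon interiors are random but screened
    so the only GGCC/GATC occurrence is the planted one (and none
    survives in the mutant allele); flanks are screened too, so marker
    design windows extending past an amplicon stay clean. Primer
    footprints are the amplicons' terminal 20-mers, checked unique
    across the chromosome.
    """
    for attempt in range(100):
        rng = np.random.default_rng((seed, attempt))
        parts: list[str] = []
        pos = 0
        loci: dict[str, FixtureLocus] = {}
        primers: dict[str, tuple[str, str]] = {}
        for geom in FIXTURE_GEOMETRIES:
            flank = _random_bases(rng, FLANK_LEN)
            _scrub_motifs(flank, rng, set())
            parts.append(flank.tobytes().decode())
            pos += FLANK_LEN
            bases = _build_amplicon_bases(rng, geom)
            start = pos + 1
            end = pos + geom.amplicon_length
            fwd = bases[:PRIMER_LEN]
            rev = reverse_complement(bases[-PRIMER_LEN:])
            variant = SnpVariant(
                locus_id=geom.locus_id, chrom_id="chrSYN",
                position=pos + geom.snp_offset,
                ref_allele=geom.ref_allele, alt_allele=geom.alt_allele,
                gene=geom.gene, exon=geom.exon, effect=geom.effect,
            )
            amp = Amplicon(
                locus_id=geom.locus_id, source_id="chrSYN",
                start=start, end=end, bases=bases,
                primer_fwd=fwd, primer_rev=rev,
                variant_offset=geom.snp_offset,
            )
            loci[geom.locus_id] = FixtureLocus(geometry=geom, amplicon=amp, variant=variant)
            primers[geom.locus_id] = (fwd, rev)
            parts.append(bases)
            pos += geom.amplicon_length
        tail = _random_bases(rng, FLANK_LEN)
        _scrub_motifs(tail, rng, set())
        parts.append(tail.tobytes().decode())
        chrom = "".join(parts)
        unique = all(
            chrom.count(f) == 1 and chrom.count(reverse_complement(r)) == 1
            for f, r in primers.values()
        )
        if unique:
            return FixtureSet(
                seed=seed,
                reference=ReferenceSequence(id="chrSYN", bases=chrom, description=f"synthetic fixture chromosome seed={seed}"),
                loci=loci,
                primers=primers,
            )
    raise RuntimeError("could not build a chromosome with unique primer sites")  # pragma: no cover


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

class PopulationKind(Enum):
    VARIETY = "variety"
    CROSS = "cross"


@dataclass
class PopulationSpec:
    """A simulated plant population.

    VARIETY: ``size`` plants homozygous at ``founder`` genotypes, each
    independently replaced by a random off-type with probability
    ``off_type_fraction`` (heterogeneous-variety model). CROSS: an F1
    heterozygous at every locus where the two founders differ, then
    ``generations_of_selfing`` rounds of selfing with 1:2:1 segregation
    at heterozygous loci, loci unlinked.
    """

    kind: PopulationKind
    size: int
    founder: MultiLocusGenotype
    founder2: MultiLocusGenotype | None = None
    off_type_fraction: float = 0.0
    generations_of_selfing: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("population size must be positive")
        if not (0.0 <= self.off_type_fraction <= 1.0):
            raise ValueError("off-type fraction must lie in [0, 1]")
        if self.kind is PopulationKind.CROSS and self.founder2 is None:
            raise ValueError("a cross needs two founder genotypes")


@dataclass
class SimulatedPopulation:
    records: list[PlantRecord]
    off_type_ids: list[str]   # generator bookkeeping: the planted off-types


_OFFTYPE_CHOICES = {
    Genotype.REF_HOM: (Genotype.HET, Genotype.ALT_HOM),
    Genotype.ALT_HOM: (Genotype.HET, Genotype.REF_HOM),
}


def _self_offspring(state: Genotype, rng: np.random.Generator) -> Genotype:
    if state is not Genotype.HET:
        return state
    draw = rng.random()
    if draw < 0.25:
        return Genotype.REF_HOM
    if draw < 0.75:
        return Genotype.HET
    return Genotype.ALT_HOM


def simulate_population(spec: PopulationSpec, family_id: str = "pop") -> SimulatedPopulation:
    """Generate plant records with ground-truth bookkeeping; seeded and reproducible."""
    rng = np.random.default_rng(spec.seed)
    records: list[PlantRecord] = []
    off_types: list[str] = []
    if spec.kind is PopulationKind.VARIETY:
        for i in range(spec.size):
            calls = dict(spec.founder.calls)
            plant_id = f"{family_id}_p{i + 1}"
            if rng.random() < spec.off_type_fraction:
                off_types.append(plant_id)
                locus = FAD3_LOCI[rng.integers(0, len(FAD3_LOCI))]
                choices = _OFFTYPE_CHOICES.get(calls[locus], (Genotype.HET,))
                calls[locus] = choices[rng.integers(0, len(choices))]
            records.append(PlantRecord(plant_id, family_id, MultiLocusGenotype(calls=calls)))
    else:
        f1 = {
            locus: (
                spec.founder.calls[locus]
                if spec.founder.calls[locus] is spec.founder2.calls[locus]
                else Genotype.HET
            )
            for locus in spec.founder.calls
        }
        for i in range(spec.size):
            calls = dict(f1)
            for _ in range(spec.generations_of_selfing):
                calls = {locus: _self_offspring(s, rng) for locus, s in calls.items()}
            records.append(
                PlantRecord(f"{family_id}_p{i + 1}", family_id, MultiLocusGenotype(calls=calls))
            )
    return SimulatedPopulation(records=records, off_type_ids=off_types)


# ---------------------------------------------------------------------------
# Pool fixtures emulating the heterogeneous breeding lines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolFixture:
    """A DNA pool of homozygous plants with an exact planted carrier count."""

    name: str
    locus_id: str
    carrier_fraction: float
    n_plants: int = 100


#: Pools mirroring the two published varietal-heterogeneity findings:
#: a g.604-like line where ~25% of plants carry the FAD3A exon-1
#: mutation and a g.582-like line where ~65% carry the FAD3B exon-2 one.
POOL_FIXTURES: dict[str, PoolFixture] = {
    "g604": PoolFixture(name="g604", locus_id="fad3a_ex1", carrier_fraction=0.25),
    "g582": PoolFixture(name="g582", locus_id="fad3b_ex2", carrier_fraction=0.65),
}


def build_pool(fixture: PoolFixture) -> SimulatedPopulation:
    """Materialize a pool with exactly round(n * fraction) homozygous carriers."""
    n_carriers = round(fixture.n_plants * fixture.carrier_fraction)
    records = []
    for i in range(fixture.n_plants):
        calls = {l: Genotype.REF_HOM for l in FAD3_LOCI}
        if i < n_carriers:
            calls[fixture.locus_id] = Genotype.ALT_HOM
        records.append(
            PlantRecord(f"{fixture.name}_p{i + 1}", fixture.name, MultiLocusGenotype(calls=calls))
        )
    return SimulatedPopulation(records=records, off_type_ids=[])


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    fixtures: FixtureSet,
    plants: Sequence[PlantRecord],
    loci: Sequence[str],
    n_reads: int,
    read_length: int = 150,
    error_rate: float = 0.005,
    seed: int = 0,
) -> ReadSet:
    """Simulate amplicon-sequencing reads from a set of plants.

    Each read picks a plant, a locus and a strand uniformly, a start
    uniform over the amplicon's ungapped windows, and the allele strand
    of the plant's genotype (heterozygotes contribute either allele
    with probability 1/2). Substitution errors occur per base at
    ``error_rate``; Phred qualities encode that rate. Deterministic
    per seed.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    qual = 40 if error_rate <= 0 else min(40, round(-10 * np.log10(error_rate)))
    allele_seqs = {
        (locus, allele): fixtures.loci[locus].allele_sequence(allele)
        for locus in loci
        for allele in ("REF", "ALT")
    }
    for locus in loci:
        if read_length > len(fixtures.loci[locus].amplicon):
            raise ValueError(f"read length {read_length} exceeds amplicon {locus}")
    reads = []
    for i in range(n_reads):
        plant = plants[rng.integers(0, len(plants))]
        locus = loci[rng.integers(0, len(loci))]
        state = plant.genotype.get(locus)
        if state is Genotype.ALT_HOM:
            allele = "ALT"
        elif state is Genotype.HET:
            allele = "ALT" if rng.random() < 0.5 else "REF"
        else:
            allele = "REF"
        template = allele_seqs[(locus, allele)]
        start = int(rng.integers(0, len(template) - read_length + 1))
        frag = np.frombuffer(template[start : start + read_length].encode(), dtype="S1").copy()
        if error_rate > 0:
            errs = np.nonzero(rng.random(read_length) < error_rate)[0]
            for j in errs:
                alternatives = [b for b in _BASES if b != frag[j]]
                frag[j] = alternatives[rng.integers(0, 3)]
        bases = frag.tobytes().decode()
        if rng.random() < 0.5:
            bases = reverse_complement(bases)
        reads.append(Read(id=f"read_{i + 1}", bases=bases, qualities=(qual,) * read_length))
    return ReadSet(reads=reads)


# ---------------------------------------------------------------------------
# Gel and HRM measurement simulation
# ---------------------------------------------------------------------------

def simulate_gel_observation(
    pattern_lengths: Sequence[int],
    sigma_rel: float,
    seed: int = 0,
) -> list[float]:
    """Noisy gel measurement: lognormal length error, shuffled band order."""
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be non-negative")
    rng = np.random.default_rng(seed)
    lengths = np.asarray(pattern_lengths, dtype=float)
    if sigma_rel > 0:
        lengths = lengths * rng.lognormal(mean=0.0, sigma=sigma_rel, size=lengths.size)
    order = rng.permutation(lengths.size)
    return [float(x) for x in lengths[order]]


def simulate_hrm_sample(
    fixtures: FixtureSet,
    locus_id: str,
    genotype: Genotype,
    noise_sigma: float = 0.0,
    seed: int = 0,
    model: ThermoModel = hrm_engine.DEFAULT_MODEL,
) -> MeltCurve:
    """Simulated sample melt curve: genotype species + Gaussian noise, renormalized."""
    locus = fixtures.loci[locus_id]
    species = hrm_engine.melt_species_for_genotype(locus.amplicon, locus.variant, genotype, model)
    curve = hrm_engine.simulate_melt_curve(species)
    values = curve.values
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, size=values.size)
    return hrm_engine.normalize_curve(MeltCurve(grid=curve.grid, values=values))
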