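"""Genotype-to-phenotype decision logic for flax breeding.

Linolenic-acid (LIN) seed-oil classes follow from the state of the two
desaturase genes: *FAD3A* is inactivated by a homozygous nonsense
mutation in exon 1 or exon 5; *FAD3B* by a homozygous substitution in
exon 2. Both genes inactivated gives low-LIN oil (about 5%), exactly
one gives medium LIN (30-40%), neither (with no heterozygosity) the
high-LIN wild type (more than 50%). Plants heterozygous at a decisive
locus still segregate and get no phenotype prediction.

The module also implements the two selection workflows built on the
markers: choosing F3 families fixed for a target LIN class, and
purifying heterogeneous varieties by discarding off-type plants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core_model import FAD3_LOCI, Genotype, MultiLocusGenotype
from .exceptions import IndeterminateGenotypeError, VariantTableError

#: Loci inactivating each gene; either FAD3A locus suffices on its own.
GENE_LOCI: Mapping[str, tuple[str, ...]] = {
    "FAD3A": ("fad3a_ex1", "fad3a_ex5"),
    "FAD3B": ("fad3b_ex2",),
}


class LinClass(Enum):
    LOW = "LOW"            # both genes knocked out, ~5% LIN
    MEDIUM = "MEDIUM"      # exactly one gene knocked out, 30-40% LIN
    HIGH = "HIGH"          # wild type at both genes, >50% LIN
    SEGREGATING = "SEGREGATING"  # heterozygous at a decisive locus

    @property
    def nominal_range(self) -> str:
        return {
            "LOW": "about 5%",
            "MEDIUM": "30-40%",
            "HIGH": "more than 50%",
            "SEGREGATING": "not predictable (segregating)",
        }[self.value]


class GeneStatus(Enum):
    INACTIVATED = "INACTIVATED"
    ACTIVE = "ACTIVE"
    SEGREGATING = "SEGREGATING"
    UNKNOWN = "UNKNOWN"


class LocusStatus(Enum):
    FIXED_REF = "FIXED_REF"
    FIXED_ALT = "FIXED_ALT"
    SEGREGATING = "SEGREGATING"
    UNKNOWN = "UNKNOWN"


@dataclass
class PlantRecord:
    plant_id: str
    family_id: str
    genotype: MultiLocusGenotype

    def __post_init__(self) -> None:
        missing = [l for l in FAD3_LOCI if l not in self.genotype.calls]
        if missing:
            raise VariantTableError(f"plant {self.plant_id!r}: loci absent from record: {missing}")


@dataclass
class FamilySummary:
    family_id: str
    locus_status: dict[str, LocusStatus]
    n_members: int
    selected: bool = False
    target: LinClass | None = None


@dataclass
class ExclusionReason:
    plant_id: str
    locus_id: str
    kind: str   # 'wrong_allele' | 'heterozygous' | 'missing'


def _gene_status(g: MultiLocusGenotype, gene: str) -> GeneStatus:
    """Aggregate a gene's loci: any homozygous mutation inactivates it
    outright (fixation at one locus is not undone by segregation at the
    other); otherwise heterozygosity means segregating and missing or
    ambiguous evidence means unknown."""
    states = [g.get(l) for l in GENE_LOCI[gene]]
    if any(s is Genotype.ALT_HOM for s in states):
        return GeneStatus.INACTIVATED
    if any(s is Genotype.HET for s in states):
        return GeneStatus.SEGREGATING
    if any(s in (Genotype.MISSING, Genotype.AMBIGUOUS) for s in states):
        return GeneStatus.UNKNOWN
    return GeneStatus.ACTIVE


def classify_lin(g: MultiLocusGenotype) -> LinClass:
    """Map a three-locus genotype to its predicted LIN seed-oil class."""
    a = _gene_status(g, "FAD3A")
    b = _gene_status(g, "FAD3B")
    if GeneStatus.UNKNOWN in (a, b):
        raise IndeterminateGenotypeError(
            "cannot classify: missing or ambiguous call at a decisive locus"
        )
    if GeneStatus.SEGREGATING in (a, b):
        return LinClass.SEGREGATING
    if a is GeneStatus.INACTIVATED and b is GeneStatus.INACTIVATED:
        return LinClass.LOW
    if a is GeneStatus.INACTIVATED or b is GeneStatus.INACTIVATED:
        return LinClass.MEDIUM
    return LinClass.HIGH


def locus_status(members: Sequence[MultiLocusGenotype], locus_id: str) -> LocusStatus:
    """Fixation state of one locus across a family's genotyped members."""
    states = [m.get(locus_id) for m in members]
    known = [s for s in states if s not in (Genotype.MISSING, Genotype.AMBIGUOUS)]
    if not known:
        return LocusStatus.UNKNOWN
    if any(s is Genotype.HET for s in known):
        return LocusStatus.SEGREGATING
    if all(s is Genotype.REF_HOM for s in known):
        return LocusStatus.FIXED_REF
    if all(s is Genotype.ALT_HOM for s in known):
        return LocusStatus.FIXED_ALT
    return LocusStatus.SEGREGATING   # mixed homozygotes


def summarize_family(
    family_id: str, members: Sequence[MultiLocusGenotype]
) -> FamilySummary:
    if not members:
        raise ValueError(f"family {family_id!r} has no genotyped members")
    return FamilySummary(
        family_id=family_id,
        locus_status={l: locus_status(members, l) for l in FAD3_LOCI},
        n_members=len(members),
    )


def _family_matches_target(summary: FamilySummary, target: LinClass) -> bool:
    st = summary.locus_status
    a_fixed_alt = [st[l] is LocusStatus.FIXED_ALT for l in GENE_LOCI["FAD3A"]]
    a_fixed_ref = [st[l] is LocusStatus.FIXED_REF for l in GENE_LOCI["FAD3A"]]
    b_fixed_alt = st["fad3b_ex2"] is LocusStatus.FIXED_ALT
    b_fixed_ref = st["fad3b_ex2"] is LocusStatus.FIXED_REF
    # Any segregating or unknown locus disqualifies a family outright.
    if any(s in (LocusStatus.SEGREGATING, LocusStatus.UNKNOWN) for s in st.values()):
        return False
    a_inactive = any(a_fixed_alt)
    a_wildtype = all(a_fixed_ref)
    if target is LinClass.LOW:
        return a_inactive and b_fixed_alt
    if target is LinClass.MEDIUM:
        return (a_inactive and b_fixed_ref) or (a_wildtype and b_fixed_alt)
    if target is LinClass.HIGH:
        return a_wildtype and b_fixed_ref
    return False


def select_families(
    families: Mapping[str, Sequence[MultiLocusGenotype]],
    target: LinClass,
) -> list[FamilySummary]:
    """Select F3 families fixed for the genotype producing the target class.

    A family qualifies only when every locus is fixed (all non-missing
    members identical homozygotes): the loci the target requires are
    fixed for the mutation, the rest fixed wild-type. For the MEDIUM
    target either gene may carry the fixed mutation. Segregating
    families are excluded — their seed would not breed true.
    """
    out = []
    for family_id, members in families.items():
        summary = summarize_family(family_id, members)
        summary.target = target
        summary.selected = _family_matches_target(summary, target)
        out.append(summary)
    return out


def purify_variety(
    records: Sequence[PlantRecord],
    desired: MultiLocusGenotype,
) -> tuple[list[PlantRecord], list[tuple[PlantRecord, ExclusionReason]]]:
    """Split plants into typical (kept) and off-type (excluded) sets.

    A plant is kept iff it matches the desired homozygous genotype at
    every locus; excluded plants are annotated with the first failing
    locus and why it failed (wrong allele, heterozygous, or missing).
    """
    for locus_id, state in desired.calls.items():
        if state not in (Genotype.REF_HOM, Genotype.ALT_HOM):
            raise ValueError(f"desired genotype at {locus_id} must be homozygous, got {state.name}")
    kept: list[PlantRecord] = []
    excluded: list[tuple[PlantRecord, ExclusionReason]] = []
    for rec in records:
        reason = None
        for locus_id in FAD3_LOCI:
            want = desired.get(locus_id)
            have = rec.genotype.get(locus_id)
            if have is want:
                continue
            if have is Genotype.HET:
                kind = "heterozygous"
            elif have in (Genotype.MISSING, Genotype.AMBIGUOUS):
                kind = "missing"
            else:
                kind = "wrong_allele"
            reason = ExclusionReason(plant_id=rec.plant_id, locus_id=locus_id, kind=kind)
            break
        if reason is None:
            kept.append(rec)
        else:
            excluded.append((rec, reason))
    return kept, excluded


# ---------------------------------------------------------------------------
# Genotype-table I/O: plant_id, family_id, then one RR/RA/AA/NN column per locus
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | Path) -> list[PlantRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 + len(FAD3_LOCI):
                raise VariantTableError(
                    f"{path}:{lineno}: expected plant_id, family_id and {len(FAD3_LOCI)} genotype columns"
                )
            calls = {
                locus: Genotype.from_code(code)
                for locus, code in zip(FAD3_LOCI, fields[2:])
            }
            records.append(
                PlantRecord(plant_id=fields[0], family_id=fields[1], genotype=MultiLocusGenotype(calls=calls))
            )
    return records


def write_genotype_table(records: Iterable[PlantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#plant_id\tfamily_id\t" + "\t".join(FAD3_LOCI) + "\n")
        for rec in records:
            codes = "\t".join(rec.genotype.get(l).code for l in FAD3_LOCI)
            fh.write(f"{rec.plant_id}\t{rec.family_id}\t{codes}\n")
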