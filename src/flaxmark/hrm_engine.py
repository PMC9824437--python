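"""High-resolution melting (HRM) engine.

HRM genotyping melts a saturating-dye-stained amplicon over a fine
temperature ramp and compares the sample's fluorescence decay curve
with the curves of reference standards: one carrying the mutation, one
without it, and a 1:1 mixture of the two. A sample resembling the
mutant standard is a homozygous carrier; resembling the wild-type
standard, a non-carrier; resembling the mixture (where heteroduplexes
with a destabilizing internal mismatch form), a heterozygote.

The simulation uses nearest-neighbor (NN) duplex thermodynamics
(SantaLucia unified parameters, Owczarzy-style monovalent-salt
correction) to place each duplex species' melting temperature, sums
logistic melting transitions weighted by species fractions, and
classifies samples by root-mean-square distance to the standards on
the instrument's 65-90 degC, 0.1-degC grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_model import Amplicon, Genotype, SnpVariant, apply_allele
from .exceptions import (
    AmbiguousBaseError,
    DegenerateCurveError,
    GridMismatchError,
    UndefinedPatternError,
)

R_GAS = 1.987  # cal / (mol K)

#: SantaLucia (1998) unified NN parameters: stack -> (dH kcal/mol, dS cal/mol/K).
NN_UNIFIED: Mapping[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
#: Duplex-initiation terms for terminal base pairs.
INIT_TERMINAL_GC = (0.1, -2.8)
INIT_TERMINAL_AT = (2.3, 4.1)

#: Complementary stacks read off the other strand share parameters.
_STACK_EQUIV = {
    "TT": "AA", "TG": "CA", "AC": "GT", "AG": "CT", "TC": "GA", "CC": "GG",
}


def _stack_params(dinuc: str, table: Mapping[str, tuple[float, float]]) -> tuple[float, float]:
    if dinuc in table:
        return table[dinuc]
    return table[_STACK_EQUIV[dinuc]]


@dataclass(frozen=True)
class ThermoModel:
    """NN parameter set plus solution conditions.

    ``salt_molar`` is the total monovalent cation concentration and
    ``strand_molar`` the total strand concentration; defaults emulate
    ordinary PCR-buffer conditions (50 mM monovalent, 250 nM strands).
    """

    nn_table: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(NN_UNIFIED))
    init_gc: tuple[float, float] = INIT_TERMINAL_GC
    init_at: tuple[float, float] = INIT_TERMINAL_AT
    salt_molar: float = 0.05
    strand_molar: float = 2.5e-7

    def __post_init__(self) -> None:
        missing = set(NN_UNIFIED) - set(self.nn_table)
        if missing:
            raise ValueError(f"NN table missing stacks: {sorted(missing)}")
        if self.salt_molar <= 0 or self.strand_molar <= 0:
            raise ValueError("salt and strand concentrations must be positive")


DEFAULT_MODEL = ThermoModel()


def duplex_tm(seq: str, model: ThermoModel = DEFAULT_MODEL) -> float:
    """NN melting temperature (degC) of a perfectly matched duplex.

    Tm(1 M Na+) = dH / (dS + R ln(C_T/4)), then corrected to the
    model's monovalent-salt concentration with the Owczarzy (2004)
    GC-dependent reciprocal-temperature correction.
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("duplex Tm needs at least 8 bases")
    bad = set(seq) - set("ACGT")
    if bad:
        raise AmbiguousBaseError(f"ambiguous bases {sorted(bad)} in duplex sequence")
    dh = 0.0  # kcal/mol
    ds = 0.0  # cal/mol/K
    for a, b in zip(seq, seq[1:]):
        h, s = _stack_params(a + b, model.nn_table)
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = model.init_gc if terminal in "GC" else model.init_at
        dh += h
        ds += s
    tm_1m = (dh * 1000.0) / (ds + R_GAS * math.log(model.strand_molar / 4.0))
    f_gc = (seq.count("G") + seq.count("C")) / len(seq)
    ln_na = math.log(model.salt_molar)
    inv_tm = 1.0 / tm_1m + (4.29 * f_gc - 3.95) * 1e-5 * ln_na + 9.40e-6 * ln_na * ln_na
    return 1.0 / inv_tm - 273.15


# ---------------------------------------------------------------------------
# Melt curves on the fixed instrument grid
# ---------------------------------------------------------------------------

GRID_START = 65.0
GRID_END = 90.0
GRID_STEP = 0.1
GRID_POINTS = 251


def temperature_grid() -> np.ndarray:
    """The instrument ramp: 65.0-90.0 degC inclusive at 0.1-degC steps (251 points)."""
    return GRID_START + GRID_STEP * np.arange(GRID_POINTS)


@dataclass
class MeltCurve:
    """Relative fluorescence over the shared temperature grid."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise GridMismatchError("grid and values have different lengths")

    def same_grid(self, other: "MeltCurve") -> bool:
        return self.grid.shape == other.grid.shape and bool(np.allclose(self.grid, other.grid))


@dataclass(frozen=True)
class DuplexSpecies:
    """One duplex population in the melt: label, molar fraction and its Tm."""

    label: str
    fraction: float
    tm: float


@dataclass
class HrmStandardSet:
    """The three reference curves a sample is compared against."""

    ref_hom: MeltCurve
    alt_hom: MeltCurve
    het_mix: MeltCurve


@dataclass
class HrmCall:
    genotype: Genotype
    distances: dict[str, float]
    margin: float


#: A single internal mismatch destabilizes a heteroduplex by a few degC;
#: a fixed penalty avoids needing mismatch-specific NN tables.
DEFAULT_MISMATCH_PENALTY = 3.0
#: Logistic melting-transition scale (degC).
DEFAULT_TRANSITION_WIDTH = 0.9
#: Pre-/post-melt normalization windows (degC), at the grid extremes.
DEFAULT_PRE_WINDOW = (65.0, 67.0)
DEFAULT_POST_WINDOW = (88.0, 90.0)
#: Relative margin below which the two best standards are too close to call.
DEFAULT_AMBIGUITY_MARGIN = 0.1


def melt_species_for_genotype(
    amplicon: Amplicon,
    variant: SnpVariant,
    genotype: Genotype,
    model: ThermoModel = DEFAULT_MODEL,
    mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY,
) -> list[DuplexSpecies]:
    """Duplex species present after denature/reanneal of a genotype's PCR product.

    Homozygotes contribute a single homoduplex. A heterozygote's two
    allele strands reanneal combinatorially into four equimolar
    species: two homoduplexes at their NN Tm and two heteroduplexes at
    the mean homoduplex Tm minus the mismatch penalty.
    """
    ref_seq = apply_allele(amplicon, variant, "REF")
    alt_seq = apply_allele(amplicon, variant, "ALT")
    if genotype is Genotype.REF_HOM:
        return [DuplexSpecies("ref/ref", 1.0, duplex_tm(ref_seq, model))]
    if genotype is Genotype.ALT_HOM:
        return [DuplexSpecies("alt/alt", 1.0, duplex_tm(alt_seq, model))]
    if genotype is Genotype.HET:
        tm_ref = duplex_tm(ref_seq, model)
        tm_alt = duplex_tm(alt_seq, model)
        tm_het = 0.5 * (tm_ref + tm_alt) - mismatch_penalty
        return [
            DuplexSpecies("ref/ref", 0.25, tm_ref),
            DuplexSpecies("alt/alt", 0.25, tm_alt),
            DuplexSpecies("ref/alt", 0.25, tm_het),
            DuplexSpecies("alt/ref", 0.25, tm_het),
        ]
    raise UndefinedPatternError(f"no melt species for genotype {genotype.name}")


def simulate_melt_curve(
    species: Sequence[DuplexSpecies],
    grid: np.ndarray | None = None,
    width: float = DEFAULT_TRANSITION_WIDTH,
    normalize: bool = True,
) -> MeltCurve:
    """Fraction-weighted sum of logistic melting transitions.

    Each species contributes ``fraction / (1 + exp((T - Tm)/width))``;
    with ``normalize`` the summed curve is min-max rescaled to [0, 1]
    on the grid.
    """
    if not species:
        raise ValueError("species list is empty")
    total = sum(s.fraction for s in species)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"species fractions sum to {total}, expected 1")
    grid = temperature_grid() if grid is None else np.asarray(grid, dtype=float)
    values = np.zeros_like(grid)
    for s in species:
        values += s.fraction / (1.0 + np.exp((grid - s.tm) / width))
    if normalize:
        lo, hi = values.min(), values.max()
        if hi - lo < 1e-12:
            raise DegenerateCurveError("simulated curve has zero dynamic range on the grid")
        values = (values - lo) / (hi - lo)
    return MeltCurve(grid=grid, values=values)


def normalize_curve(
    curve: MeltCurve,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    post_window: tuple[float, float] = DEFAULT_POST_WINDOW,
) -> MeltCurve:
    """Standard HRM pre-/post-melt normalization.

    Affine rescale so the mean over the pre-melt window is 1 and over
    the post-melt window is 0, then clip to [0, 1]. A curve with no
    difference between the windows is degenerate.
    """
    g, v = curve.grid, curve.values
    pre = (g >= pre_window[0]) & (g <= pre_window[1])
    post = (g >= post_window[0]) & (g <= post_window[1])
    if not pre.any() or not post.any():
        raise GridMismatchError("normalization windows fall outside the curve grid")
    pre_mean = float(v[pre].mean())
    post_mean = float(v[post].mean())
    if abs(pre_mean - post_mean) < 1e-12:
        raise DegenerateCurveError("curve has no dynamic range between the normalization windows")
    scaled = (v - post_mean) / (pre_mean - post_mean)
    return MeltCurve(grid=g, values=np.clip(scaled, 0.0, 1.0))


def average_replicates(curves: Sequence[MeltCurve]) -> MeltCurve:
    """Pointwise mean of replicate curves (reactions are run in triplicate)."""
    if not curves:
        raise ValueError("no replicate curves given")
    first = curves[0]
    for c in curves[1:]:
        if not first.same_grid(c):
            raise GridMismatchError("replicate curves are on different grids")
    return MeltCurve(grid=first.grid, values=np.mean([c.values for c in curves], axis=0))


def make_standard_set(
    amplicon: Amplicon,
    variant: SnpVariant,
    model: ThermoModel = DEFAULT_MODEL,
    mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY,
    width: float = DEFAULT_TRANSITION_WIDTH,
) -> HrmStandardSet:
    """Simulated curves for the mutation-free standard, the mutant standard
    and their 1:1 mixture (which reanneals into the heteroduplex-containing
    species set that a true heterozygote also produces)."""
    curves = {}
    for g, key in ((Genotype.REF_HOM, "ref_hom"), (Genotype.ALT_HOM, "alt_hom"), (Genotype.HET, "het_mix")):
        species = melt_species_for_genotype(amplicon, variant, g, model, mismatch_penalty)
        curves[key] = normalize_curve(simulate_melt_curve(species, width=width))
    return HrmStandardSet(**curves)


_STANDARD_GENOTYPE = {
    "ref_hom": Genotype.REF_HOM,
    "het_mix": Genotype.HET,
    "alt_hom": Genotype.ALT_HOM,
}


def classify_hrm(
    sample: MeltCurve,
    standards: HrmStandardSet,
    margin: float = DEFAULT_AMBIGUITY_MARGIN,
) -> HrmCall:
    """Assign the genotype of the nearest standard curve.

    Distance is the root-mean-square difference over the grid after
    pre-/post-melt normalization. When the two smallest distances are
    relatively closer than ``margin`` the call is AMBIGUOUS.
    """
    for std in (standards.ref_hom, standards.alt_hom, standards.het_mix):
        if not sample.same_grid(std):
            raise GridMismatchError("sample and standards are on different temperature grids")
    sample_n = normalize_curve(sample)
    distances = {}
    for label, std in (("ref_hom", standards.ref_hom), ("het_mix", standards.het_mix), ("alt_hom", standards.alt_hom)):
        std_n = normalize_curve(std)
        distances[label] = float(np.sqrt(np.mean((sample_n.values - std_n.values) ** 2)))
    ranked = sorted(distances.items(), key=lambda kv: kv[1])
    (best, d1), (_, d2) = ranked[0], ranked[1]
    rel_margin = (d2 - d1) / d2 if d2 > 0 else 0.0
    genotype = _STANDARD_GENOTYPE[best] if rel_margin >= margin else Genotype.AMBIGUOUS
    return HrmCall(genotype=genotype, distances=distances, margin=rel_margin)


# ---------------------------------------------------------------------------
# Curve I/O: long TSV (temperature, value) or wide TSV (temperature + samples)
# ---------------------------------------------------------------------------

def write_curves_tsv(curves: Mapping[str, MeltCurve], path: str | Path) -> None:
    names = list(curves)
    grid = curves[names[0]].grid
    with open(path, "w") as fh:
        fh.write("temperature\t" + "\t".join(names) + "\n")
        for i, t in enumerate(grid):
            row = "\t".join(f"{curves[n].values[i]:.6f}" for n in names)
            fh.write(f"{t:.1f}\t{row}\n")


def read_curves_tsv(path: str | Path) -> dict[str, MeltCurve]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        names = header[1:]
        temps: list[float] = []
        cols: list[list[float]] = [[] for _ in names]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields[0]:
                continue
            temps.append(float(fields[0]))
            for j, x in enumerate(fields[1:]):
                cols[j].append(float(x))
    grid = np.asarray(temps)
    return {n: MeltCurve(grid=grid, values=np.asarray(col)) for n, col in zip(names, cols)}
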