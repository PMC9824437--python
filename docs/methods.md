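# Methods

This note records the models behind each engine, the defaults that
matter, what the synthetic data does and does not emulate, and the
design choices made where the design was genuinely open.

## Coordinates and sequence model

All coordinates are 1-based and inclusive (GenBank style, matching the
way the *FAD3* mutation positions such as CP027631.1:16092348 are
quoted). IUPAC ambiguity codes are legal in reference sequences and in
enzyme recognition motifs; a variant site itself must be an
unambiguous A/C/G/T, and only single-base substitutions are modeled —
the three target mutations are all SNPs, and indel support would buy
nothing here. Input case is normalized to upper on read.

In-silico PCR (`extract_amplicon`) requires each primer to bind
exactly once (forward on the plus strand, reverse as its reverse
complement downstream); the product spans the two footprints
inclusive, and its ends are the primer sequences themselves, as in a
real reaction where primers are incorporated into the product. By
default binding is exact-match; an optional tolerance (up to a
configurable number of mismatches, none within the 3′-terminal 5
bases, where a mismatch blocks extension) accommodates template
variation, since the markers' primers target conserved regions but
real genotypes drift.

## CAPS engine

A restriction enzyme is a recognition motif plus a top-strand cut
offset: HaeIII is `GGCC` with offset 2 (`GG^CC`, blunt), BstMBI `GATC`
with offset 0 (`^GATC`, 4-nt 5′ overhang). Site scanning checks both
strands; a palindromic motif presents the same site on both strands
and is counted once, with the cut position taken from the plus-strand
reading — the bottom-strand nick of a staggered cutter is invisible at
gel resolution, so fragment lengths are defined by top-strand cuts
only. Cuts falling at position 0 or at the sequence end produce no new
fragment and are dropped. Digestion fragments are the inter-cut
intervals; their sum always equals the input length.

A marker is **valid** when exactly one allele carries a single
recognition site overlapping the SNP and the other allele carries
none. Extra sites elsewhere in the amplicon set a
`confounded_extra_sites` flag (every genotype would be cut, blurring
the diagnosis); two expected bands closer than max(10 bp, 8% of the
larger) set `unresolvable_bands`, a threshold chosen for 2% agarose
resolution. The designer (`design_caps`) windows the reference around
the SNP within the 250–300 bp length constraint (short amplicons
tolerate degraded DNA); because a cut site dead-center would split the
product into two nearly equal, unresolvable fragments, several
off-center placements of the SNP within the window are tried, and
candidates are ranked valid-first, then fewer bands, shorter amplicon,
enzyme name.

**Genotype calling from gel bands.** Observed lengths are matched to
the three expected patterns (wild-type homozygote, heterozygote = the
union pattern with three distinct bands, mutant homozygote). The
strict rule demands equal band counts and every band within a 5%
relative tolerance of its size-ordered counterpart; exactly one
strictly matching pattern wins. When no pattern passes strictly, the
band *count* — the primary diagnostic on a gel, where heterozygosity
is read off as "three fragments" — decides, provided exactly one
pattern has the observed count and all its bands sit within a wider
15% reject bound; anything further off, or consistent with several
patterns, is an AMBIGUOUS no-call. The two-tier rule reflects how
gels are actually read (count first, sizes as confirmation): a hard 5%
gate alone would randomly no-call a small percentage of honest lanes
at realistic 2% sizing noise, while the 15% bound still rejects
nonsense fragments outright.

## HRM engine

Melting temperatures come from nearest-neighbor thermodynamics with
the unified duplex parameter set (SantaLucia 1998) and terminal
initiation terms: Tm(1 M Na⁺) = ΔH/(ΔS + R·ln(Cₜ/4)), corrected to the
working monovalent-salt concentration with the Owczarzy (2004)
GC-dependent reciprocal-temperature correction. Defaults are 50 mM
monovalent cation and 250 nM total strands — ordinary PCR-buffer
conditions; the instrument's exact chemistry is unknown, and only the
*relative* placement of curves matters for classification. The
self-complementary symmetry correction is omitted (amplicons are never
palindromic).

A homozygote's PCR product melts as one homoduplex. A heterozygote's
denature/reanneal step pairs strands combinatorially: two homoduplexes
and two heteroduplexes at ¼ each, the heteroduplexes destabilized by a
single internal mismatch. Rather than carrying mismatch-specific NN
tables, that destabilization is a fixed, configurable penalty of
3.0 °C below the mean homoduplex Tm — the typical magnitude for one
internal mismatch in a short amplicon. The 1:1 mixture standard is
modeled with the same four-species set, since mixing the two standards
and re-annealing forms heteroduplexes exactly as a true heterozygote
does — which is why the mixture is a valid HET reference.

Curves live on the fixed instrument grid (65.0–90.0 °C inclusive,
0.1 °C steps, 251 points). Each species contributes a logistic
transition `f/(1 + exp((T − Tm)/w))` with width w = 0.9 °C (chosen so
simulated transitions span ~2–4 °C as real amplicon melts do);
mixtures are linear before normalization. Normalization is the
standard HRM pre/post-melt affine rescale — mean 1 over 65–67 °C,
mean 0 over 88–90 °C, clipped to [0, 1]; because of the clip the
operation is exactly idempotent only on already-normalized curves and
contracts (≈1e-6 per pass) on others, which is irrelevant at
classification scale. Classification computes the RMS difference to
each of the three standards after normalization and takes the nearest;
when the two best distances differ by less than 10% relatively the
call is AMBIGUOUS. Replicate curves (reactions are run in triplicate)
are averaged pointwise before classification.

## Amplicon-sequencing engine

Reads are placed by exhaustive ungapped sliding over every amplicon
and both strands, maximizing exact matches (vectorized over all
offsets); a read below 90% identity is unassigned. Ties break
deterministically (locus id, plus strand, smallest offset). This is a
deliberate minimal aligner: the amplicons are short, known, and few,
so gapped alignment machinery would add nothing — replicating a full
short-read pipeline is out of scope.

Pileups count ref/alt/other bases of assigned reads covering the SNP
offset, honoring base qualities (minimum 20 when present; reads
without qualities pass). Individual calls threshold the alt fraction
of informative (ref+alt) reads: ≤0.10 wild-type homozygote, ≥0.90
mutant homozygote, 0.35–0.65 heterozygote, below 50 reads MISSING,
anything between the bands AMBIGUOUS. The gaps are deliberate: for
inbred-line material a fraction near 0.2 or 0.8 signals contamination
or allele-specific amplification, and a conservative no-call beats a
forced one. By exact binomial tails the homozygote call is correct
with probability >0.999 at depth 100, and a heterozygote is never
miscalled as a homozygote (P < 1e-12 at depth 100); the het call
itself reaches the 0.999 level slightly above depth 100 (0.9982 at
exactly 100, ≥0.9999 at 200), its failure mode being the AMBIGUOUS
no-call.

Pool estimation divides alt by informative reads; sequencing-error
bases (neither allele) are excluded from the denominator. The default
**inbred-homozygous** assumption equates the allele frequency with the
carrier-plant fraction, which is the right model for a self-pollinated
crop where varietal heterogeneity means a mixture of homozygous lines;
the Hardy–Weinberg mode (carriers = 1 − (1−p)²) covers outbred
material. Whether the original field percentages were computed as raw
read fractions or model-based is not documented; both modes exist and
the default is a package choice, not an attribution. Confidence
intervals are Wilson score at 95%, mapped through the monotone
carrier transform in HW mode and snapped exactly to the boundary when
the count sits at 0 or n.

## Synthetic fixtures

The generator replaces the real plant material and genome. Marker
geometry is **back-calculated from the published fragment lengths**:
a 302 bp amplicon whose HaeIII digest is 195 + 107 forces the `GGCC`
at amplicon offsets 194–197 (cut offset 2 ⇒ top-strand cut after base
195), with the G→A substitution placed on the motif base at offset 195
where it destroys the site; likewise `GGCC` at 156–159 (C→T at 158)
for the 260 bp *FAD3B* exon-2 amplicon and `GATC` at 164–167 (C→T at
167) for the 272 bp *FAD3A* exon-5 amplicon. Which motif base
coincides with the real genomic mutation is not derivable from the
published material, so this phasing is a documented modeling choice
about the synthetic loci, not a claim about the real genome. Amplicon
interiors and flanks are random sequence scrubbed (by deterministic
single-base repair) of every stray `GGCC`/`GATC`, so each wild-type
amplicon carries exactly one site and each mutant allele none; primer
footprints are the terminal 20-mers, verified unique across the
synthetic chromosome. Everything is a pure function of one integer
seed.

Populations: a VARIETY is homozygous founders with independent
off-type replacement (each off-type differs from the founder at one
random locus, as heterozygote or opposite homozygote — bookkept, so
purification can be scored exactly); a CROSS is an F1 heterozygous at
all differing loci followed by per-locus 1:2:1 selfing, loci unlinked.
The two *FAD3A* mutations are physically linked in reality but never
co-occur in the material this models, so independence is harmless and
is stated, not asserted of real flax. Pool fixtures plant **exact**
carrier counts — 25/100 and 65/100 homozygous carriers, mirroring the
two published varietal-heterogeneity findings (~25% and ~65% of
plants) — so the simulation's ground truth coincides with the printed
percentages and all remaining error is read-sampling noise. Reads draw
plant, locus, strand and window uniformly, apply uniform substitution
errors (default 0.5%, a MiSeq-like rate) and carry matching Phred
qualities. Gel noise is a lognormal length factor (2% default) with
shuffled band order; HRM samples add Gaussian noise to the simulated
curve and renormalize.

What the synthetic data does **not** emulate: real flax sequence
composition, primer thermodynamics, indels and structural variation,
coverage bias, adapter/quality artifacts, partial digestion, or
linkage. Passing tests therefore demonstrate the correctness of the
assay logic and estimators under clean, known-truth conditions — not
robustness to every artifact of real instruments.

## Genetics rules

*FAD3A* is inactivated by a homozygous mutation at either its exon-1
or exon-5 locus (the rule is symmetric in the two, and a double
knockout of the same gene earns nothing extra); *FAD3B* by its exon-2
locus. Both genes out → LOW, one → MEDIUM, none (all wild-type
homozygous) → HIGH. Heterozygosity at a locus that is not already
overridden by a fixed knockout of the same gene makes the plant
SEGREGATING — seed phenotype is predicted only for fixed genotypes,
because wild-type dominance is not quantified; for the same reason the
nominal LIN percentages (≈5%, 30–40%, >50%) are annotations, never
computed. A missing or ambiguous call at a locus that could change
the outcome raises an error rather than guessing. Family selection
requires every locus fixed across members (the target loci fixed
mutant, the rest fixed wild-type; for MEDIUM either gene qualifies);
mixed homozygotes within a family count as segregating. Variety
purification keeps exact matches to the desired homozygous genotype
and annotates each exclusion with the first failing locus and reason.

## Problem sizes and determinism

The bundled experiments run at the scales the workflows define: 100
random sequences for scanner-oracle equivalence, 50 noisy replicates ×
3 genotypes × 3 loci for HRM concordance, 100 noisy gels per
genotype/marker, F2 cohorts of 10 000 and 16 000 plants for Mendelian
checks, and 20 seeds × 5000 reads per pool for the estimation
experiment (the ~95% Wilson coverage is assessed jointly over all 40
per-seed intervals). Every stochastic component takes an explicit
integer seed through `numpy.random.default_rng`, so all outputs are
bit-reproducible.
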