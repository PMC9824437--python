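# flaxmark

In-silico genotyping of the low-linolenic *FAD3* mutations in flax
(*Linum usitatissimum*).

Linseed oil quality is set largely by its linolenic-acid (LIN, ω-3)
content, and LIN content is controlled by the two fatty-acid
desaturase genes *FAD3A* and *FAD3B*. Three natural point mutations
knock these genes out: a G→A nonsense mutation in *FAD3A* exon 1
(Trp→stop), a C→T substitution in *FAD3B* exon 2 (His→Tyr), and a C→T
nonsense mutation in *FAD3A* exon 5 (Arg→stop). A plant homozygous for
mutations in **both** genes produces low-LIN oil (≈5%, food-grade), in
exactly **one** gene medium-LIN (30–40%), and a wild type at both
genes the high-LIN (>50%) technical oil. Marker-assisted selection on
these three SNPs is therefore the practical way to breed flax for a
target oil type, and to purge off-type plants from heterogeneous
varieties.

`flaxmark` implements the three complementary genotyping systems used
for these mutations, as simulatable, testable software:

* **CAPS markers** (`flaxmark.caps_engine`) — restriction-enzyme model
  (IUPAC recognition motif + top-strand cut offset; HaeIII `GG^CC` and
  BstMBI `^GATC` built in), double-strand site scanning, digestion
  simulation, marker validation/design, and genotype calling from
  observed gel band lengths. The three markers give allele-diagnostic
  patterns, e.g. 195+107 bp (wild type) vs. 302 bp (mutant) for the
  *FAD3A* exon-1 amplicon, with heterozygotes showing all three bands.
* **HRM analysis** (`flaxmark.hrm_engine`) — nearest-neighbor duplex
  thermodynamics (unified NN parameters, Owczarzy monovalent-salt
  correction), logistic melt-curve simulation on the instrument's
  65–90 °C / 0.1 °C grid, pre/post-melt normalization, and genotype
  classification by RMS similarity to three standards (with the
  mutation, without it, and their 1:1 mixture, which forms
  mismatch-destabilized heteroduplexes like a true heterozygote).
* **Targeted amplicon sequencing** (`flaxmark.ampseq_engine`) —
  ungapped best-offset read assignment, allele pileups at the SNPs,
  threshold-based individual genotype calls, and pooled plant-fraction
  estimation: in a self-pollinating crop the plants of a variety are
  essentially homozygous, so the mutant-allele read fraction `p` of a
  many-plant DNA pool estimates the fraction of carrier plants
  directly (a Hardy–Weinberg mode, carriers `= 1 − (1−p)²`, is
  provided for outbred material), with Wilson 95% intervals.
* **Breeding decisions** (`flaxmark.genetics`) — the genotype→LIN-class
  rule, selection of F3 families fixed for a target class, and variety
  purification with per-plant exclusion reasons.
* **Synthetic fixtures** (`flaxmark.synthetic_fixtures`) — a
  deterministic generator of marker loci whose assay geometry
  reproduces the published fragment tables exactly, plus seeded
  simulators for populations (varieties with off-types, selfed
  crosses), sequencing reads, gel measurements and melt curves, with
  ground-truth bookkeeping for every simulation.

## Worked example

```
$ flaxmark fixtures --seed 7 -o out/fx
wrote fixtures (seed 7) to out/fx

$ flaxmark digest -i out/fx --locus fad3a_ex1 --allele ref
fad3a_ex1	ref	HaeIII	fragments=195,107

$ flaxmark digest -i out/fx --locus fad3a_ex1 --allele alt
fad3a_ex1	alt	HaeIII	fragments=302
```

The wild-type *FAD3A* exon-1 amplicon carries a single HaeIII site and
digests into 195 + 107 bp; the G→A mutation destroys the site, leaving
the uncut 302 bp product — so a two-band lane is a wild-type
homozygote, one band a mutant homozygote, and three bands a
heterozygote. The same geometry gives 157+103/260 bp for *FAD3B*
exon 2 (HaeIII) and 163+109/272 bp for *FAD3A* exon 5 (BstMBI).

Calling genotypes from a gel and classifying the oil type:

```
$ flaxmark call-caps -i out/fx --bands bands.tsv -o calls.tsv   # 302,195,107 -> RA
$ flaxmark classify-lin --genotypes genos.tsv -o classes.tsv
```

A plant `AA RR AA` (both genes knocked out) is classed `LOW` (about 5%
LIN), `RR RR AA` is `MEDIUM` (30–40%), `RR RR RR` is `HIGH` (more than
50%); any heterozygous decisive locus yields `SEGREGATING`.

In the library, a pooled-sequencing estimate looks like:

```python
>>> import flaxmark as fm
>>> from flaxmark.synthetic_fixtures import POOL_FIXTURES, build_pool, simulate_reads
>>> fx = fm.build_fixture_loci(seed=7)
>>> pool = build_pool(POOL_FIXTURES["g582"])          # 65 of 100 plants carry fad3b_ex2
>>> reads = simulate_reads(fx, pool.records, ["fad3b_ex2"], 5000, seed=1)
>>> piles = fm.count_alleles(reads, fx.amplicons, fx.variants)
>>> est = fm.estimate_pool_fraction(piles["fad3b_ex2"])
>>> round(est.plant_fraction_percent, 2), round(est.ci_low, 2), round(est.ci_high, 2)
(64.37, 62.99, 65.74)
```

i.e. from 5000 simulated reads at 0.5% error the pool is estimated to
contain 64.4% carrier plants (95% CI 63.0–65.7) against a planted
truth of 65%.

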