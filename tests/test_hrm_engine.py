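"""NN thermodynamics, melt-curve simulation and similarity classification."""

import math

import numpy as np
import pytest

from flaxmark import Genotype, classify_hrm, duplex_tm, make_standard_set, reverse_complement
from flaxmark.hrm_engine import (
    DEFAULT_MODEL,
    INIT_TERMINAL_AT,
    INIT_TERMINAL_GC,
    NN_UNIFIED,
    DuplexSpecies,
    MeltCurve,
    R_GAS,
    average_replicates,
    melt_species_for_genotype,
    normalize_curve,
    read_curves_tsv,
    simulate_melt_curve,
    temperature_grid,
    write_curves_tsv,
)
from flaxmark.exceptions import AmbiguousBaseError, DegenerateCurveError, GridMismatchError
from flaxmark.synthetic_fixtures import simulate_hrm_sample

_BASES = np.array(list("ACGT"))


def brute_force_tm(seq: str, model=DEFAULT_MODEL) -> float:
    """Independent oracle: explicit two-strand NN summation.

    Sums stack parameters by pairing each top-strand dinucleotide with
    its bottom-strand complement and always reading the
    lexicographically smaller orientation, rather than reusing the
    implementation's equivalence map.
    """
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        top = seq[i : i + 2]
        bottom = reverse_complement(top)
        key = top if top in NN_UNIFIED else bottom
        h, s = NN_UNIFIED[key]
        dh += h
        ds += s
    for t in (seq[0], seq[-1]):
        h, s = INIT_TERMINAL_GC if t in "GC" else INIT_TERMINAL_AT
        dh += h
        ds += s
    tm = dh * 1000.0 / (ds + R_GAS * math.log(model.strand_molar / 4.0))
    fgc = (seq.count("G") + seq.count("C")) / len(seq)
    ln_na = math.log(model.salt_molar)
    return 1.0 / (1.0 / tm + (4.29 * fgc - 3.95) * 1e-5 * ln_na + 9.4e-6 * ln_na**2) - 273.15


class TestDuplexTm:
    def test_matches_independent_nn_summation(self):
        for seed in range(20):
            seq = "".join(np.random.default_rng(seed).choice(_BASES, size=25))
            assert duplex_tm(seq) == pytest.approx(brute_force_tm(seq), abs=0.01)

    def test_strand_symmetry(self):
        for seed in range(50):
            seq = "".join(np.random.default_rng(100 + seed).choice(_BASES, size=30))
            assert duplex_tm(seq) == pytest.approx(duplex_tm(reverse_complement(seq)), abs=1e-9)

    def test_gc_clamp_raises_tm(self):
        seq = "ATGCATTAGCAATTACGATA"
        assert duplex_tm(seq + "GCGCGC") > duplex_tm(seq)

    def test_ambiguous_base_rejected(self):
        with pytest.raises(AmbiguousBaseError):
            duplex_tm("ACGTNACGTACGT")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            duplex_tm("ACGTAC")


class TestMeltSpecies:
    def test_homozygote_single_species(self, fixture_set):
        lc = fixture_set.loci["fad3a_ex1"]
        species = melt_species_for_genotype(lc.amplicon, lc.variant, Genotype.REF_HOM)
        assert len(species) == 1 and species[0].fraction == 1.0

    def test_het_four_species_fractions_conserve(self, fixture_set):
        lc = fixture_set.loci["fad3a_ex1"]
        species = melt_species_for_genotype(lc.amplicon, lc.variant, Genotype.HET)
        assert len(species) == 4
        assert sum(s.fraction for s in species) == pytest.approx(1.0)

    def test_heteroduplex_tm_below_both_homoduplexes(self, fixture_set):
        for lc in fixture_set.loci.values():
            species = melt_species_for_genotype(lc.amplicon, lc.variant, Genotype.HET)
            tms = {s.label: s.tm for s in species}
            assert tms["ref/alt"] < min(tms["ref/ref"], tms["alt/alt"])


class TestSimulateMeltCurve:
    def test_logistic_midpoint_before_normalization(self):
        curve = simulate_melt_curve([DuplexSpecies("x", 1.0, 77.0)], normalize=False)
        i = int(np.argmin(np.abs(curve.grid - 77.0)))
        assert curve.values[i] == pytest.approx(0.5, abs=1e-6)

    def test_saturation_at_grid_ends(self):
        curve = simulate_melt_curve([DuplexSpecies("x", 1.0, 77.0)])
        assert curve.values[0] > 0.999 and curve.values[-1] < 0.001

    def test_mixture_linearity(self):
        a = simulate_melt_curve([DuplexSpecies("a", 1.0, 75.0)], normalize=False)
        b = simulate_melt_curve([DuplexSpecies("b", 1.0, 80.0)], normalize=False)
        mix = simulate_melt_curve(
            [DuplexSpecies("a", 0.5, 75.0), DuplexSpecies("b", 0.5, 80.0)], normalize=False
        )
        np.testing.assert_allclose(mix.values, 0.5 * (a.values + b.values), atol=1e-12)

    def test_noise_free_curves_monotone_non_increasing(self, fixture_set):
        for lid in fixture_set.loci:
            for g in (Genotype.REF_HOM, Genotype.HET, Genotype.ALT_HOM):
                c = simulate_hrm_sample(fixture_set, lid, g, noise_sigma=0.0)
                assert np.all(np.diff(c.values) <= 1e-12)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            simulate_melt_curve([DuplexSpecies("x", 0.6, 75.0)])


class TestNormalizeCurve:
    def _normalized_curve(self):
        """A curve that is exactly normalized: saturated at 1 across the
        pre-melt window and at 0 across the post-melt window."""
        g = temperature_grid()
        return MeltCurve(grid=g, values=np.clip((80.0 - g) / 10.0, 0.0, 1.0))

    def test_idempotent_on_normalized_curve(self):
        n1 = normalize_curve(self._normalized_curve())
        n2 = normalize_curve(n1)
        np.testing.assert_allclose(n1.values, n2.values, atol=1e-12)
        np.testing.assert_allclose(n1.values, self._normalized_curve().values, atol=1e-12)

    def test_near_idempotent_on_simulated_curve(self):
        # clipping makes repeated normalization contract, not oscillate
        c = simulate_melt_curve([DuplexSpecies("x", 1.0, 77.0)])
        n1 = normalize_curve(c)
        n2 = normalize_curve(n1)
        np.testing.assert_allclose(n1.values, n2.values, atol=1e-5)

    def test_affine_invariance(self):
        c = self._normalized_curve()
        scaled = MeltCurve(grid=c.grid, values=3.0 * c.values + 7.0)
        np.testing.assert_allclose(
            normalize_curve(c).values, normalize_curve(scaled).values, atol=1e-9
        )

    def test_constant_curve_degenerate(self):
        flat = MeltCurve(grid=temperature_grid(), values=np.full(251, 0.4))
        with pytest.raises(DegenerateCurveError):
            normalize_curve(flat)


class TestClassify:
    def test_self_match_zero_distance(self, fixture_set):
        lc = fixture_set.loci["fad3a_ex1"]
        std = make_standard_set(lc.amplicon, lc.variant)
        call = classify_hrm(std.alt_hom, std)
        assert call.genotype is Genotype.ALT_HOM
        assert call.distances["alt_hom"] == pytest.approx(0.0, abs=1e-12)

    def test_mixture_standard_classifies_het(self, fixture_set):
        lc = fixture_set.loci["fad3b_ex2"]
        std = make_standard_set(lc.amplicon, lc.variant)
        assert classify_hrm(std.het_mix, std).genotype is Genotype.HET

    def test_grid_mismatch_rejected(self, fixture_set):
        lc = fixture_set.loci["fad3a_ex1"]
        std = make_standard_set(lc.amplicon, lc.variant)
        short = MeltCurve(grid=np.linspace(65, 90, 100), values=np.linspace(1, 0, 100))
        with pytest.raises(GridMismatchError):
            classify_hrm(short, std)

    def test_triplicate_average_classifies_like_members(self, fixture_set):
        lc = fixture_set.loci["fad3a_ex5"]
        std = make_standard_set(lc.amplicon, lc.variant)
        reps = [
            simulate_hrm_sample(fixture_set, "fad3a_ex5", Genotype.HET, noise_sigma=0.005, seed=s)
            for s in range(3)
        ]
        assert classify_hrm(average_replicates(reps), std).genotype is Genotype.HET

    def test_noisy_concordance_all_loci(self, fixture_set):
        """50 noisy replicates x 3 genotypes x 3 loci all classify correctly,
        mirroring the complete HRM/sequencing agreement on real plants."""
        for lid, lc in fixture_set.loci.items():
            std = make_standard_set(lc.amplicon, lc.variant)
            for g in (Genotype.REF_HOM, Genotype.HET, Genotype.ALT_HOM):
                for seed in range(50):
                    c = simulate_hrm_sample(fixture_set, lid, g, noise_sigma=0.005, seed=seed)
                    assert classify_hrm(c, std).genotype is g


def test_curve_tsv_round_trip(tmp_path, fixture_set):
    lc = fixture_set.loci["fad3a_ex1"]
    std = make_standard_set(lc.amplicon, lc.variant)
    p = tmp_path / "curves.tsv"
    write_curves_tsv({"ref": std.ref_hom, "het": std.het_mix}, p)
    back = read_curves_tsv(p)
    np.testing.assert_allclose(back["ref"].values, std.ref_hom.values, atol=1e-6)
    np.testing.assert_allclose(back["het"].grid, std.het_mix.grid, atol=1e-9)
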