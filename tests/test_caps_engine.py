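"""Restriction scanning, digestion, CAPS marker validation and band calling."""

import numpy as np
import pytest

from flaxmark import (
    BSTMBI,
    HAEIII,
    Genotype,
    RestrictionEnzyme,
    SnpVariant,
    call_genotype_from_bands,
    design_caps,
    digest,
    find_sites,
    predict_band_pattern,
    reverse_complement,
    validate_caps_marker,
)
from flaxmark.caps_engine import DesignConstraints, read_enzyme_library
from flaxmark.core_model import Amplicon, ReferenceSequence, IUPAC_EXPANSION
from flaxmark.exceptions import NotACapsCandidateError, UndefinedPatternError

_BASES = np.array(list("ACGT"))


def _random_seq(rng, n):
    return "".join(rng.choice(_BASES, size=n))


def naive_cut_positions(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Independent oracle: sliding-window IUPAC match over both strands.

    For a palindromic motif both strands present the same site, and only
    the plus-strand reading defines the top-strand cut (the minus-strand
    reading cuts the bottom strand); non-palindromic motifs found on the
    minus strand map their cut to ``span_start + (len - cut_offset)``.
    """
    def matches(window: str, motif: str) -> bool:
        return all(w in IUPAC_EXPANSION[m] for w, m in zip(window, motif))

    n, m = len(seq), len(enzyme.recognition)
    cuts = set()
    rc_motif = reverse_complement(enzyme.recognition)
    palindrome = rc_motif == enzyme.recognition
    for i in range(n - m + 1):
        w = seq[i : i + m]
        if matches(w, enzyme.recognition):
            cuts.add(i + enzyme.cut_offset)
        if not palindrome and matches(w, rc_motif):
            cuts.add(i + (m - enzyme.cut_offset))
    return sorted(p for p in cuts if 0 < p < n)


class TestFindSites:
    def test_hand_worked_haeiii_cut(self):
        # GGCC starts at base 3 of AAGGCCTT; GG^CC puts the cut after base 4
        assert find_sites("AAGGCCTT", HAEIII) == [4]

    def test_no_motif_no_cut(self):
        assert find_sites("ATATATAT", HAEIII) == []

    @pytest.mark.parametrize("enzyme", [HAEIII, BSTMBI], ids=lambda e: e.name)
    def test_matches_sliding_window_oracle_on_random_200mers(self, enzyme):
        for seed in range(100):
            seq = _random_seq(np.random.default_rng(seed), 200)
            assert find_sites(seq, enzyme) == naive_cut_positions(seq, enzyme)

    def test_non_palindromic_enzyme_counts_both_strands(self):
        enz = RestrictionEnzyme(name="Toy", recognition="GGATG", cut_offset=5)
        seq = "TT" + "GGATG" + "TTTT" + reverse_complement("GGATG") + "TT"
        assert find_sites(seq, enz) == naive_cut_positions(seq, enz)
        assert len(find_sites(seq, enz)) == 2

    def test_degenerate_motif_oracle_agreement(self):
        enz = RestrictionEnzyme(name="Hinfy", recognition="GANTC", cut_offset=1)
        for seed in range(25):
            seq = _random_seq(np.random.default_rng(1000 + seed), 300)
            assert find_sites(seq, enz) == naive_cut_positions(seq, enz)

    def test_agrees_with_biopython_restriction(self):
        """Independent cross-check against Bio.Restriction (MboI shares
        BstMBI's GATC/offset-0 geometry)."""
        from Bio.Restriction import HaeIII as BioHaeIII, MboI
        from Bio.Seq import Seq

        for seed in range(20):
            seq = _random_seq(np.random.default_rng(seed), 400)
            bio_hae = sorted(p - 1 for p in BioHaeIII.search(Seq(seq)))
            bio_mbo = sorted(p - 1 for p in MboI.search(Seq(seq)))
            assert find_sites(seq, HAEIII) == [p for p in bio_hae if 0 < p < 400]
            assert find_sites(seq, BSTMBI) == [p for p in bio_mbo if 0 < p < 400]


class TestDigest:
    def test_fixture_fragments_match_published_tables(self, fixture_set):
        expected = {
            "fad3a_ex1": (HAEIII, (195, 107), (302,)),
            "fad3b_ex2": (HAEIII, (157, 103), (260,)),
            "fad3a_ex5": (BSTMBI, (163, 109), (272,)),
        }
        for locus_id, (enz, ref_frags, alt_frags) in expected.items():
            lc = fixture_set.loci[locus_id]
            assert digest(lc.allele_sequence("REF"), enz).fragment_lengths == ref_frags
            assert digest(lc.allele_sequence("ALT"), enz).fragment_lengths == alt_frags

    def test_uncut_sequence_single_full_length_fragment(self):
        assert digest("ATATATATAT", HAEIII).fragment_lengths == (10,)

    def test_planted_cuts_give_interval_arithmetic(self):
        rng = np.random.default_rng(11)
        arr = list(_random_seq(rng, 200))
        for start in (48, 118):  # GGCC starting here cuts after start+2 (0-based)
            arr[start : start + 4] = "GGCC"
        seq = "".join(arr)
        cuts = find_sites(seq, HAEIII)
        if cuts == [50, 120]:  # guard against accidental extra motifs
            assert digest(seq, HAEIII).fragment_lengths == (80, 70, 50)

    def test_fragment_sum_conservation_property(self):
        for seed in range(50):
            seq = _random_seq(np.random.default_rng(seed), int(np.random.default_rng(seed).integers(20, 500)))
            for enz in (HAEIII, BSTMBI):
                assert sum(digest(seq, enz).fragment_lengths) == len(seq)


class TestBandPatterns:
    def test_published_per_genotype_patterns(self, markers):
        mk = markers["fad3b_ex2"]
        assert predict_band_pattern(mk, Genotype.REF_HOM).bands == (157, 103)
        assert predict_band_pattern(mk, Genotype.ALT_HOM).bands == (260,)

    def test_heterozygote_is_union_with_three_bands(self, markers):
        for mk in markers.values():
            het = predict_band_pattern(mk, Genotype.HET)
            assert set(het.bands) == set(mk.pattern_ref_hom.bands) | set(mk.pattern_alt_hom.bands)
            assert het.band_count == 3

    def test_missing_genotype_has_no_pattern(self, markers):
        with pytest.raises(UndefinedPatternError):
            predict_band_pattern(markers["fad3a_ex1"], Genotype.MISSING)


class TestValidateMarker:
    def test_fixture_markers_valid_with_site_on_ref(self, markers):
        for mk in markers.values():
            assert mk.valid and mk.allele_with_site == "REF"
            assert not mk.confounded_extra_sites and not mk.unresolvable_bands

    def test_extra_flanking_site_sets_confounded_flag(self, fixture_set):
        lc = fixture_set.loci["fad3a_ex1"]
        bases = lc.amplicon.bases[:40] + "GGCC" + lc.amplicon.bases[44:]
        amp = Amplicon(
            locus_id="fad3a_ex1", source_id="x", start=1, end=len(bases), bases=bases,
            primer_fwd=bases[:20], primer_rev=reverse_complement(bases[-20:]),
            variant_offset=lc.amplicon.variant_offset,
        )
        mk = validate_caps_marker(amp, lc.variant, HAEIII)
        assert mk.confounded_extra_sites and not mk.valid

    def test_snp_outside_any_motif_not_a_candidate(self, fixture_set):
        lc = fixture_set.loci["fad3a_ex1"]
        with pytest.raises(NotACapsCandidateError):
            validate_caps_marker(lc.amplicon, lc.variant, BSTMBI)


class TestDesignCaps:
    def test_fixture_variant_yields_valid_haeiii_candidate(self, fixture_set):
        v = fixture_set.loci["fad3a_ex1"].variant
        cands = design_caps(fixture_set.reference, v, [HAEIII, BSTMBI])
        assert cands and cands[0].valid and cands[0].enzyme.name == "HaeIII"
        assert 250 <= len(cands[0].amplicon) <= 300

    def test_motif_free_variant_yields_empty_list(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(np.array(list("AT")), size=600))
        ref = ReferenceSequence(id="at", bases=seq)
        pos = 300
        v = SnpVariant("x", "at", pos, seq[pos - 1], "T" if seq[pos - 1] == "A" else "A")
        assert design_caps(ref, v, [HAEIII, BSTMBI]) == []

    def test_max_len_below_reference_span_excludes(self, fixture_set):
        v = fixture_set.loci["fad3a_ex1"].variant
        tight = DesignConstraints(min_len=5000, max_len=6000)
        assert design_caps(fixture_set.reference, v, [HAEIII], tight) == []


class TestCallGenotypeFromBands:
    def test_noisy_bands_call_het_within_tolerance(self, markers):
        assert call_genotype_from_bands([301, 196, 106], markers["fad3a_ex1"], tol=0.05) is Genotype.HET

    def test_exact_patterns_round_trip_for_all_genotypes(self, markers):
        for mk in markers.values():
            for g in (Genotype.REF_HOM, Genotype.HET, Genotype.ALT_HOM):
                assert call_genotype_from_bands(predict_band_pattern(mk, g).bands, mk) is g

    def test_unmatchable_band_is_ambiguous(self, markers):
        assert call_genotype_from_bands([500], markers["fad3a_ex1"]) is Genotype.AMBIGUOUS

    def test_partial_pattern_is_not_called(self, markers):
        # only two of the three het bands: neither hom pattern matches either
        assert call_genotype_from_bands([302, 195], markers["fad3a_ex1"]) is Genotype.AMBIGUOUS


def test_enzyme_library_includes_builtins_and_user_rows(tmp_path):
    p = tmp_path / "enzymes.tsv"
    p.write_text("#name\trecognition\tcut_offset\nEcoRI\tGAATTC\t1\n")
    lib = read_enzyme_library(p)
    assert {"HaeIII", "BstMBI", "EcoRI"} <= set(lib)
    assert lib["EcoRI"].cut_offset == 1
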