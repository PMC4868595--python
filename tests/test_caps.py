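"""CAPS marker design: site finding, digest sizing, enzyme ranking, gel."""

from collections import Counter

import numpy as np
import pytest
from Bio.Restriction import EcoRI as BioEcoRI
from Bio.Restriction import HphI as BioHphI
from Bio.Seq import Seq

from clonotyper.caps import (
    Enzyme,
    GelConfig,
    amplicon_window,
    compare_alleles,
    digest,
    enumerate_enzymes,
    find_sites,
    load_enzyme_library,
    parse_enzyme_library,
    render_gel,
)
from clonotyper.seqs import random_sequence, revcomp

LIBRARY = {e.name: e for e in load_enzyme_library()}
HPHI = LIBRARY["HphI"]

# The two allele contexts of a C->T transition at the 7th base: the T allele
# carries a GGTGA (HphI) site, the C allele does not.
SITE_ALLELE = "TAAAGGTGAAGGTAGAAGCGAAAAT"
NO_SITE_ALLELE = "TAAAGGCGAAGGTAGAAGCGAAAAT"


def bio_fragments(seq: str, bio_enzyme) -> list[int]:
    """Fragment lengths according to Biopython's Bio.Restriction."""
    cuts = sorted(bio_enzyme.search(Seq(seq), linear=True))
    bounds = [0] + [c - 1 for c in cuts] + [len(seq)]
    return sorted((b - a for a, b in zip(bounds, bounds[1:])), reverse=True)


class TestFindSites:
    def test_transition_creates_hphi_site(self):
        hits = find_sites(SITE_ALLELE, HPHI)
        assert len(hits) == 1
        (hit,) = hits
        assert (hit.position, hit.strand) == (5, "+")
        # GGTGA ends at base 9; the cut falls 8 nt downstream, after base 17
        assert hit.cut_coordinate == 17
        assert find_sites(NO_SITE_ALLELE, HPHI) == []

    def test_minus_strand_site_detected(self):
        seq = revcomp(SITE_ALLELE)
        (hit,) = find_sites(seq, HPHI)
        assert hit.strand == "-"
        # the duplex is severed at the mirrored coordinate
        assert hit.cut_coordinate == len(seq) - 17

    def test_site_count_matches_brute_force_single_base_enzyme(self, rng):
        enz = Enzyme("OneBase", "A", cut_offset_top=0)
        for _ in range(20):
            seq = random_sequence(rng, 200)
            hits = find_sites(seq, enz)
            assert sum(h.strand == "+" for h in hits) == seq.count("A")
            assert sum(h.strand == "-" for h in hits) == seq.count("T")

    def test_degenerate_recognition_expands_iupac(self):
        enz = Enzyme("HinfI-like", "GANTC", cut_offset_top=-4)
        for mid in "ACGT":
            assert any(h.strand == "+" for h in find_sites(f"TTGA{mid}TCTT", enz))

    def test_non_acgt_input_rejected(self):
        with pytest.raises(ValueError):
            find_sites("ACGNT", HPHI)

    def test_invalid_enzyme_rejected(self):
        with pytest.raises(ValueError):
            Enzyme("bad", "GGQGA", 8)
        with pytest.raises(ValueError):
            Enzyme("bad", "", 8)


class TestDigest:
    def test_single_hphi_site_fragments(self):
        assert digest(SITE_ALLELE, HPHI).fragment_lengths == [17, 8]
        assert digest(NO_SITE_ALLELE, HPHI).fragment_lengths == [25]

    def test_fragment_lengths_conserve_total(self, rng):
        for enzyme in LIBRARY.values():
            for _ in range(10):
                seq = random_sequence(rng, int(rng.integers(30, 400)))
                pat = digest(seq, enzyme)
                assert pat.total == len(seq)
                assert pat.fragment_lengths == sorted(pat.fragment_lengths, reverse=True)

    def test_digest_reverse_complement_symmetric(self, rng):
        for _ in range(40):
            seq = random_sequence(rng, 300)
            fwd = digest(seq, HPHI).fragment_lengths
            rev = digest(revcomp(seq), HPHI).fragment_lengths
            assert Counter(fwd) == Counter(rev)

    def test_offset_cut_running_off_the_end_leaves_no_cut(self):
        # GGTGA with only 3 downstream bases: the cut site lies past the end
        seq = "TTTTTTTTTTGGTGATTT"
        assert digest(seq, HPHI).fragment_lengths == [len(seq)]

    def test_agrees_with_reference_implementation_ecori(self, rng):
        for _ in range(40):
            seq = random_sequence(rng, 300)
            assert digest(seq, LIBRARY["EcoRI"]).fragment_lengths == bio_fragments(seq, BioEcoRI)

    def test_agrees_with_reference_implementation_hphi_plus_sites(self, rng):
        """For amplicons whose HphI sites are all on the + strand the sizing
        convention coincides with Biopython's top-strand cut positions."""
        checked = 0
        while checked < 15:
            seq = random_sequence(rng, 400)
            if "TCACC" in seq or "GGTGA" not in seq:
                continue
            assert digest(seq, HPHI).fragment_lengths == bio_fragments(seq, BioHphI)
            checked += 1


class TestCompareAndRank:
    @staticmethod
    def _planted_amplicons(rng):
        """660 bp alleles: shared HphI sites at 100 and 400, allele A gains
        a third at 300 (mimicking a site-creating transition)."""
        while True:
            seq = random_sequence(rng, 660)
            if "GGTGA" not in seq and "TCACC" not in seq:
                break
        def plant(s, positions):
            out = list(s)
            for p in positions:
                out[p - 1 : p + 4] = "GGTGA"
            return "".join(out)
        return plant(seq, [100, 300, 400]), plant(seq, [100, 400])

    def test_gained_site_yields_diagnostic_fragments(self, rng):
        amp_a, amp_b = self._planted_amplicons(rng)
        report = compare_alleles(amp_a, amp_b, HPHI)
        # cuts after 112/312/412 vs 112/412
        assert report.patterns[0].fragment_lengths == [248, 200, 112, 100]
        assert report.patterns[1].fragment_lengths == [300, 248, 112]
        assert report.diagnostic_fragments["allele_A"] == [200, 100]
        assert report.diagnostic_fragments["allele_B"] == [300]
        assert report.resolvable and report.score > 0

    def test_identical_alleles_not_resolvable(self, rng):
        amp_a, _ = self._planted_amplicons(rng)
        report = compare_alleles(amp_a, amp_a, HPHI)
        assert not report.resolvable
        assert report.diagnostic_fragments == {"allele_A": [], "allele_B": []}

    def test_sub_detectable_fragment_not_resolvable(self):
        # diagnostic fragments 17 and 8 are below a 50 bp detection floor
        report = compare_alleles(SITE_ALLELE, NO_SITE_ALLELE, HPHI, GelConfig())
        assert not report.resolvable

    def test_enumerate_reports_only_differing_enzymes(self, rng):
        amp_a, amp_b = self._planted_amplicons(rng)
        reports = enumerate_enzymes(amp_a, amp_b, list(LIBRARY.values()))
        assert any(r.enzyme.name == "HphI" for r in reports)
        for r in reports:
            assert Counter(r.patterns[0].fragment_lengths) != Counter(r.patterns[1].fragment_lengths)
        scores = [r.score for r in reports]
        assert scores == sorted(scores, reverse=True)

    def test_ranking_invariant_to_library_order(self, rng):
        amp_a, amp_b = self._planted_amplicons(rng)
        lib = list(LIBRARY.values())
        r1 = enumerate_enzymes(amp_a, amp_b, lib)
        r2 = enumerate_enzymes(amp_a, amp_b, list(reversed(lib)))
        assert [r.enzyme.name for r in r1] == [r.enzyme.name for r in r2]

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            enumerate_enzymes("ACGT" * 10, "ACGT" * 10, [])


class TestLibraryIO:
    def test_bundled_library_contents(self):
        assert len(LIBRARY) >= 10
        assert HPHI.recognition == "GGTGA"
        assert (HPHI.cut_offset_top, HPHI.cut_offset_bottom) == (8, 7)
        assert LIBRARY["EcoRI"].cut_offset_top == -5

    def test_parse_skips_comments_and_blanks(self):
        text = "# comment\n\nFooI  GGCC(-2/-2)\n"
        (enz,) = parse_enzyme_library(text)
        assert (enz.name, enz.recognition, enz.cut_offset_top) == ("FooI", "GGCC", -2)

    def test_malformed_line_rejected(self):
        with pytest.raises(ValueError):
            parse_enzyme_library("FooI GGCC\n")


class TestWindowsAndGel:
    def test_amplicon_window_centred_and_clipped(self):
        genome = {"c": "ACGT" * 500}  # 2000 bp
        assert len(amplicon_window(genome, "c", 1000, 660)) == 660
        assert amplicon_window(genome, "c", 5, 660) == genome["c"][:660]
        assert amplicon_window(genome, "c", 1999, 660) == genome["c"][-660:]
        with pytest.raises(IndexError):
            amplicon_window(genome, "c", 0)

    def test_render_gel_shows_band_rows(self, rng):
        amp_a, amp_b = TestCompareAndRank._planted_amplicons(rng)
        report = compare_alleles(amp_a, amp_b, HPHI)
        art = render_gel([report])
        lines = art.splitlines()
        assert "allele_A:HphI" in lines[0] and "allele_A:uncut" in lines[0]
        assert sum("=" in line for line in lines[1:]) >= 3

    def test_render_gel_empty_rejected(self):
        with pytest.raises(ValueError):
            render_gel([])
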