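"""In-silico PCR, genotype calls, allele alignment, primer picking."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_dna
from ymarker.flanks import ConservedWindows
from ymarker.kmer import revcomp
from ymarker.markers import (
    PrimerPair,
    align_alleles,
    call_genotype,
    gc_content,
    insilico_pcr,
    pick_primer_regions,
    wallace_tm,
)

F = "ACGTTGCAACGTTGCAACGT"
R = "TGCAACGTTGCATGCAACGT"


def _primers():
    return PrimerPair(name="t", forward=F, reverse=R)


class TestInsilicoPcr:
    def test_constructed_template_product_length(self, rng):
        """template = F + 100 bp filler + revcomp(R) -> one product of
        len(F) + 100 + len(R), re-extractable from the template."""
        template = F + random_dna(rng, 100) + revcomp(R)
        amps = insilico_pcr(_primers(), template)
        assert amps.lengths == [len(F) + 100 + len(R)]
        product = amps.products[0]
        assert template[product.start : product.start + product.length] == product.sequence

    def test_template_without_forward_site_empty(self, rng):
        amps = insilico_pcr(_primers(), random_dna(rng, 300) + revcomp(R))
        assert len(amps) == 0

    def test_primer_sites_at_template_ends(self, rng):
        """An X-allele template of 458 bp with terminal primer sites yields a
        single full-length 458 bp product."""
        template = F + random_dna(rng, 458 - len(F) - len(R)) + revcomp(R)
        assert insilico_pcr(_primers(), template).lengths == [458]

    def test_all_site_combinations_reported(self, rng):
        filler = random_dna(rng, 50)
        template = F + filler + revcomp(R) + filler + revcomp(R)
        lengths = sorted(insilico_pcr(_primers(), template).lengths)
        assert len(lengths) == 2 and lengths[0] < lengths[1]

    def test_max_product_cap(self, rng):
        template = F + random_dna(rng, 400) + revcomp(R)
        assert insilico_pcr(_primers(), template, max_product=300).lengths == []

    def test_both_strand_search_finds_flipped_template(self, rng):
        template = F + random_dna(rng, 100) + revcomp(R)
        flipped = revcomp(template)
        assert insilico_pcr(_primers(), flipped).lengths == []
        amps = insilico_pcr(_primers(), flipped, search_both_strands=True)
        assert amps.lengths == [len(template)]
        assert amps.products[0].strand == "-"

    def test_mismatch_mode_spares_3prime_terminus(self, rng):
        template = F + random_dna(rng, 60) + revcomp(R)
        mutated = "C" + template[1:] if template[0] != "C" else "G" + template[1:]
        assert insilico_pcr(_primers(), mutated).lengths == []
        assert insilico_pcr(_primers(), mutated, max_mismatches=1).lengths == [len(template)]
        # the same substitution at the forward 3' terminus is never tolerated
        pos = len(F) - 1
        base = "C" if template[pos] != "C" else "G"
        mutated3 = template[:pos] + base + template[pos + 1 :]
        assert insilico_pcr(_primers(), mutated3, max_mismatches=1).lengths == []


class TestGenotypeCalls:
    @pytest.mark.parametrize(
        "x,y,expected,bands",
        [
            ([458], [], "XX", (458,)),
            ([458], [570], "XY", (458, 570)),
            ([], [570], "YY", (570,)),
            ([], [], "NO_CALL", ()),
        ],
    )
    def test_band_logic(self, x, y, expected, bands):
        call = call_genotype(x, y)
        assert call.call == expected
        assert call.bands == bands

    @given(
        x=st.lists(st.integers(50, 3000), max_size=4),
        y=st.lists(st.integers(50, 3000), max_size=4),
    )
    def test_pure_function_of_presence(self, x, y):
        """Order and multiplicity of products never change the call."""
        base = call_genotype(x, y).call
        assert call_genotype(list(reversed(x)), y * 2).call == base
        expected = {
            (True, True): "XY",
            (True, False): "XX",
            (False, True): "YY",
            (False, False): "NO_CALL",
        }[(bool(x), bool(y))]
        assert base == expected


def brute_force_best_score(a, b, match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-1.0):
    """Enumerate every global alignment as a sequence of moves (oracle)."""

    def gap_cost(length):
        return gap_open + (length - 1) * gap_extend

    best = [float("-inf")]

    def walk(i, j, score, last_move):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            walk(i + 1, j + 1, score + s, "M")
        if j < len(b):  # gap in a
            inc = gap_extend if last_move == "Ga" else gap_open
            walk(i, j + 1, score + inc, "Ga")
        if i < len(a):  # gap in b
            inc = gap_extend if last_move == "Gb" else gap_open
            walk(i + 1, j, score + inc, "Gb")

    walk(0, 0, 0.0, None)
    return best[0]


class TestAlignAlleles:
    def test_identical_sequences(self):
        s = align_alleles("ACGTACGT", "ACGTACGT")
        assert s.total_indel_bp == 0
        assert s.identity_pct == 100.0
        assert s.score == 8.0

    def test_single_deletion_example(self):
        s = align_alleles("ACGT", "ACT")
        assert s.total_indel_bp == 1
        assert s.gap_events_in_b == [1] and s.gap_events_in_a == []
        assert s.score == brute_force_best_score("ACGT", "ACT")

    def test_matches_brute_force_on_short_random_pairs(self, rng):
        for _ in range(30):
            a = random_dna(rng, int(rng.integers(1, 9)))
            b = random_dna(rng, int(rng.integers(1, 9)))
            s = align_alleles(a, b)
            assert s.score == pytest.approx(brute_force_best_score(a, b)), (a, b)

    def test_column_classes_partition_alignment(self, rng):
        a, b = random_dna(rng, 120), random_dna(rng, 140)
        s = align_alleles(a, b)
        gapped = sum(s.gap_events_in_a) + sum(s.gap_events_in_b)
        assert s.matches + s.mismatches + gapped == s.aligned_length
        assert s.total_indel_bp == gapped
        assert len(s.aligned_a) == len(s.aligned_b) == s.aligned_length
        assert s.aligned_a.replace("-", "") == a
        assert s.aligned_b.replace("-", "") == b

    def test_four_planted_deletions_sum_to_112(self, rng):
        """X/Y pair built by deleting 16, 7, 68 and 21 bp blocks from a
        Y-like sequence: the alignment reports exactly those four gap
        events on the X side, 112 bp of In/Del in total."""
        y = random_dna(rng, 570)
        blocks = [(60, 16), (180, 7), (300, 68), (460, 21)]
        x, removed = y, 0
        for pos, length in blocks:
            x = x[: pos - removed] + x[pos - removed + length :]
            removed += length
        assert len(y) - len(x) == 112
        s = align_alleles(x, y)
        assert sorted(s.gap_events_in_a) == [7, 16, 21, 68]
        assert s.gap_events_in_b == []
        assert s.total_indel_bp == 112

    def test_score_agrees_with_biopython_on_long_pairs(self, rng):
        """Independent cross-check: optimal score matches Bio.Align's
        affine-gap global aligner on sequences far beyond oracle size."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -1
        for _ in range(5):
            a = random_dna(rng, int(rng.integers(50, 160)))
            b = random_dna(rng, int(rng.integers(50, 160)))
            assert align_alleles(a, b).score == pytest.approx(aligner.score(a, b))

    def test_identity_denominators(self):
        s = align_alleles("AAAATTTT", "AAAATT")
        assert s.identity("columns") == pytest.approx(100 * 6 / 8)
        assert s.identity("shorter") == pytest.approx(100.0)


class TestPrimerPicking:
    @staticmethod
    def _flanks(rng, up_core=None, down_core=None):
        up = random_dna(rng, 150) if up_core is None else up_core
        down = random_dna(rng, 150) if down_core is None else down_core
        return up, down

    def test_wide_windows_yield_candidates(self, rng):
        up, down = self._flanks(rng)
        cw = ConservedWindows(upstream=[(0, 150)], downstream=[(0, 150)])
        pairs = pick_primer_regions(cw, up, down)
        assert pairs
        for p in pairs:
            assert 18 <= len(p.forward) <= 25
            assert 0.40 <= gc_content(p.forward) <= 0.60
            assert p.forward in up
            assert revcomp(p.reverse) in down

    def test_windows_too_short_yield_nothing(self, rng):
        up, down = self._flanks(rng)
        cw = ConservedWindows(upstream=[(0, 12)], downstream=[(0, 150)])
        assert pick_primer_regions(cw, up, down) == []

    def test_unique_planted_windows_recovered(self, rng):
        """Flanks with a single qualifying 20 bp window each: the top-ranked
        pair reproduces them; oracle = exhaustive substring enumeration."""
        fwd_site = "ATCGGCTAGCATCCGGATAT"  # GC 50%
        rev_site = "GCTAGGATCCAATTGCGCAT"
        up = "A" * 65 + fwd_site + "A" * 65
        down = "T" * 65 + rev_site + "T" * 65
        cw = ConservedWindows(upstream=[(60, 90)], downstream=[(60, 90)])
        qualifying = [
            sub
            for L in range(18, 26)
            for i in range(60, 90 - L + 1)
            if 0.4 <= gc_content(sub := up[i : i + L]) <= 0.6
            and up.count(sub) == 1
            and revcomp(sub) not in up
        ]
        pairs = pick_primer_regions(cw, up, down)
        assert pairs and pairs[0].forward in qualifying
        assert pairs[0].forward in "A" * 5 + fwd_site + "A" * 5
        assert revcomp(pairs[0].reverse) in "T" * 5 + rev_site + "T" * 5

    def test_wallace_rule(self):
        assert wallace_tm("ACGT") == 2 * 2 + 4 * 2
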