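"""De Bruijn unitig assembly: reconstruction, branching, pruning, histograms."""

import math
from collections import Counter

import pytest

from conftest import random_dna
from ymarker.assembly import Contig, assemble, length_histogram
from ymarker.errors import ContractError
from ymarker.kmer import canonical, revcomp


def kmerize(seq: str, k: int) -> list[str]:
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def oracle_unitigs(kmers: list[str], k: int) -> set[str]:
    """Exhaustive maximal non-branching path enumeration (independent oracle).

    Walks every oriented k-mer that is a legal path start; no seed-and-extend
    bookkeeping shared with the implementation.
    """
    oriented = set()
    for x in set(kmers):
        oriented.add(x)
        oriented.add(revcomp(x))

    def succ(x):
        return [x[1:] + b for b in "ACGT" if x[1:] + b in oriented]

    def pred(x):
        return [b + x[:-1] for b in "ACGT" if b + x[:-1] in oriented]

    out = set()
    for x in sorted(oriented):
        p = pred(x)
        if len(p) == 1 and len(succ(p[0])) == 1 and canonical(p[0]) != canonical(x):
            continue  # interior k-mer, not a path start
        path = [x]
        seen = {canonical(x)}
        cur = x
        while True:
            s = succ(cur)
            if len(s) != 1:
                break
            nxt = s[0]
            if len(pred(nxt)) != 1 or canonical(nxt) in seen:
                break
            path.append(nxt)
            seen.add(canonical(nxt))
            cur = nxt
        seq = path[0] + "".join(q[-1] for q in path[1:])
        out.add(min(seq, revcomp(seq)))
    return out


class TestReconstruction:
    def test_single_kmer(self):
        contigs = assemble(["ACGTACG"], min_cov=1, min_len=7)
        assert len(contigs) == 1
        assert contigs[0].sequence == min("ACGTACG", revcomp("ACGTACG"))

    def test_repeat_free_500bp_sequence_from_exact_60mers(self, rng):
        seq = random_dna(rng, 500)
        assert len(set(kmerize(seq, 59)) | {revcomp(w) for w in kmerize(seq, 59)}) == 2 * (
            500 - 58
        ), "fixture must be repeat-free at the node length"
        contigs = assemble(kmerize(seq, 60), min_cov=1, min_len=60)
        assert len(contigs) == 1
        assert contigs[0].sequence in (seq, revcomp(seq))

    def test_sub_k_graph_reconstructs_sparse_60mer_sampling(self, rng):
        """60-mers sampled every few bases still overlap at dbg_k < 60 and
        reassemble into the source sequence."""
        seq = random_dna(rng, 400)
        sample = [seq[i : i + 60] for i in range(0, 341, 5)]
        contigs = assemble(sample, min_cov=1, min_len=60, dbg_k=21)
        assert len(contigs) == 1
        assert contigs[0].sequence in (seq, revcomp(seq))

    def test_mixed_kmer_lengths_rejected(self):
        with pytest.raises(ContractError):
            assemble(["ACGTA", "ACGT"], min_cov=1)


class TestBranching:
    def test_unitigs_break_at_shared_node_and_match_oracle(self, rng):
        k = 11
        shared = random_dna(rng, k - 1)
        while shared != min(shared, revcomp(shared)):
            shared = random_dna(rng, k - 1)
        s1 = random_dna(rng, 60) + shared + random_dna(rng, 60)
        s2 = random_dna(rng, 60) + shared + random_dna(rng, 60)
        kmers = kmerize(s1, k) + kmerize(s2, k)
        contigs = assemble(kmers, min_cov=1, min_len=k)
        assert len(contigs) > 2, "the shared node must break the unitigs"
        assert {c.sequence for c in contigs} == oracle_unitigs(kmers, k)

    def test_random_sets_match_oracle(self, rng):
        for trial in range(5):
            seqs = [random_dna(rng, 80) for _ in range(3)]
            kmers = [w for s in seqs for w in kmerize(s, 15)]
            contigs = assemble(kmers, min_cov=1, min_len=15)
            assert {c.sequence for c in contigs} == oracle_unitigs(kmers, 15)


class TestDeterminismAndProvenance:
    def test_input_order_invariance(self, rng):
        seq = random_dna(rng, 300)
        kmers = kmerize(seq, 31)
        a = assemble(kmers, min_cov=1, min_len=31)
        b = assemble(list(reversed(kmers)), min_cov=1, min_len=31)
        assert [(c.id, c.sequence) for c in a] == [(c.id, c.sequence) for c in b]

    def test_output_kmers_subset_of_input_support(self, rng):
        seqs = [random_dna(rng, 120) for _ in range(2)]
        kmers = [w for s in seqs for w in kmerize(s, 21)]
        support = {canonical(w) for w in kmers}
        for contig in assemble(kmers, min_cov=1, min_len=21):
            for w in kmerize(contig.sequence, 21):
                assert canonical(w) in support

    def test_min_cov_prunes_singletons(self, rng):
        seq = random_dna(rng, 200)
        counts = Counter({w: 2 for w in kmerize(seq, 31)})
        counts[random_dna(rng, 31)] = 1  # an error k-mer seen once
        stats: dict = {}
        contigs = assemble(counts, min_cov=2, min_len=31, stats=stats)
        assert stats["n_pruned"] >= 1
        assert len(contigs) == 1 and contigs[0].sequence in (seq, revcomp(seq))
        assert contigs[0].mean_coverage == pytest.approx(2.0)

    def test_short_unitigs_dropped_and_counted(self, rng):
        stats: dict = {}
        contigs = assemble(["ACGTACGTACG"], min_cov=1, min_len=100, stats=stats)
        assert contigs == [] and stats["n_dropped_short"] == 1


class TestLengthHistogram:
    @staticmethod
    def _contigs(lengths):
        return [Contig(id=f"c{i}", sequence="A" * n) for i, n in enumerate(lengths)]

    def test_documented_binning_example(self):
        table = length_histogram(self._contigs([250, 300, 1600]), [250, 500, 1500])
        by_bin = dict(zip(table["bin"], table["fraction"]))
        assert by_bin["[250,500)"] == pytest.approx(2 / 3)
        assert by_bin["[1500,inf)"] == pytest.approx(1 / 3)
        assert table["fraction"].sum() == pytest.approx(1.0)

    def test_empty_input_empty_table(self):
        assert length_histogram([], [100, 200]).empty

    def test_single_contig_single_bin(self):
        table = length_histogram(self._contigs([120]), [100, 200])
        assert table["fraction"].sum() == pytest.approx(1.0)
        assert table.loc[table["count"] == 1, "bin"].tolist() == ["[100,200)"]

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ContractError):
            length_histogram(self._contigs([10]), [200, 100])
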