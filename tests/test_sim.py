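"""Simulator ground truth, read generation, evaluation, and crosses."""

import math

import numpy as np
import pytest

from ymarker.assembly import Contig
from ymarker.errors import ConfigError
from ymarker.kmer import canonical, revcomp
from ymarker.markers import insilico_pcr
from ymarker.sim import (
    SimConfig,
    cross,
    evaluate_candidates,
    simulate_genomes,
    simulate_reads,
)

SMALL = dict(
    autosome_len=20_000,
    x_len=20_000,
    y_divergent_region=(9_000, 2_000),
    n_pool_females=3,
)


@pytest.fixture(scope="module")
def truth():
    return simulate_genomes(SimConfig(seed=42, **SMALL))


class TestConfig:
    def test_rates_validated(self):
        with pytest.raises(ConfigError):
            SimConfig(y_snp_rate=1.5)

    def test_insert_must_cover_read(self):
        with pytest.raises(ConfigError):
            SimConfig(insert_range=(100, 500))

    def test_divergent_region_away_from_ends(self):
        with pytest.raises(ConfigError):
            SimConfig(x_len=20_000, y_divergent_region=(100, 2_000))

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimConfig(seed=9, **SMALL)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert SimConfig.from_yaml(tmp_path / "cfg.yaml") == cfg

    def test_unknown_keys_rejected(self, tmp_path):
        (tmp_path / "cfg.yaml").write_text("seeed: 3\n")
        with pytest.raises(ConfigError):
            SimConfig.from_yaml(tmp_path / "cfg.yaml")


class TestGenomeTruth:
    def test_allele_length_difference_is_total_insertion(self, truth):
        m = truth.marker
        assert len(m.x_allele) == 458
        assert len(m.y_allele) - len(m.x_allele) == sum((16, 7, 68, 21)) == 112

    def test_marker_band_logic_on_truth_alleles(self, truth):
        m = truth.marker
        assert insilico_pcr(m.primers, m.x_allele).lengths == [458]
        assert insilico_pcr(m.primers, m.y_allele).lengths == [570]

    def test_intervals_share_no_kmer_with_female_haplotypes(self, truth):
        """The defining contract of a Y-specific interval."""
        members = truth.female_kmer_index.members
        for s, e in truth.y_specific_intervals:
            seq = truth.y_seq[s : e]
            assert len(seq) >= truth.config.min_truth_interval
            for i in range(len(seq) - 59):
                assert canonical(seq[i : i + 60]) not in members

    def test_marker_core_inside_an_interval(self, truth):
        yc = truth.marker.y_core
        assert any(s <= yc[0] and yc[1] <= e for s, e in truth.y_specific_intervals)

    def test_no_divergence_means_no_intervals(self):
        cfg = SimConfig(
            seed=3, y_insertion_lens=(), y_snp_rate=0.0, **SMALL
        )
        truth = simulate_genomes(cfg)
        assert truth.marker.x_allele == truth.marker.y_allele
        assert truth.y_specific_intervals == []
        assert truth.y_seq == truth.x_ref

    def test_same_seed_identical_truth(self):
        a = simulate_genomes(SimConfig(seed=77, **SMALL))
        b = simulate_genomes(SimConfig(seed=77, **SMALL))
        assert a.y_seq == b.y_seq
        assert a.pop_sites == b.pop_sites
        assert {k: v.haplotypes for k, v in a.individuals.items()} == {
            k: v.haplotypes for k, v in b.individuals.items()
        }


class TestReads:
    def test_error_free_reads_are_haplotype_substrings(self, truth):
        cfg = truth.config
        cfg0 = SimConfig(**{**cfg.to_dict(), "error_rate": 0.0})
        hap = truth.y_seq
        pairs = simulate_reads([hap], cfg0, stream=4, coverage=2)
        assert pairs
        for p in pairs:
            assert p.r1.sequence in hap
            assert revcomp(p.r2.sequence) in hap

    def test_read_and_insert_geometry(self, truth):
        """150 bp mates; implied fragment spans within the 300-500 window."""
        hap = truth.x_ref
        cfg0 = SimConfig(**{**truth.config.to_dict(), "error_rate": 0.0})
        pairs = simulate_reads([hap], cfg0, stream=5, coverage=2)
        for p in pairs:
            assert len(p.r1) == len(p.r2) == 150
            start = hap.find(p.r1.sequence)
            end = hap.find(revcomp(p.r2.sequence)) + 150
            assert 300 <= end - start <= 500

    def test_expected_pair_count(self, truth):
        pairs = simulate_reads([truth.x_ref], truth.config, stream=6, coverage=4)
        expected = len(truth.x_ref) * 4 / (2 * 150)
        assert len(pairs) == round(expected)

    def test_error_positions_flagged_by_quality(self, truth):
        cfg = SimConfig(**{**truth.config.to_dict(), "error_rate": 0.02})
        pairs = simulate_reads([truth.x_ref], cfg, stream=7, coverage=1)
        n_err = 0
        for p in pairs[:50]:
            for base_q in p.r1.qualities + p.r2.qualities:
                assert base_q in (37, 11)
                n_err += base_q == 11
        assert n_err > 0

    def test_same_seed_identical_reads(self, truth):
        a = simulate_reads([truth.x_ref], truth.config, stream=8, coverage=1)
        b = simulate_reads([truth.x_ref], truth.config, stream=8, coverage=1)
        assert [(p.r1.sequence, p.r2.qualities) for p in a] == [
            (p.r1.sequence, p.r2.qualities) for p in b
        ]


class TestEvaluation:
    def test_exact_truth_sequences_score_perfectly(self, truth):
        cands = [
            Contig(id=f"t{i}", sequence=truth.y_seq[s:e])
            for i, (s, e) in enumerate(truth.y_specific_intervals)
        ]
        ev = evaluate_candidates(cands, truth)
        assert ev.recall == 1.0 and ev.precision == 1.0

    def test_no_candidates_undefined_precision(self, truth):
        ev = evaluate_candidates([], truth)
        assert ev.recall == 0.0
        assert math.isnan(ev.precision)

    def test_half_overlap_boundary_counts(self, truth):
        """A candidate straddling an interval edge with exactly half its
        length inside is a true positive (>= convention)."""
        s, e = truth.y_specific_intervals[0]
        cand = Contig(id="edge", sequence=truth.y_seq[e - 75 : e + 75])
        ev = evaluate_candidates([cand], truth, min_overlap_frac=0.5)
        assert ev.n_true_positive == 1
        cand2 = Contig(id="less", sequence=truth.y_seq[e - 74 : e + 76])
        ev2 = evaluate_candidates([cand2], truth, min_overlap_frac=0.5)
        assert ev2.n_true_positive == 0

    def test_revcomp_candidates_count(self, truth):
        s, e = truth.y_specific_intervals[0]
        cand = Contig(id="rc", sequence=revcomp(truth.y_seq[s:e]))
        ev = evaluate_candidates([cand], truth)
        assert ev.n_true_positive == 1


class TestMendelianClosure:
    def test_yy_by_xx_cross_gives_all_xy(self, truth):
        """Offspring of a YY super-male and XX females are uniformly XY —
        the breeding rationale for the marker."""
        rng = np.random.default_rng(5)
        father = truth.individuals["YY1"]
        m = truth.marker
        for name in ("F1", "P1", "P2"):
            mother = truth.individuals[name]
            for _ in range(3):
                child = cross(father, mother, rng)
                assert child.sex_genotype == "XY"
                x_products = [
                    L
                    for h in child.haplotypes_of("X")
                    for L in insilico_pcr(m.primers, h).lengths
                ]
                y_products = [
                    L
                    for h in child.haplotypes_of("Y")
                    for L in insilico_pcr(m.primers, h).lengths
                ]
                assert sorted(set(x_products + y_products)) == [458, 570]
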