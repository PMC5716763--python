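"""End-to-end orchestration of the marker-discovery stages.

``run_study`` executes the three-step discovery scheme on a simulated
experiment — subtractive hybridization (fixed-locus male k-mers minus the
female reference), enrichment (unitig assembly, then exclusion of every
contig sharing a k-mer with the pooled-female reads), and counter-parting
(flank recovery, conserved windows, primer design, in-silico genotyping) —
and returns all stage artifacts plus a count-consistent manifest.

Everything is deterministic given the simulation seed; re-running with an
identical config reproduces identical artifacts.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Sequence

from . import __version__
from .assembly import Contig, assemble
from .errors import DataError, YmarkerError
from .flanks import ConservedWindows, FlankSet, conserved_windows, recover_flanks
from .kmer import KmerIndex, KmerWindow, build_index, revcomp
from .markers import (
    AlignmentSummary,
    GenotypeCall,
    PrimerPair,
    align_alleles,
    call_genotype,
    insilico_pcr,
    pick_primer_regions,
)
from .poolscreen import PoolScreenResult, screen_against_pool
from .seqio import ReadPair, filter_pairs
from .sim import (
    CandidateEvaluation,
    Individual,
    SimConfig,
    TruthSet,
    evaluate_candidates,
    simulate_genomes,
    simulate_reads,
)
from .subtract import SubtractionResult, subtract_kmers

#: De Bruijn edge length used when assembling fixed-locus 60-mers sampled
#: from reads. Chosen by the sampling-density analysis in docs/methods.md.
PIPELINE_DBG_K = 17


class StageError(DataError):
    """A pipeline stage failed; carries the stage name and manifest so far."""

    def __init__(self, stage: str, message: str, manifest: "RunManifest | None" = None):
        self.stage = stage
        self.manifest = manifest
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunManifest:
    """Config snapshot plus per-stage input/output counts."""

    config: dict
    seed: int
    version: str = __version__
    started: float = field(default_factory=time.time)
    finished: float | None = None
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, **counts) -> None:
        self.stages.setdefault(stage, {}).update(counts)

    def validate(self) -> None:
        """Count conservation at every stage boundary."""
        f = self.stages.get("filter", {})
        if f:
            assert f["pairs_kept"] + f["pairs_discarded"] == f["pairs_total"]
        s = self.stages.get("subtract", {})
        if s:
            assert s["kmers_aligned"] + s["kmers_unaligned"] == s["kmers_total"]
        a = self.stages.get("assemble", {})
        p = self.stages.get("poolfilter", {})
        if p and a:
            assert p["retained"] + p["excluded"] == a["contigs"]

    def to_json(self, path=None) -> str:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "started": self.started,
            "finished": self.finished,
            "config": self.config,
            "stages": self.stages,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class MarkerResult:
    """A validated marker: primers plus the band pair they produce."""

    contig_id: str
    primers: PrimerPair
    flanks: FlankSet
    windows: ConservedWindows
    x_band: int
    y_band: int
    alignment: AlignmentSummary | None = None


@dataclass
class StudyResult:
    config: SimConfig
    truth: TruthSet
    manifest: RunManifest
    subtraction: SubtractionResult
    contigs: list[Contig]
    screen: PoolScreenResult
    evaluation: CandidateEvaluation
    marker: MarkerResult | None = None
    genotype_calls: dict[str, GenotypeCall] = field(default_factory=dict)

    @property
    def candidates(self) -> list[Contig]:
        return self.screen.retained

    @property
    def genotypes_correct(self) -> bool:
        expected = self.truth.expected_genotypes()
        return bool(self.genotype_calls) and all(
            self.genotype_calls[n].call == expected[n] for n in self.genotype_calls
        )


def default_study_config(seed: int = 0) -> SimConfig:
    """The desk-scale study conditions: 200 kb autosome + 100 kb X with a
    2 kb divergent envelope, 20x individuals, a pool of 8 females at 5x."""
    return SimConfig(seed=seed, n_pool_females=8)


def run_study(
    config: SimConfig,
    include_marker_stages: bool = True,
    window: KmerWindow = KmerWindow(),
    min_mean_q: int = 30,
    min_cov: int = 2,
    min_len: int | None = None,
    dbg_k: int = PIPELINE_DBG_K,
    max_mismatches: int = 0,
) -> StudyResult:
    """Simulate an experiment and run the full discovery pipeline on it."""
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    k = window.k
    if min_len is None:
        min_len = 2 * k

    truth = simulate_genomes(config)
    male = truth.individuals["M1"]
    male_raw = simulate_reads(male.haplotypes, config, stream=1, id_prefix="M1")
    male_pairs, n_discarded = filter_pairs(male_raw, min_mean_q)
    manifest.record(
        "filter",
        pairs_total=len(male_raw),
        pairs_kept=len(male_pairs),
        pairs_discarded=n_discarded,
    )

    female_index = build_index(truth.female_reference, k=k, source_label="female-ref")
    sub = _stage_subtract(male_pairs, female_index, window, max_mismatches, manifest)

    asm_stats: dict = {}
    contigs = assemble(
        sub.unaligned_kmers, min_cov=min_cov, min_len=min_len, dbg_k=dbg_k, stats=asm_stats
    )
    manifest.record("assemble", contigs=len(contigs), **asm_stats)

    pool_pairs: list[ReadPair] = []
    for i, name in enumerate(sorted(n for n in truth.individuals if n.startswith("P"))):
        reads = simulate_reads(
            truth.individuals[name].haplotypes,
            config,
            stream=100 + i,
            coverage=config.pool_coverage,
            id_prefix=name,
        )
        kept, _ = filter_pairs(reads, min_mean_q)
        pool_pairs.extend(kept)
    pool_index = build_index(
        (r.sequence for pair in pool_pairs for r in (pair.r1, pair.r2)),
        k=k,
        source_label="pool",
    )
    manifest.record("pool", pairs=len(pool_pairs), distinct_kmers=len(pool_index))

    screen = screen_against_pool(contigs, pool_index, max_mismatches=max_mismatches)
    manifest.record(
        "poolfilter",
        retained=len(screen.retained),
        excluded=len(screen.excluded),
        unscreenable=len(screen.unscreenable),
    )

    evaluation = evaluate_candidates(screen.retained, truth)
    manifest.record(
        "evaluate",
        candidates=evaluation.n_candidates,
        true_positives=evaluation.n_true_positive,
        intervals=len(truth.y_specific_intervals),
        intervals_hit=sum(evaluation.intervals_hit),
    )

    result = StudyResult(
        config=config,
        truth=truth,
        manifest=manifest,
        subtraction=sub,
        contigs=contigs,
        screen=screen,
        evaluation=evaluation,
    )

    if include_marker_stages:
        result.marker = discover_marker(
            screen.retained, male_pairs, female_index, truth.individuals
        )
        manifest.record("marker", found=int(result.marker is not None))
        if result.marker is not None:
            for name in sorted(truth.individuals):
                ind = truth.individuals[name]
                result.genotype_calls[name] = genotype_individual(
                    result.marker.primers, ind
                )
            n_ok = sum(
                1
                for n, call in result.genotype_calls.items()
                if call.call == truth.individuals[n].sex_genotype
            )
            manifest.record(
                "genotype", individuals=len(result.genotype_calls), correct=n_ok
            )

    manifest.finished = time.time()
    manifest.validate()
    return result


def _stage_subtract(male_pairs, female_index, window, max_mismatches, manifest):
    if not male_pairs:
        raise StageError("subtract", "no male read pairs on input", manifest)
    try:
        sub = subtract_kmers(
            male_pairs, female_index, window, max_mismatches=max_mismatches
        )
    except YmarkerError as exc:
        raise StageError("subtract", str(exc), manifest) from exc
    manifest.record(
        "subtract",
        kmers_total=sub.total,
        kmers_aligned=sub.aligned_count,
        kmers_unaligned=sub.unaligned_count,
        kmers_distinct_unaligned=sub.distinct_unaligned,
        kmers_skipped=sub.skipped,
    )
    return sub


def discover_marker(
    candidates: Sequence[Contig],
    male_pairs: Sequence[ReadPair],
    female_index: KmerIndex,
    individuals: dict[str, Individual],
    max_anchor_dist: int = 500,
    min_support: int = 2,
) -> MarkerResult | None:
    """Counter-parting: find candidate flanks that yield a working marker.

    Every recovered flank with conserved windows is an *amplicon arm*.
    Because an assembled candidate's orientation is arbitrary and the
    divergent locus may fragment into several candidates, arms are taken in
    both orientations and amplicon designs pair any upstream arm with any
    downstream arm (same-candidate, natural-frame pairs first). Each primer
    pair drawn from an arm pair is validated by the in-silico analogue of
    the wet PCR screen: it must amplify exactly one band in an XX female
    and, in the XY male, that same X band plus exactly one Y band of a
    different length. Returns None when nothing validates.
    """
    male = individuals["M1"]
    female = next(
        individuals[n] for n in sorted(individuals) if individuals[n].sex_genotype == "XX"
    )
    ordered = sorted(candidates, key=lambda c: (-len(c), c.id))
    arms: list[tuple[Contig, str, str, str, list[tuple[int, int]], int]] = []
    for cand in ordered:
        fl = recover_flanks(
            cand, male_pairs, max_anchor_dist=max_anchor_dist, min_support=min_support
        )
        for side, seq, support in (
            ("up", fl.upstream, fl.support_upstream),
            ("down", fl.downstream, fl.support_downstream),
        ):
            if seq is None:
                continue
            wins = conserved_windows(seq, female_index)
            if not wins:
                continue
            arms.append((cand, side, "+", seq, wins, support))
            arms.append((cand, side, "-", revcomp(seq), _mirror(wins, len(seq)), support))

    def natural(u, d) -> bool:
        return u[0].id == d[0].id and (u[1], u[2], d[1], d[2]) == ("up", "+", "down", "+")

    combos = [
        (u, d)
        for u in arms
        for d in arms
        if (u[0].id, u[1], u[2]) != (d[0].id, d[1], d[2])
    ]
    combos.sort(key=lambda ud: (not natural(*ud), -len(ud[0][0]), -len(ud[1][0])))
    for u, d in combos[:400]:
        marker = _validate_arm_pair(u, d, female, male)
        if marker is not None:
            return marker
    return None


def _mirror(windows: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    return sorted((length - e, length - s) for s, e in windows)


def _validate_arm_pair(up, down, female: Individual, male: Individual) -> MarkerResult | None:
    cu, u_side, u_orient, u_seq, u_wins, u_sup = up
    cd, d_side, d_orient, d_seq, d_wins, d_sup = down
    cw = ConservedWindows(upstream=u_wins, downstream=d_wins)
    for primers in pick_primer_regions(cw, u_seq, d_seq):
        female_bands = _bands(primers, female, "X")
        male_x = _bands(primers, male, "X")
        male_y = _bands(primers, male, "Y")
        if len(female_bands) != 1 or male_x != female_bands or len(male_y) != 1:
            continue
        x_band = next(iter(female_bands))
        y_band = next(iter(male_y))
        if y_band == x_band:
            continue
        cu.stage = "validated"
        cd.stage = "validated"
        if cu.id == cd.id and (u_side, u_orient, d_side, d_orient) == ("up", "+", "down", "+"):
            label = cu.id
        else:
            label = f"{cu.id}:{u_side}{u_orient}+{cd.id}:{d_side}{d_orient}"
        fl = FlankSet(
            contig_id=label,
            upstream=u_seq,
            downstream=d_seq,
            support_upstream=u_sup,
            support_downstream=d_sup,
        )
        marker = MarkerResult(
            contig_id=label,
            primers=primers,
            flanks=fl,
            windows=cw,
            x_band=x_band,
            y_band=y_band,
        )
        marker.alignment = _allele_alignment(primers, female, male)
        return marker
    return None


def _bands(primers: PrimerPair, individual: Individual, chrom_class: str) -> set[int]:
    bands: set[int] = set()
    for hap in individual.haplotypes_of(chrom_class):
        bands.update(insilico_pcr(primers, hap, search_both_strands=True).lengths)
    return bands


def _allele_alignment(
    primers: PrimerPair, female: Individual, male: Individual
) -> AlignmentSummary | None:
    """Align the amplified X and Y allele sequences (plus-strand products)."""

    def first_product(individual: Individual, chrom_class: str) -> str | None:
        for hap in individual.haplotypes_of(chrom_class):
            amps = insilico_pcr(primers, hap, search_both_strands=True)
            if amps.products:
                return amps.products[0].sequence
        return None

    x_seq = first_product(female, "X")
    y_seq = first_product(male, "Y")
    if x_seq is None or y_seq is None:
        return None
    return align_alleles(x_seq, y_seq)


def genotype_individual(primers: PrimerPair, individual: Individual) -> GenotypeCall:
    """Genotype one individual from its sex-chromosome haplotypes.

    Products are grouped by the haplotype class (X or Y) they amplified
    from; autosomes are not templates for a sex marker and are skipped.
    """
    x_products: list[int] = []
    y_products: list[int] = []
    for label in sorted(individual.haplotypes):
        if label.startswith("A"):
            continue
        lengths = insilico_pcr(
            primers, individual.haplotypes[label], search_both_strands=True
        ).lengths
        if label.startswith("X"):
            x_products.extend(lengths)
        else:
            y_products.extend(lengths)
    return call_genotype(x_products, y_products)
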