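"""Synthetic XY-genome and paired-end read simulator, with ground truth.

The generator emulates the study design the discovery pipeline targets: a
fish-like species with male heterogamety (XX/XY), a young Y whose
divergence from X is confined to one region, an individual male and female,
and a pooled female library used to subtract population-level variation.

Genome model
------------
One autosome and an X are drawn uniformly at random. The Y is a copy of the
X whose divergent envelope (default 2 kb, placed away from the chromosome
ends by more than the maximum insert) is laid out as::

    [ diverged block A | conserved gap | marker core | conserved gap | diverged block C ]

Diverged blocks and the core carry substitutions at ``y_snp_rate``
(default 0.15, matching the low-80s% X/Y homology typical of a validated
marker locus); the core additionally carries insertions of the configured
lengths (default 16, 7, 68, 21 bp, totalling 112 bp), so the X allele shows
exactly those deletions relative to Y. The marker X allele is the core plus
one conserved arm on each side (458 bp total by default; the Y allele is
570 bp), and the truth primer pair is the first/last 20 bp of the X allele
— conserved, so it amplifies both alleles.

Population variation is modeled as shared biallelic SNP sites (rate
``pop_snp_rate``, allele frequencies ~ U(0.2, 0.8)) sampled once and drawn
per haplotype, so an individual's non-reference k-mers are usually present
somewhere in the pool — the property the pool screen relies on. The default
rate (2e-4) describes a low-diversity aquaculture population, for which a
small pool statistically captures the common variation the way a 48-female
pool does for a wild population. The
divergent envelope plus a one-gap margin carries no sites, emulating the
fixed-conserved primer regions a validated marker is implicitly selected
for.

Reads are 150 bp FR pairs from 300-500 bp fragments, uniform start,
substitution errors only, constant Q37 with errors downgraded to Q11.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import ConfigError, DataError
from .kmer import KmerIndex, build_index, canonical, revcomp
from .markers import PrimerPair, insilico_pcr
from .seqio import Read, ReadPair

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(DataError):
    """The simulated divergence violated its own k-mer-disjointness contract."""


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment (all lengths in bp)."""

    seed: int = 0
    autosome_len: int = 200_000
    x_len: int = 100_000
    y_divergent_region: tuple[int, int] = (49_000, 2_000)  # (start, length) on X
    y_insertion_lens: tuple[int, ...] = (16, 7, 68, 21)
    y_snp_rate: float = 0.15
    pop_snp_rate: float = 0.0002
    n_pool_females: int = 48
    read_len: int = 150
    insert_range: tuple[int, int] = (300, 500)
    error_rate: float = 0.001
    coverage: float = 20.0  # per-haplotype fold for individual libraries
    pool_coverage: float = 5.0  # per-haplotype fold per pool female
    marker_x_allele_len: int = 458
    marker_arm_len: int = 155  # conserved arm on each side of the core
    conserved_gap: int = 200  # X/Y-identical spacer around the marker core
    min_truth_interval: int = 120  # shorter Y-specific islands are sub-marker scale

    def __post_init__(self):
        self.y_divergent_region = tuple(self.y_divergent_region)
        self.y_insertion_lens = tuple(self.y_insertion_lens)
        self.insert_range = tuple(self.insert_range)
        self.validate()

    def validate(self) -> None:
        for name in ("y_snp_rate", "pop_snp_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.insert_range[0] < self.read_len:
            raise ConfigError("minimum insert must be >= read length")
        if self.insert_range[0] > self.insert_range[1]:
            raise ConfigError("insert_range must be (min, max)")
        if min(self.autosome_len, self.x_len) <= 0:
            raise ConfigError("chromosome lengths must be positive")
        start, length = self.y_divergent_region
        if length > 0:
            if start < self.insert_range[1] or start + length > self.x_len - self.insert_range[1]:
                raise ConfigError(
                    "divergent region must sit at least one maximum insert from the X ends"
                )
            if self.core_x_len < len(self.y_insertion_lens) + 1:
                raise ConfigError("marker core too short for the configured insertions")
            if self.marker_arm_len > self.conserved_gap:
                raise ConfigError("marker arm must fit inside the conserved gap")
            if length < self.core_x_len + 2 * self.conserved_gap:
                raise ConfigError("divergent region too short for the marker layout")

    @property
    def core_x_len(self) -> int:
        return self.marker_x_allele_len - 2 * self.marker_arm_len

    # -- structured-text round trip ------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("y_divergent_region", "y_insertion_lens", "insert_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class Individual:
    """A simulated diploid (or YY) individual with phased haplotypes."""

    name: str
    sex_genotype: str  # XX | XY | YY
    haplotypes: dict[str, str]  # labels A*/X*/Y* -> sequence

    def haplotypes_of(self, chrom_class: str) -> list[str]:
        return [s for label, s in sorted(self.haplotypes.items()) if label.startswith(chrom_class)]


@dataclass
class MarkerTruth:
    x_allele: str
    y_allele: str
    primers: PrimerPair
    x_core: tuple[int, int]  # core interval on the X reference
    y_core: tuple[int, int]  # core interval on the Y


@dataclass
class TruthSet:
    """Ground truth for one simulated experiment."""

    config: SimConfig
    autosome_ref: str
    x_ref: str
    y_seq: str
    pop_sites: dict[str, list[tuple[int, str, float]]]
    individuals: dict[str, Individual]
    y_specific_intervals: list[tuple[int, int]]
    marker: MarkerTruth | None
    female_kmer_index: KmerIndex  # all 60-mers of every simulated female haplotype

    @property
    def female_reference(self) -> list[str]:
        """The assembled female genome: reference autosome + X contigs."""
        return [self.autosome_ref, self.x_ref]

    def expected_genotypes(self) -> dict[str, str]:
        return {name: ind.sex_genotype for name, ind in self.individuals.items()}


# -- sequence helpers --------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _snp_mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for p in hits:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _apply_sites(
    seq: str, carried: list[tuple[int, str]]
) -> str:
    if not carried:
        return seq
    arr = bytearray(seq.encode())
    for pos, alt in carried:
        arr[pos] = ord(alt)
    return arr.decode()


# -- genome simulation -------------------------------------------------------


def simulate_genomes(config: SimConfig, max_attempts: int = 10) -> TruthSet:
    """Draw genomes, individuals and ground truth; deterministic given seed.

    Regenerates (fresh draw, same config) if the planted divergence fails
    its self-checks — the marker core not landing in a Y-specific interval,
    or the truth primers not producing the single expected product per
    allele; raises GenerationError after ``max_attempts``.
    """
    for attempt in range(max_attempts):
        rng = np.random.default_rng([config.seed % (2**31), attempt])
        truth = _simulate_once(config, rng)
        if _truth_ok(truth):
            return truth
    raise GenerationError(
        f"could not generate a valid divergent region in {max_attempts} attempts; "
        "consider a larger or more divergent region"
    )


def _simulate_once(config: SimConfig, rng: np.random.Generator) -> TruthSet:
    autosome = _random_seq(rng, config.autosome_len)
    x_ref = _random_seq(rng, config.x_len)

    env_start, env_len = config.y_divergent_region
    marker: MarkerTruth | None = None
    if env_len > 0:
        core_x_len = config.core_x_len
        gap = config.conserved_gap
        rest = env_len - core_x_len - 2 * gap
        a_len = rest // 2
        c_len = rest - a_len
        core_x_start = env_start + a_len + gap
        core_x_end = core_x_start + core_x_len

        block_a = _snp_mutate(x_ref[env_start : env_start + a_len], config.y_snp_rate, rng)
        core_y = _mutate_core(
            x_ref[core_x_start:core_x_end], config.y_insertion_lens, config.y_snp_rate, rng
        )
        block_c = _snp_mutate(x_ref[core_x_end + gap : env_start + env_len], config.y_snp_rate, rng)
        y_seq = (
            x_ref[:env_start]
            + block_a
            + x_ref[env_start + a_len : core_x_start]
            + core_y
            + x_ref[core_x_end : core_x_end + gap]
            + block_c
            + x_ref[env_start + env_len :]
        )
        y_core = (core_x_start, core_x_start + len(core_y))
        arm = config.marker_arm_len
        x_allele = x_ref[core_x_start - arm : core_x_end + arm]
        y_allele = y_seq[y_core[0] - arm : y_core[1] + arm]
        primers = PrimerPair(
            name="markerXY", forward=x_allele[:20], reverse=revcomp(x_allele[-20:])
        )
        marker = MarkerTruth(
            x_allele=x_allele,
            y_allele=y_allele,
            primers=primers,
            x_core=(core_x_start, core_x_end),
            y_core=y_core,
        )
    else:
        y_seq = x_ref

    # shared polymorphic sites; none inside the divergent envelope + margin
    margin = config.conserved_gap
    excluded = (max(0, env_start - margin), min(config.x_len, env_start + env_len + margin))
    pop_sites = {
        "A": _draw_sites(autosome, config.pop_snp_rate, rng, None),
        "X": _draw_sites(x_ref, config.pop_snp_rate, rng, excluded if env_len > 0 else None),
    }

    individuals: dict[str, Individual] = {}
    # F1: the reference individual whose reads built the female assembly
    individuals["F1"] = Individual(
        name="F1",
        sex_genotype="XX",
        haplotypes={"A1": autosome, "A2": autosome, "X1": x_ref, "X2": x_ref},
    )
    individuals["M1"] = Individual(
        name="M1",
        sex_genotype="XY",
        haplotypes={
            "A1": _draw_haplotype(autosome, pop_sites["A"], rng),
            "A2": _draw_haplotype(autosome, pop_sites["A"], rng),
            "X1": _draw_haplotype(x_ref, pop_sites["X"], rng),
            "Y1": y_seq,
        },
    )
    individuals["YY1"] = Individual(
        name="YY1", sex_genotype="YY", haplotypes={"Y1": y_seq, "Y2": y_seq}
    )
    for i in range(config.n_pool_females):
        name = f"P{i + 1}"
        individuals[name] = Individual(
            name=name,
            sex_genotype="XX",
            haplotypes={
                "A1": _draw_haplotype(autosome, pop_sites["A"], rng),
                "A2": _draw_haplotype(autosome, pop_sites["A"], rng),
                "X1": _draw_haplotype(x_ref, pop_sites["X"], rng),
                "X2": _draw_haplotype(x_ref, pop_sites["X"], rng),
            },
        )

    female_index = _female_kmer_index(autosome, x_ref, pop_sites, individuals)
    intervals = _y_specific_intervals(y_seq, female_index, config.min_truth_interval)

    return TruthSet(
        config=config,
        autosome_ref=autosome,
        x_ref=x_ref,
        y_seq=y_seq,
        pop_sites=pop_sites,
        individuals=individuals,
        y_specific_intervals=intervals,
        marker=marker,
        female_kmer_index=female_index,
    )


def _mutate_core(
    core_x: str, insertion_lens: Sequence[int], snp_rate: float, rng: np.random.Generator
) -> str:
    """SNP-mutate the core, then plant insertions at evenly spread positions."""
    mutated = _snp_mutate(core_x, snp_rate, rng)
    k = len(insertion_lens)
    pieces = []
    prev = 0
    for i, ins_len in enumerate(insertion_lens):
        pos = len(core_x) * (i + 1) // (k + 1)
        pieces.append(mutated[prev:pos])
        pieces.append(_random_seq(rng, ins_len))
        prev = pos
    pieces.append(mutated[prev:])
    return "".join(pieces)


def _draw_sites(
    seq: str, rate: float, rng: np.random.Generator, excluded: tuple[int, int] | None
) -> list[tuple[int, str, float]]:
    sites = []
    positions = np.flatnonzero(rng.random(len(seq)) < rate)
    freqs = rng.uniform(0.2, 0.8, positions.size)
    alt_draws = rng.integers(0, 3, positions.size)
    for pos, freq, draw in zip(positions, freqs, alt_draws):
        if excluded is not None and excluded[0] <= pos < excluded[1]:
            continue
        ref = seq[pos]
        alt = [b for b in "ACGT" if b != ref][draw]
        sites.append((int(pos), alt, float(freq)))
    return sites


def _draw_haplotype(
    ref: str, sites: list[tuple[int, str, float]], rng: np.random.Generator
) -> str:
    carried = [(pos, alt) for pos, alt, freq in sites if rng.random() < freq]
    return _apply_sites(ref, carried)


def _female_kmer_index(
    autosome: str,
    x_ref: str,
    pop_sites: dict,
    individuals: dict[str, Individual],
    k: int = 60,
) -> KmerIndex:
    """Every k-mer of every simulated female haplotype.

    Haplotypes equal the reference away from their carried sites, so the
    exact union is the reference k-mers plus, per female haplotype, the
    k-mers of windows overlapping carried sites.
    """
    index = build_index([autosome, x_ref], k=k, source_label="female-haplotypes")
    ref_of = {"A": autosome, "X": x_ref}
    positions = {
        chrom: {pos: alt for pos, alt, _ in sites} for chrom, sites in pop_sites.items()
    }
    for ind in individuals.values():
        if "Y" in ind.sex_genotype:
            continue
        for label, hap in ind.haplotypes.items():
            chrom = label[0]
            ref = ref_of[chrom]
            for pos, alt in positions[chrom].items():
                if hap[pos] == alt and hap[pos] != ref[pos]:
                    lo = max(0, pos - k + 1)
                    hi = min(len(hap), pos + k)
                    index.update_from_sequences([hap[lo:hi]])
    return index


def _y_specific_intervals(
    y_seq: str, female_index: KmerIndex, min_len: int, k: int = 60
) -> list[tuple[int, int]]:
    """Maximal runs of Y k-mers absent from every female haplotype.

    Runs shorter than ``min_len`` are below marker scale and excluded from
    the truth (they cannot support an assembled candidate).
    """
    intervals = []
    run_start = None
    last_absent = None
    for p in range(len(y_seq) - k + 1):
        absent = canonical(y_seq[p : p + k]) not in female_index.members
        if absent:
            if run_start is None:
                run_start = p
            last_absent = p
        elif run_start is not None:
            intervals.append((run_start, last_absent + k))
            run_start = None
    if run_start is not None:
        intervals.append((run_start, last_absent + k))
    return [(s, e) for s, e in intervals if e - s >= min_len]


def _truth_ok(truth: TruthSet) -> bool:
    cfg = truth.config
    if truth.marker is None:
        return True
    m = truth.marker
    if len(m.y_allele) - len(m.x_allele) != sum(cfg.y_insertion_lens):
        return False
    if cfg.y_snp_rate > 0 or cfg.y_insertion_lens:
        # the marker core must be Y-specific and inside one truth interval
        yc = m.y_core
        if not any(s <= yc[0] and yc[1] <= e for s, e in truth.y_specific_intervals):
            return False
        # truth primers must yield exactly the one expected product per allele
        for template, expect in ((m.x_allele, len(m.x_allele)), (m.y_allele, len(m.y_allele))):
            if insilico_pcr(m.primers, template).lengths != [expect]:
                return False
        for hap, expect in ((truth.x_ref, len(m.x_allele)), (truth.y_seq, len(m.y_allele))):
            if insilico_pcr(m.primers, hap).lengths != [expect]:
                return False
    # self-check of the interval contract (holds by construction)
    for s, e in truth.y_specific_intervals:
        seq = truth.y_seq[s:e]
        for i in range(len(seq) - 59):
            if canonical(seq[i : i + 60]) in truth.female_kmer_index.members:
                return False
    return True


# -- read simulation ---------------------------------------------------------


def simulate_reads(
    haplotypes: Sequence[str] | dict[str, str],
    config: SimConfig,
    stream: int = 0,
    coverage: float | None = None,
    id_prefix: str = "sim",
) -> list[ReadPair]:
    """FR paired-end reads from a set of haplotypes.

    Fragment starts are uniform, lengths uniform over ``insert_range``;
    r1 is the plus-strand 5' end of the fragment, r2 the reverse complement
    of its 3' end. Substitution errors at ``error_rate``; qualities are a
    constant Q37 with error positions downgraded to Q11. The expected pair
    count is total_length * coverage / (2 * read_len). ``stream`` decouples
    independent libraries drawn from the same seed.
    """
    if isinstance(haplotypes, dict):
        haps = [haplotypes[k] for k in sorted(haplotypes)]
    else:
        haps = list(haplotypes)
    if not haps:
        return []
    cov = config.coverage if coverage is None else coverage
    rlen = config.read_len
    ins_lo, ins_hi = config.insert_range
    for h in haps:
        if len(h) < ins_hi:
            raise DataError(
                f"haplotype of length {len(h)} shorter than the maximum insert {ins_hi}"
            )
    total = sum(len(h) for h in haps)
    n_pairs = int(round(total * cov / (2 * rlen)))
    rng = np.random.default_rng([config.seed % (2**31), 7919, stream % (2**31)])

    weights = np.array([len(h) for h in haps], dtype=float)
    weights /= weights.sum()
    hap_idx = rng.choice(len(haps), size=n_pairs, p=weights)
    frag_lens = rng.integers(ins_lo, ins_hi + 1, size=n_pairs)
    u = rng.random(n_pairs)

    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        hap = haps[hap_idx[i]]
        f = int(frag_lens[i])
        start = int(u[i] * (len(hap) - f + 1))
        fragment = hap[start : start + f]
        r1_seq = fragment[:rlen]
        r2_seq = revcomp(fragment[-rlen:])
        r1_seq, q1 = _apply_errors(r1_seq, config.error_rate, rng)
        r2_seq, q2 = _apply_errors(r2_seq, config.error_rate, rng)
        name = f"{id_prefix}:{i}"
        pairs.append(
            ReadPair(
                r1=Read(id=f"{name}/1", sequence=r1_seq, qualities=q1),
                r2=Read(id=f"{name}/2", sequence=r2_seq, qualities=q2),
            )
        )
    return pairs


def _apply_errors(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, list[int]]:
    quals = [37] * len(seq)
    if rate <= 0:
        return seq, quals
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq, quals
    arr = bytearray(seq.encode())
    positions = rng.choice(len(seq), size=n_err, replace=False)
    for p in positions:
        choices = [b for b in b"ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
        quals[p] = 11
    return arr.decode(), quals


# -- evaluation and crosses --------------------------------------------------


@dataclass
class CandidateEvaluation:
    recall: float  # NaN when the truth has no intervals
    precision: float  # NaN when there are no candidates
    n_candidates: int
    n_true_positive: int
    intervals_hit: list[bool]


def evaluate_candidates(
    candidates: Iterable, truth: TruthSet, min_overlap_frac: float = 0.5
) -> CandidateEvaluation:
    """Interval-overlap scoring of candidate contigs against the truth.

    A candidate is a true positive iff at least ``min_overlap_frac`` of its
    length exact-matches (either orientation) inside one Y-specific truth
    interval; recall is the fraction of intervals hit, precision the
    fraction of candidates that are true positives.
    """
    intervals = truth.y_specific_intervals
    hit = [False] * len(intervals)
    n_cand = 0
    n_tp = 0
    y = truth.y_seq
    for cand in candidates:
        seq = cand.sequence if hasattr(cand, "sequence") else str(cand)
        n_cand += 1
        placements = _occurrences(y, seq) + _occurrences(y, revcomp(seq))
        is_tp = False
        for ps in placements:
            pe = ps + len(seq)
            for idx, (s, e) in enumerate(intervals):
                overlap = min(pe, e) - max(ps, s)
                if overlap / len(seq) >= min_overlap_frac:
                    is_tp = True
                    hit[idx] = True
        if is_tp:
            n_tp += 1
    recall = sum(hit) / len(intervals) if intervals else float("nan")
    precision = n_tp / n_cand if n_cand else float("nan")
    return CandidateEvaluation(
        recall=recall,
        precision=precision,
        n_candidates=n_cand,
        n_true_positive=n_tp,
        intervals_hit=hit,
    )


def _occurrences(haystack: str, needle: str) -> list[int]:
    out, start = [], haystack.find(needle)
    while start != -1:
        out.append(start)
        start = haystack.find(needle, start + 1)
    return out


def cross(father: Individual, mother: Individual, rng: np.random.Generator) -> Individual:
    """One offspring of a cross: one sex haplotype and one autosome per parent."""

    def gamete(parent: Individual) -> dict[str, str]:
        sex = [l for l in parent.haplotypes if l[0] in "XY"]
        auto = [l for l in parent.haplotypes if l.startswith("A")]
        picked = {}
        label = sex[rng.integers(0, len(sex))]
        picked[label[0]] = parent.haplotypes[label]
        if auto:
            picked["A"] = parent.haplotypes[auto[rng.integers(0, len(auto))]]
        return picked

    g_f, g_m = gamete(father), gamete(mother)
    haplotypes = {}
    sex_labels = []
    for i, g in enumerate((g_f, g_m), start=1):
        for cls, seq in g.items():
            if cls == "A":
                haplotypes[f"A{i}"] = seq
            else:
                sex_labels.append(cls)
                haplotypes[f"{cls}{i}"] = seq
    genotype = "".join(sorted(sex_labels))
    return Individual(name="offspring", sex_genotype=genotype, haplotypes=haplotypes)
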