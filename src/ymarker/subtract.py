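"""In-silico subtractive hybridization.

Every male read contributes one fixed-locus 60-mer (each mate an independent
locus). A k-mer "aligns" iff its canonical form is a member of the female
reference index (optionally within a 1-mismatch neighborhood); the retained
unaligned multiset is the male-specific k-mer pool fed to assembly.
Multiplicities are preserved so that assembly can prune sequencing-error
k-mers by coverage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .errors import ConfigError
from .kmer import KmerIndex, KmerWindow, canonical, extract_fixed_kmer
from .seqio import ReadPair


@dataclass
class SubtractionResult:
    """Outcome of classifying male k-mers against the female index."""

    total: int = 0  # k-mers extracted (skips excluded)
    aligned_count: int = 0
    unaligned_count: int = 0
    skipped: int = 0  # reads too short / N in window
    unaligned_kmers: Counter = field(default_factory=Counter)

    @property
    def distinct_unaligned(self) -> int:
        return len(self.unaligned_kmers)

    def validate(self) -> None:
        assert self.aligned_count + self.unaligned_count == self.total
        assert self.unaligned_count == sum(self.unaligned_kmers.values())

    def stats_line(self) -> str:
        """Tab-separated flow counts (total, aligned, unaligned, distinct, skipped)."""
        return (
            f"{self.total}\t{self.aligned_count}\t{self.unaligned_count}"
            f"\t{self.distinct_unaligned}\t{self.skipped}"
        )


def subtract_kmers(
    male_pairs: Iterable[ReadPair],
    female_index: KmerIndex,
    window: KmerWindow = KmerWindow(),
    max_mismatches: int = 0,
) -> SubtractionResult:
    """Classify each male fixed-locus k-mer against the female reference.

    Deterministic for fixed inputs. Unaligned k-mers are stored canonically
    with multiplicity; duplicates are retained (both raw and distinct counts
    are reported).
    """
    if female_index.k != window.k:
        raise ConfigError(
            f"female index k={female_index.k} does not match window k={window.k}"
        )
    res = SubtractionResult()
    for pair in male_pairs:
        for read in (pair.r1, pair.r2):
            kmer = extract_fixed_kmer(read, window)
            if kmer is None:
                res.skipped += 1
                continue
            res.total += 1
            if female_index.contains(kmer, max_mismatches=max_mismatches):
                res.aligned_count += 1
            else:
                res.unaligned_count += 1
                res.unaligned_kmers[canonical(kmer)] += 1
    res.validate()
    return res
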