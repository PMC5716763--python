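"""Enrichment screen against the pooled-female library.

A candidate contig is excluded as soon as any one of its canonical
``screen_k``-mers (default 60) occurs in the pool-read index: sharing even a
single window with any female read means the sequence is not Y-specific.
Survivors are promoted to stage "candidate". The first matching
(contig offset, k-mer) pair is recorded per exclusion for auditability.

This is the symmetric, well-defined replacement for aligning contigs
(query) against 150 bp reads (reference): the "any read hit -> exclude"
semantics is preserved, and adding pool reads can only move contigs from
retained to excluded (monotone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .assembly import Contig
from .kmer import KmerIndex, canonical


@dataclass
class Exclusion:
    """Audit record: why a contig was excluded."""

    contig: Contig
    offset: int  # 0-based offset of the first matching window in the contig
    kmer: str  # canonical form of the matching window


@dataclass
class PoolScreenResult:
    retained: list[Contig] = field(default_factory=list)
    excluded: list[Exclusion] = field(default_factory=list)
    unscreenable: list[Contig] = field(default_factory=list)  # shorter than screen_k
    screen_k: int = 60

    def validate(self, n_input: int) -> None:
        assert len(self.retained) + len(self.excluded) == n_input
        retained_ids = {c.id for c in self.retained}
        assert not retained_ids & {e.contig.id for e in self.excluded}


def screen_against_pool(
    contigs: Iterable[Contig],
    pool_index: KmerIndex,
    max_mismatches: int = 0,
) -> PoolScreenResult:
    """Partition contigs into pool-clean candidates and excluded contigs.

    Contigs shorter than ``pool_index.k`` cannot be screened; they are
    retained with ``unscreenable=True`` and also listed separately.
    """
    k = pool_index.k
    res = PoolScreenResult(screen_k=k)
    n_input = 0
    for contig in contigs:
        n_input += 1
        if len(contig) < k:
            contig.unscreenable = True
            contig.stage = "candidate"
            res.unscreenable.append(contig)
            res.retained.append(contig)
            continue
        hit = None
        seq = contig.sequence
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if pool_index.contains(window, max_mismatches=max_mismatches):
                hit = Exclusion(contig=contig, offset=i, kmer=canonical(window))
                break
        if hit is None:
            contig.stage = "candidate"
            res.retained.append(contig)
        else:
            res.excluded.append(hit)
    res.validate(n_input)
    return res
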