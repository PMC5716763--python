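"""Flank recovery by mate anchoring, and conserved-window detection.

A validated Y-specific contig is too short to place primers on directly when
its own sequence has no X counterpart. The homologous-cloning trick instead
recovers the sequence immediately up- and downstream of the contig from the
male library's paired reads: a pair is *anchored* when one mate matches the
contig exactly (either orientation) near one end while its partner does not
match at all — the partner must then lie in the flank. Partner reads are
placed at base resolution by maximal exact suffix/prefix overlap with the
growing contig+flank consensus (the per-fragment insert length, uniform in
300-500 bp, cannot position a mate exactly on its own), and a per-column
majority vote yields up to one read length (150 bp) of flank per side.

Conserved windows then mark every flank position covered by a full-length
female k-mer: those stretches exist on both X and Y and are where primers
can bind in both sexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .assembly import Contig
from .kmer import KmerIndex, canonical, revcomp
from .seqio import ReadPair

_ACGT = frozenset("ACGT")


@dataclass
class FlankSet:
    """Recovered flanks of one contig (None where support was insufficient)."""

    contig_id: str
    upstream: str | None = None
    downstream: str | None = None
    support_upstream: int = 0
    support_downstream: int = 0
    ties_upstream: int = 0  # consensus columns decided by the lexicographic tie-break
    ties_downstream: int = 0

    @property
    def is_empty(self) -> bool:
        return self.upstream is None and self.downstream is None


@dataclass
class ConservedWindows:
    """Per-flank intervals (0-based half-open) covered by female k-mers."""

    upstream: list[tuple[int, int]] = field(default_factory=list)
    downstream: list[tuple[int, int]] = field(default_factory=list)


def recover_flanks(
    contig: Contig,
    male_pairs: Iterable[ReadPair],
    max_anchor_dist: int = 500,
    min_support: int = 2,
    flank_len: int = 150,
    min_overlap: int = 15,
    end_overlap: int = 30,
) -> FlankSet:
    """Recover up to ``flank_len`` bp of sequence flanking a contig.

    Two evidence classes feed each flank pile:

    * **mate anchoring** (FR geometry in the contig's frame): a pair whose
      one mate matches the contig exactly while the other does not. A
      reverse-complement match near the left end puts the partner (as
      sequenced) in the upstream pile; a forward match near the right end
      puts the partner's reverse complement in the downstream pile.
    * **end-overlapping reads**: any read whose exact suffix/prefix overlap
      with a contig end is at least ``end_overlap`` bp while the read
      extends beyond it. These bridge the junction, which mate-anchored
      partners alone (insert 300-500 bp) often cannot.

    Piles with fewer than ``min_support`` placeable reads yield an absent
    flank; a contig with no evidence yields an empty FlankSet.
    """
    cseq = contig.sequence
    left_pile: list[str] = []
    right_pile: list[str] = []
    for pair in male_pairs:
        mates = (pair.r1.sequence, pair.r2.sequence)
        hits = []
        for m in mates:
            if not _ACGT.issuperset(m):
                hits.append(None)
                continue
            fwd_pos = cseq.find(m)
            rc_pos = cseq.find(revcomp(m))
            if fwd_pos == -1 and rc_pos == -1:
                hits.append(None)
                for oriented in (m, revcomp(m)):
                    for side in _end_overlap_sides(oriented, cseq, end_overlap):
                        (left_pile if side == "left" else right_pile).append(oriented)
            else:
                hits.append((fwd_pos, rc_pos))
        matched = [i for i, h in enumerate(hits) if h is not None]
        if len(matched) != 1:
            continue  # unanchored (0 hits) or uninformative (both mates inside)
        anchor_idx = matched[0]
        partner = mates[1 - anchor_idx]
        fwd_pos, rc_pos = hits[anchor_idx]
        mlen = len(mates[anchor_idx])
        if fwd_pos != -1 and len(cseq) - (fwd_pos + mlen) <= max_anchor_dist:
            right_pile.append(revcomp(partner))
        elif rc_pos != -1 and rc_pos <= max_anchor_dist:
            left_pile.append(partner)

    up, sup_up, ties_up = _consensus_upstream(
        cseq, left_pile, flank_len, min_overlap, min_support
    )
    # the downstream side is the upstream side of the reverse complement
    down_rc, sup_down, ties_down = _consensus_upstream(
        revcomp(cseq), [revcomp(s) for s in right_pile], flank_len, min_overlap, min_support
    )
    return FlankSet(
        contig_id=contig.id,
        upstream=up,
        downstream=revcomp(down_rc) if down_rc is not None else None,
        support_upstream=sup_up,
        support_downstream=sup_down,
        ties_upstream=ties_up,
        ties_downstream=ties_down,
    )


def _consensus_upstream(
    contig: str,
    pile: list[str],
    flank_len: int,
    min_overlap: int,
    min_support: int,
) -> tuple[str | None, int, int]:
    """Place pile reads upstream of ``contig`` by exact overlap; majority vote.

    Offsets are relative to the contig start (negative = upstream). Reads are
    processed in sorted order and re-scanned until a fixpoint so that reads
    overlapping only the growing flank consensus still get placed.
    Deterministic: ties in the vote go to the lexicographically smallest base
    (counted); placement prefers the largest overlap.
    """
    placed: list[tuple[int, str]] = []
    remaining = sorted(pile)
    reference = contig
    ref_left = 0  # offset of reference[0] relative to the contig start
    for _ in range(max(1, 2 * flank_len // max(1, min_overlap))):
        if not remaining:
            break
        progressed = False
        still: list[str] = []
        for m in remaining:
            off = _place_upstream(m, reference, ref_left, min_overlap)
            if off is None:
                still.append(m)
            else:
                placed.append((off, m))
                progressed = True
        remaining = still
        if not progressed:
            break
        flank = _vote(placed, flank_len)[0]
        reference = flank + contig
        ref_left = -len(flank)

    flank, ties = _vote(placed, flank_len)
    support = len([1 for off, m in placed if off < 0])
    if not flank or support < min_support:
        return None, support, 0
    return flank, support, ties


def _end_overlap_sides(oriented: str, contig: str, end_overlap: int) -> list[str]:
    """Sides a non-contained read exactly overlaps the contig on.

    Left: a read suffix of >= end_overlap bases equals a contig prefix with
    the read sticking out upstream; right: symmetric. A read that contains
    the whole contig overlaps both ends. Seeded by the terminal
    ``end_overlap``-mer of the contig so the common no-overlap case is one
    C-level find.
    """
    sides: list[str] = []
    n, c = len(oriented), len(contig)
    if c <= n:
        p = oriented.find(contig)
        if p != -1:
            if p > 0:
                sides.append("left")
            if p + c < n:
                sides.append("right")
            return sides
    p = oriented.find(contig[:end_overlap])
    if p >= 1:
        ov = n - p
        if ov <= c and oriented[p:] == contig[:ov]:
            sides.append("left")
    p = oriented.rfind(contig[-end_overlap:])
    if p != -1:
        ov = p + end_overlap
        if ov < n and ov <= c and oriented[:ov] == contig[-ov:]:
            sides.append("right")
    return sides


def _place_upstream(
    m: str, reference: str, ref_left: int, min_overlap: int
) -> int | None:
    """Offset of read ``m`` (vs contig start) or None if unplaceable.

    Containment anywhere in the current reference wins; otherwise the longest
    exact suffix(read)/prefix(reference) overlap >= min_overlap.
    """
    idx = reference.find(m)
    if idx != -1:
        return ref_left + idx
    top = min(len(m) - 1, len(reference))
    for ov in range(top, min_overlap - 1, -1):
        if reference.startswith(m[len(m) - ov :]):
            return ref_left - (len(m) - ov)
    return None


def _vote(placed: list[tuple[int, str]], flank_len: int) -> tuple[str, int]:
    """Majority-vote consensus over columns -flank_len..-1, contiguous to -1."""
    votes: dict[int, dict[str, int]] = {}
    for off, m in placed:
        for j, base in enumerate(m):
            col = off + j
            if -flank_len <= col < 0:
                votes.setdefault(col, {}).setdefault(base, 0)
                votes[col][base] += 1
    out: list[str] = []
    ties = 0
    col = -1
    while col >= -flank_len and col in votes:
        counts = votes[col]
        best = max(counts.values())
        winners = sorted(b for b, n in counts.items() if n == best)
        if len(winners) > 1:
            ties += 1
        out.append(winners[0])
        col -= 1
    return "".join(reversed(out)), ties


def conserved_windows(flank: str, female_kmers: KmerIndex) -> list[tuple[int, int]]:
    """Maximal runs of flank positions covered by >=1 full female k-mer match.

    Coverage is per-base: position p is covered iff some window [i, i+k)
    containing p has its canonical k-mer in the index. Windows with non-ACGT
    characters never match. Returns sorted, disjoint, 0-based half-open
    intervals; an empty index (or a flank shorter than k) yields none.
    """
    k = female_kmers.k
    n = len(flank)
    covered = [False] * n
    for i in range(n - k + 1):
        window = flank[i : i + k]
        if not _ACGT.issuperset(window):
            continue
        if canonical(window) in female_kmers.members:
            for p in range(i, i + k):
                covered[p] = True
    runs: list[tuple[int, int]] = []
    start = None
    for p, c in enumerate(covered):
        if c and start is None:
            start = p
        elif not c and start is not None:
            runs.append((start, p))
            start = None
    if start is not None:
        runs.append((start, n))
    return runs
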