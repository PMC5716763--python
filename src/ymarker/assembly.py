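"""Minimal De Bruijn unitig assembly of the male-specific k-mer pool.

Unitigs only: maximal non-branching paths in a canonical (bidirected) De
Bruijn graph. Paths terminate at every branch — no bubble popping, no
tie-breaking among alternatives — so no chimeric ("coined") contig can be
emitted; ambiguity costs contiguity instead of correctness.

The graph edge length ``dbg_k`` defaults to the input k-mer length, which
assembles an exact k-mer set directly. When the input 60-mers are sparse
samples of the underlying locus (one fixed-locus k-mer per read), a smaller
``dbg_k`` is used so that k-mers from nearby read starts overlap — the same
reason the original short-fragment assemblers iterate from small k. See
docs/methods.md for the sampling-density analysis behind the pipeline
default.

Coverage pruning: an edge must be seen ``min_cov`` times to survive; with
multiplicity-preserving subtraction this suppresses sequencing-error k-mers,
the failure mode behind chimeric short-fragment assemblies.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ContractError
from .kmer import canonical, revcomp

_ACGT = frozenset("ACGT")


@dataclass
class Contig:
    """An assembled candidate sequence with provenance."""

    id: str
    sequence: str
    mean_coverage: float = 1.0
    stage: str = "assembled"  # assembled -> candidate -> validated
    unscreenable: bool = False  # set by the pool screen for too-short contigs

    def __post_init__(self):
        if not self.sequence or not _ACGT.issuperset(self.sequence):
            raise ContractError(f"contig {self.id!r}: empty or non-ACGT sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize_input(kmers) -> Counter:
    if isinstance(kmers, Mapping):
        return Counter(kmers)
    return Counter(kmers)


def build_edge_counts(kmers: Counter, dbg_k: int) -> Counter:
    """Canonical dbg_k-mer multiset of the input sequences (step-1 windows)."""
    edges: Counter = Counter()
    for seq, mult in kmers.items():
        for i in range(len(seq) - dbg_k + 1):
            w = seq[i : i + dbg_k]
            if _ACGT.issuperset(w):
                edges[canonical(w)] += mult
    return edges


def assemble(
    kmers,
    min_cov: int = 2,
    min_len: int | None = None,
    dbg_k: int | None = None,
    stats: dict | None = None,
) -> list[Contig]:
    """Assemble a k-mer multiset into unitigs.

    Parameters
    ----------
    kmers
        Iterable or Counter of same-length DNA strings (mixed lengths are a
        contract error). Multiplicities, when given, feed coverage pruning.
    min_cov
        Minimum edge multiplicity kept (use 1 for a plain set).
    min_len
        Minimum contig length emitted; defaults to twice the input k-mer
        length. Shorter unitigs are dropped and counted in ``stats``.
    dbg_k
        De Bruijn edge length; defaults to the input k-mer length.

    Output is sorted (length desc, sequence asc) and orientation-normalized
    (each contig is the lexicographic minimum of itself and its reverse
    complement), so the result is invariant under input order.
    """
    counts = _normalize_input(kmers)
    if stats is None:
        stats = {}
    if not counts:
        stats.update(n_edges=0, n_pruned=0, n_dropped_short=0)
        return []
    lengths = {len(s) for s in counts}
    if len(lengths) != 1:
        raise ContractError(f"mixed k-mer lengths in input: {sorted(lengths)}")
    k = lengths.pop()
    if dbg_k is None:
        dbg_k = k
    if not (2 <= dbg_k <= k):
        raise ContractError(f"dbg_k={dbg_k} outside [2, {k}]")
    if min_len is None:
        min_len = 2 * k

    edges = build_edge_counts(counts, dbg_k)
    pruned = [e for e, c in edges.items() if c < min_cov]
    for e in pruned:
        del edges[e]
    stats["n_edges"] = len(edges)
    stats["n_pruned"] = len(pruned)

    contigs = _unitigs(edges, dbg_k)
    kept = []
    dropped = 0
    for seq, cov in contigs:
        if len(seq) >= min_len:
            kept.append((seq, cov))
        else:
            dropped += 1
    stats["n_dropped_short"] = dropped

    kept.sort(key=lambda t: (-len(t[0]), t[0]))
    width = max(5, len(str(len(kept))))
    return [
        Contig(
            id=f"contig_{i + 1:0{width}d}",
            sequence=seq,
            mean_coverage=cov,
            stage="assembled",
        )
        for i, (seq, cov) in enumerate(kept)
    ]


def _unitigs(edges: Counter, k: int) -> list[tuple[str, float]]:
    """Maximal non-branching paths over a canonical edge multiset."""
    members = set(edges)

    def fwd(s: str) -> list[str]:
        core = s[1:]
        return [core + b for b in "ACGT" if canonical(core + b) in members]

    def bwd(s: str) -> list[str]:
        core = s[:-1]
        return [b + core for b in "ACGT" if canonical(b + core) in members]

    used: set[str] = set()
    out: list[tuple[str, float]] = []
    for seed in sorted(members):
        if seed in used:
            continue
        used.add(seed)
        path: list[str] = [seed]
        # forward extension: unique successor whose in-degree is 1
        cur = seed
        while True:
            nxt = fwd(cur)
            if len(nxt) != 1:
                break
            t = nxt[0]
            if canonical(t) in used or len(bwd(t)) != 1:
                break
            used.add(canonical(t))
            path.append(t)
            cur = t
        # backward extension, symmetric
        cur = seed
        while True:
            prv = bwd(cur)
            if len(prv) != 1:
                break
            t = prv[0]
            if canonical(t) in used or len(fwd(t)) != 1:
                break
            used.add(canonical(t))
            path.insert(0, t)
            cur = t
        seq = path[0] + "".join(p[-1] for p in path[1:])
        cov = sum(edges[canonical(p)] for p in path) / len(path)
        out.append((min(seq, revcomp(seq)), cov))
    return out


def length_histogram(
    contigs: Iterable[Contig], bin_edges: list[int]
) -> pd.DataFrame:
    """Contig-length distribution over half-open bins.

    ``bin_edges`` must be ascending; bins are [e0,e1), ..., [e_last, inf),
    with an extra [0, e0) bin when any contig falls below the first edge.
    Fractions sum to 1 over non-empty input.
    """
    if sorted(bin_edges) != list(bin_edges):
        raise ContractError("bin_edges must be ascending")
    lengths = [len(c) for c in contigs]
    if not lengths:
        return pd.DataFrame(columns=["bin", "count", "fraction"])
    edges = list(bin_edges)
    bounds = []
    if any(l < edges[0] for l in lengths):
        bounds.append((0, edges[0]))
    bounds += list(zip(edges, edges[1:])) + [(edges[-1], math.inf)]
    rows = []
    total = len(lengths)
    for lo, hi in bounds:
        n = sum(1 for l in lengths if lo <= l < hi)
        label = f"[{lo},{'inf' if hi is math.inf else hi})"
        rows.append({"bin": label, "count": n, "fraction": n / total})
    return pd.DataFrame(rows)
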