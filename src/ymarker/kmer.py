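"""Fixed-locus k-mer extraction, canonicalization, and k-mer set indexing.

The discovery pipeline never aligns reads; every membership question
("does this male 60-mer occur anywhere in the female genome / pool?") is
answered by exact canonical k-mer lookup, optionally widened to a 1-mismatch
neighborhood. Canonical form (lexicographic minimum of a k-mer and its
reverse complement) makes every comparison strand-independent, standing in
for the strandedness an aligner would otherwise provide.

Coordinates: the read window is expressed in the 1-based inclusive dialect
used at the bench (default 11..70, i.e. a 60-mer); internally everything is
0-based half-open.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from .errors import ConfigError, ContractError, DataError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ACGT = frozenset("ACGT")

INDEX_FORMAT_VERSION = 1


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of ``kmer`` and its reverse complement.

    Idempotent; raises ContractError on characters outside {A,C,G,T}.
    """
    if not _ACGT.issuperset(kmer):
        bad = sorted(set(kmer) - _ACGT)
        raise ContractError(f"non-ACGT character(s) {bad} in k-mer {kmer!r}")
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class KmerWindow:
    """Fixed read locus to cut a k-mer from (1-based inclusive ends)."""

    start: int = 11
    end: int = 70

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ConfigError(f"invalid k-mer window {self.start}..{self.end}")

    @property
    def k(self) -> int:
        return self.end - self.start + 1

    @property
    def slice(self) -> slice:
        """0-based half-open slice equivalent."""
        return slice(self.start - 1, self.end)


def extract_fixed_kmer(read, window: KmerWindow = KmerWindow()) -> str | None:
    """Cut the fixed-locus k-mer out of a read.

    Returns None (a skip signal, not an error) for reads shorter than the
    window or with N/other ambiguity codes inside the window. Each mate of a
    pair is treated as an independent locus by the callers.
    """
    seq = read.sequence if hasattr(read, "sequence") else read
    if len(seq) < window.end:
        return None
    kmer = seq[window.slice].upper()
    if not _ACGT.issuperset(kmer):
        return None
    return kmer


@dataclass
class KmerIndex:
    """Membership structure over canonical fixed-length k-mers.

    ``counts`` holds per-member multiplicities when the index was built from
    a multiset; it is optional and absent indexes behave as plain sets.
    """

    k: int
    members: set = field(default_factory=set)
    counts: Counter | None = None
    source_label: str = ""
    n_skipped: int = 0  # windows skipped for N/ambiguity during construction

    def __post_init__(self):
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, kmer: str) -> bool:
        return self.contains(kmer)

    def add(self, kmer: str, count: int = 1) -> None:
        if len(kmer) != self.k:
            raise ContractError(f"k-mer length {len(kmer)} != index k {self.k}")
        can = canonical(kmer)
        self.members.add(can)
        if self.counts is not None:
            self.counts[can] += count

    def contains(self, kmer: str, max_mismatches: int = 0) -> bool:
        """Exact canonical membership, optionally widened to 1 mismatch.

        ``max_mismatches`` in {0, 1}: with 1, every single-base substitution
        variant of the query is also looked up (the bounded stand-in for an
        aligner's mismatch tolerance).
        """
        if len(kmer) != self.k:
            raise ContractError(f"query length {len(kmer)} != index k {self.k}")
        if max_mismatches not in (0, 1):
            raise ConfigError("max_mismatches must be 0 or 1")
        if canonical(kmer) in self.members:
            return True
        if max_mismatches == 0:
            return False
        for i, base in enumerate(kmer):
            for alt in "ACGT":
                if alt != base:
                    var = kmer[:i] + alt + kmer[i + 1 :]
                    if canonical(var) in self.members:
                        return True
        return False

    def update_from_sequences(self, sequences: Iterable[str]) -> None:
        """Add every overlapping k-mer (step 1) of each sequence."""
        k = self.k
        members = self.members
        counts = self.counts
        acgt = _ACGT
        for seq in sequences:
            seq = str(seq).upper()
            clean = acgt.issuperset(seq)
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if not clean and not acgt.issuperset(kmer):
                    self.n_skipped += 1
                    continue
                rc = kmer.translate(_COMPLEMENT)[::-1]
                can = kmer if kmer <= rc else rc
                members.add(can)
                if counts is not None:
                    counts[can] += 1

    # -- persistence: versioned plain-text dump -------------------------------

    def save(self, path) -> None:
        """Write a sorted plain-text dump (gzip by ``.gz`` suffix)."""
        with _open_text(path, "wt") as fh:
            fh.write(
                f"#ymarker-kmerindex\tv{INDEX_FORMAT_VERSION}\tk={self.k}"
                f"\tsource={self.source_label}\tcounts={int(self.counts is not None)}\n"
            )
            if self.counts is not None:
                for kmer in sorted(self.members):
                    fh.write(f"{kmer}\t{self.counts[kmer]}\n")
            else:
                for kmer in sorted(self.members):
                    fh.write(kmer + "\n")

    @classmethod
    def load(cls, path) -> "KmerIndex":
        with _open_text(path, "rt") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if not header or header[0] != "#ymarker-kmerindex":
                raise DataError(f"{path}: not a ymarker k-mer index")
            meta = dict(f.split("=", 1) for f in header[2:])
            k = int(meta["k"])
            with_counts = meta.get("counts", "0") == "1"
            idx = cls(
                k=k,
                counts=Counter() if with_counts else None,
                source_label=meta.get("source", ""),
            )
            for line in fh:
                if with_counts:
                    kmer, n = line.split("\t")
                    idx.members.add(kmer)
                    idx.counts[kmer] = int(n)
                else:
                    idx.members.add(line.rstrip("\n"))
        return idx


def build_index(
    sequences: Iterable[str],
    k: int,
    source_label: str = "",
    with_counts: bool = False,
) -> KmerIndex:
    """Index all overlapping canonical k-mers of a stream of sequences.

    Sequences shorter than k contribute nothing; windows containing non-ACGT
    characters are skipped and counted in ``n_skipped``.
    """
    idx = KmerIndex(
        k=k,
        counts=Counter() if with_counts else None,
        source_label=source_label,
    )
    idx.update_from_sequences(sequences)
    return idx


def _open_text(path, mode: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)
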