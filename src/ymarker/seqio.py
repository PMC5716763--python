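"""FASTA/FASTQ I/O, mate pairing, and the per-read quality filter.

Files are read and written through Biopython's SeqIO; gzip is handled
transparently by the ``.gz`` suffix. Quality scores are Sanger Phred+33
integers throughout.

The quality filter follows the pipeline's read-cleaning rule: a pair is kept
only if the mean Phred score of EACH mate is at least ``min_mean_q``
(default 30); pairs are discarded whole. The statistic (per-read mean,
boundary kept) is a documented choice — see docs/methods.md.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ContractError, FastqParseError, PairingError

_MATE_SUFFIXES = ("/1", "/2")


@dataclass
class Read:
    """A sequencing read; ``qualities`` is None for FASTA records."""

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ContractError(f"read {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ContractError(
                f"read {self.id!r}: {len(self.qualities)} quality values for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        if self.qualities is None:
            raise ContractError(f"read {self.id!r} has no quality scores")
        return sum(self.qualities) / len(self.qualities)


def strip_mate_suffix(read_id: str) -> str:
    """Drop a trailing ``/1``/``/2`` or a space-delimited tag (Casava style)."""
    head = read_id.split()[0].split("\t")[0]
    for suffix in _MATE_SUFFIXES:
        if head.endswith(suffix):
            return head[: -len(suffix)]
    return head


@dataclass
class ReadPair:
    """A mated pair in FR orientation; mate ids must match after suffix strip."""

    r1: Read
    r2: Read
    orientation: str = "FR"

    def __post_init__(self):
        if strip_mate_suffix(self.r1.id) != strip_mate_suffix(self.r2.id):
            raise PairingError(
                f"mate ids do not match: {self.r1.id!r} vs {self.r2.id!r}"
            )

    @property
    def name(self) -> str:
        return strip_mate_suffix(self.r1.id)


# -- parsing -----------------------------------------------------------------


def _open_auto(path, mode: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _iter_records(path, fmt: str) -> Iterator[SeqRecord]:
    record_index = 0
    lines_per_record = 4 if fmt == "fastq" else None
    try:
        with _open_auto(path, "rt") as handle:
            for record in SeqIO.parse(handle, fmt):
                yield record
                record_index += 1
    except ValueError as exc:
        line = (
            record_index * lines_per_record + 1 if lines_per_record else None
        )
        raise FastqParseError(f"{path}: {exc}", line=line) from exc


def read_fastq(path) -> Iterator[Read]:
    for rec in _iter_records(path, "fastq"):
        yield Read(
            id=rec.description or rec.id,
            sequence=str(rec.seq).upper(),
            qualities=list(rec.letter_annotations["phred_quality"]),
        )


def read_fasta(path) -> Iterator[Read]:
    for rec in _iter_records(path, "fasta"):
        yield Read(id=rec.description or rec.id, sequence=str(rec.seq).upper())


def read_fastq_pairs(path_r1, path_r2) -> Iterator[ReadPair]:
    """Stream mate pairs from two FASTQ files in file order.

    A record-count mismatch or non-corresponding ids raise PairingError.
    """
    sentinel = object()
    for i, (r1, r2) in enumerate(
        itertools.zip_longest(read_fastq(path_r1), read_fastq(path_r2), fillvalue=sentinel)
    ):
        if r1 is sentinel or r2 is sentinel:
            short = path_r2 if r2 is sentinel else path_r1
            raise PairingError(
                f"mate files have different record counts ({short} ended at record {i})"
            )
        yield ReadPair(r1=r1, r2=r2)


# -- writing -----------------------------------------------------------------


def _to_record(read: Read) -> SeqRecord:
    rec = SeqRecord(Seq(read.sequence), id=read.id.split()[0], description=read.id)
    # SeqIO would duplicate the id if description repeats it
    rec.description = read.id if read.id != rec.id else ""
    if read.qualities is not None:
        rec.letter_annotations["phred_quality"] = list(read.qualities)
    return rec


def write_fastq(reads: Iterable[Read], path) -> int:
    with _open_auto(path, "wt") as handle:
        return SeqIO.write((_to_record(r) for r in reads), handle, "fastq")


def write_fasta(reads: Iterable[Read], path) -> int:
    with _open_auto(path, "wt") as handle:
        return SeqIO.write((_to_record(r) for r in reads), handle, "fasta")


def write_fastq_pairs(pairs: Iterable[ReadPair], path_r1, path_r2) -> int:
    pairs = list(pairs)
    write_fastq((p.r1 for p in pairs), path_r1)
    write_fastq((p.r2 for p in pairs), path_r2)
    return len(pairs)


# -- filtering ---------------------------------------------------------------


def quality_filter(pair: ReadPair, min_mean_q: int = 30) -> bool:
    """True iff the mean Phred of each mate is >= ``min_mean_q``.

    Monotone in the threshold: raising it can only discard more pairs.
    """
    if pair.r1.qualities is None or pair.r2.qualities is None:
        raise ContractError("quality_filter requires qualities on both mates")
    return pair.r1.mean_quality >= min_mean_q and pair.r2.mean_quality >= min_mean_q


def clip_adapter(read: Read, adapter: str) -> Read:
    """Exact 3' adapter clipping (simplified; the simulator is adapter-free).

    Removes everything from the first full occurrence of ``adapter`` onward,
    or a terminal exact prefix of the adapter at the 3' end.
    """
    if not adapter:
        return read
    seq = read.sequence
    cut = seq.find(adapter)
    if cut == -1:
        # longest adapter prefix that is a suffix of the read
        for n in range(min(len(adapter) - 1, len(seq) - 1), 0, -1):
            if seq.endswith(adapter[:n]):
                cut = len(seq) - n
                break
    if cut <= 0:
        # -1: no adapter; 0: read is pure adapter — left whole so the Read
        # non-empty invariant holds (such reads fail downstream extraction).
        return read
    quals = read.qualities[:cut] if read.qualities is not None else None
    return Read(id=read.id, sequence=seq[:cut], qualities=quals)


def filter_pairs(
    pairs: Iterable[ReadPair], min_mean_q: int = 30
) -> tuple[list[ReadPair], int]:
    """Apply quality_filter to a stream; returns (kept, n_discarded)."""
    kept: list[ReadPair] = []
    discarded = 0
    for pair in pairs:
        if quality_filter(pair, min_mean_q):
            kept.append(pair)
        else:
            discarded += 1
    return kept, discarded
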