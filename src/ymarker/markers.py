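"""In-silico PCR, XX/XY/YY genotype calls, allele alignment, primer picking.

The genotyping logic is the computational core of sex-marker validation: a
primer pair sitting in X/Y-conserved flanks amplifies an X-allele product in
every individual and a longer Y-allele product (the Y carries insertions)
only when a Y is present, so band patterns {X}, {X,Y}, {Y} read out XX, XY
and YY respectively.

``align_alleles`` is a global (end-to-end) Needleman-Wunsch alignment with
affine gap scores, implemented here rather than borrowed because the
summary needs gap-run events and a fixed deterministic traceback order
(match/mismatch > gap-in-A > gap-in-B on ties). A gap run of length L
scores gap_open + (L-1)*gap_extend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractError
from .flanks import ConservedWindows
from .kmer import revcomp

_ACGT = frozenset("ACGT")
_NEG = -1e18  # effective -infinity that stays NaN-free under addition


def gc_content(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature, 2*(A+T) + 4*(G+C). Reporting only."""
    at = seq.count("A") + seq.count("T")
    return 2.0 * at + 4.0 * (len(seq) - at)


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str

    def __post_init__(self):
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq or not _ACGT.issuperset(seq):
                raise ContractError(f"{label} primer of {self.name!r} is empty or non-ACGT")


@dataclass(frozen=True)
class Amplicon:
    start: int  # 0-based start of the forward footprint on the searched strand
    length: int
    sequence: str
    strand: str = "+"


@dataclass
class AmpliconSet:
    primers: PrimerPair
    template_name: str = ""
    products: list[Amplicon] = field(default_factory=list)

    @property
    def lengths(self) -> list[int]:
        return [p.length for p in self.products]

    def __len__(self) -> int:
        return len(self.products)


def _find_all(template: str, site: str, max_mismatches: int, protect_3prime: int) -> list[int]:
    """All match positions; mismatches (if allowed) spare the 3'-terminal bases."""
    if max_mismatches == 0:
        hits, start = [], template.find(site)
        while start != -1:
            hits.append(start)
            start = template.find(site, start + 1)
        return hits
    hits = []
    n, m = len(template), len(site)
    core, tail = site[: m - protect_3prime], site[m - protect_3prime :]
    for i in range(n - m + 1):
        if template[i + m - protect_3prime : i + m] != tail:
            continue
        mm = sum(1 for a, b in zip(template[i : i + m - protect_3prime], core) if a != b)
        if mm <= max_mismatches:
            hits.append(i)
    return hits


def insilico_pcr(
    primers: PrimerPair,
    template: str,
    max_product: int = 3000,
    max_mismatches: int = 0,
    search_both_strands: bool = False,
    template_name: str = "",
) -> AmpliconSet:
    """Predict PCR products on a template.

    A product is any span where the forward primer matches the plus strand
    and the reverse primer's reverse complement matches downstream, with
    non-overlapping footprints and span <= ``max_product``. All qualifying
    (F, R) site combinations are reported; product length includes both
    primer footprints. Optional mismatches never touch the 3'-terminal
    3 bases of either primer (where polymerase extension is intolerant).

    With ``search_both_strands`` the reverse complement of the template is
    searched too (an assembled template's orientation is arbitrary);
    products found there are reported with strand "-".
    """
    result = AmpliconSet(primers=primers, template_name=template_name)
    strands = [("+", template)] + ([("-", revcomp(template))] if search_both_strands else [])
    rc_reverse = revcomp(primers.reverse)
    for strand, seq in strands:
        fwd_sites = _find_all(seq, primers.forward, max_mismatches, 3)
        rev_sites = _find_all(seq, rc_reverse, max_mismatches, 3)
        for f in fwd_sites:
            for r in rev_sites:
                if r < f + len(primers.forward):
                    continue
                length = r + len(rc_reverse) - f
                if length > max_product:
                    continue
                result.products.append(
                    Amplicon(start=f, length=length, sequence=seq[f : f + length], strand=strand)
                )
    return result


# -- genotype calls ----------------------------------------------------------


@dataclass
class GenotypeCall:
    call: str  # XX | XY | YY | NO_CALL
    evidence: dict[str, tuple[int, ...]]  # band lengths per allele class

    @property
    def bands(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.evidence.get("X", ())) | set(self.evidence.get("Y", ()))))


def call_genotype(
    x_products: Sequence[int], y_products: Sequence[int]
) -> GenotypeCall:
    """Genotype from which allele classes produced products.

    X only -> XX; both -> XY; Y only -> YY; neither -> NO_CALL. The call is
    a pure function of product presence (order and multiplicity are
    irrelevant).
    """
    evidence = {
        "X": tuple(sorted(set(x_products))),
        "Y": tuple(sorted(set(y_products))),
    }
    if evidence["X"] and evidence["Y"]:
        call = "XY"
    elif evidence["X"]:
        call = "XX"
    elif evidence["Y"]:
        call = "YY"
    else:
        call = "NO_CALL"
    return GenotypeCall(call=call, evidence=evidence)


# -- allele alignment --------------------------------------------------------


@dataclass
class AlignmentSummary:
    """Global alignment of an X/Y allele pair, summarized by column classes."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        a, b = self.aligned_a, self.aligned_b
        assert len(a) == len(b)
        self.aligned_length = len(a)
        self.matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
        self.gap_events_in_a = _gap_runs(a)
        self.gap_events_in_b = _gap_runs(b)
        gapped = sum(self.gap_events_in_a) + sum(self.gap_events_in_b)
        self.mismatches = self.aligned_length - self.matches - gapped
        self.total_indel_bp = gapped

    @property
    def identity_pct(self) -> float:
        """Percent identity with gaps counting against (matches / columns)."""
        return 100.0 * self.matches / self.aligned_length

    def identity(self, denominator: str = "columns") -> float:
        """Alternative identity definitions; "shorter" divides by min(len a, len b)."""
        if denominator == "columns":
            return self.identity_pct
        if denominator == "shorter":
            shorter = min(
                self.aligned_length - sum(self.gap_events_in_a),
                self.aligned_length - sum(self.gap_events_in_b),
            )
            return 100.0 * self.matches / shorter
        raise ContractError(f"unknown identity denominator {denominator!r}")

    def to_text(self, width: int = 60) -> str:
        """Human-readable gapped alignment block."""
        lines = []
        for i in range(0, self.aligned_length, width):
            a = self.aligned_a[i : i + width]
            b = self.aligned_b[i : i + width]
            mid = "".join("|" if x == y and x != "-" else " " for x, y in zip(a, b))
            lines += [f"A {a}", f"  {mid}", f"B {b}", ""]
        lines.append(
            f"length={self.aligned_length} matches={self.matches} "
            f"mismatches={self.mismatches} indel_bp={self.total_indel_bp} "
            f"identity={self.identity_pct:.1f}% score={self.score:g}"
        )
        return "\n".join(lines)


def _gap_runs(aligned: str) -> list[int]:
    runs, n = [], 0
    for ch in aligned:
        if ch == "-":
            n += 1
        elif n:
            runs.append(n)
            n = 0
    if n:
        runs.append(n)
    return runs


def align_alleles(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> AlignmentSummary:
    """Optimal global alignment of two alleles under affine gap scores.

    Dynamic programming over three states (match/mismatch, gap in A, gap in
    B); the within-row gap-in-A recurrence is solved with a running-maximum
    transform so rows vectorize. Traceback ties prefer match/mismatch, then
    gap-in-A, then gap-in-B, making the reported alignment deterministic.
    """
    if not a or not b:
        raise ContractError("align_alleles requires two non-empty sequences")
    n, m = len(a), len(b)
    A = np.frombuffer(a.encode(), dtype=np.uint8)
    B = np.frombuffer(b.encode(), dtype=np.uint8)

    M = np.full((n + 1, m + 1), _NEG)
    Ga = np.full((n + 1, m + 1), _NEG)  # gap in A: column consumes b only
    Gb = np.full((n + 1, m + 1), _NEG)  # gap in B: column consumes a only
    M[0, 0] = 0.0
    js = np.arange(1, m + 1)
    Ga[0, 1:] = gap_open + (js - 1) * gap_extend
    Gb[1:, 0] = gap_open + (np.arange(1, n + 1) - 1) * gap_extend

    ext_j = gap_extend * np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(B == A[i - 1], match, mismatch)  # length m
        best_prev = np.maximum(np.maximum(M[i - 1, :m], Ga[i - 1, :m]), Gb[i - 1, :m])
        M[i, 1:] = best_prev + sub
        Gb[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] + gap_open, Ga[i - 1, 1:] + gap_open),
            Gb[i - 1, 1:] + gap_extend,
        )
        # Ga[i, j] = max_{j'<j} (max(M,Gb)[i, j'] + gap_open + (j-1-j') * gap_extend)
        U = np.maximum(M[i], Gb[i]) + gap_open - ext_j
        run = np.maximum.accumulate(U[:m])
        Ga[i, 1:] = run + ext_j[1:] - gap_extend

    ali_a, ali_b, score = _traceback(a, b, M, Ga, Gb, match, mismatch, gap_open, gap_extend)
    return AlignmentSummary(aligned_a=ali_a, aligned_b=ali_b, score=score)


def _traceback(a, b, M, Ga, Gb, match, mismatch, gap_open, gap_extend):
    n, m = len(a), len(b)
    tol = 1e-6

    def pick(options):
        # options: list of (state, value); first feasible equal to the max wins,
        # ordered match/mismatch > gap-in-A > gap-in-B
        best = max(v for _, v in options)
        for state, v in options:
            if v >= best - tol:
                return state
        raise AssertionError

    i, j = n, m
    state = pick([("M", M[n, m]), ("Ga", Ga[n, m]), ("Gb", Gb[n, m])])
    score = {"M": M[n, m], "Ga": Ga[n, m], "Gb": Gb[n, m]}[state]
    out_a, out_b = [], []
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = match if a[i - 1] == b[j - 1] else mismatch
            target = M[i, j] - s
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = pick([("M", M[i, j]), ("Ga", Ga[i, j]), ("Gb", Gb[i, j])])
            assert abs({"M": M[i, j], "Ga": Ga[i, j], "Gb": Gb[i, j]}[state] - target) < tol
        elif state == "Ga":
            out_a.append("-")
            out_b.append(b[j - 1])
            target = Ga[i, j]
            j -= 1
            state = pick(
                [
                    ("M", M[i, j] + gap_open),
                    ("Ga", Ga[i, j] + gap_extend),
                    ("Gb", Gb[i, j] + gap_open),
                ]
            )
            check = {
                "M": M[i, j] + gap_open,
                "Ga": Ga[i, j] + gap_extend,
                "Gb": Gb[i, j] + gap_open,
            }[state]
            assert abs(check - target) < tol
        else:  # Gb
            out_a.append(a[i - 1])
            out_b.append("-")
            target = Gb[i, j]
            i -= 1
            state = pick(
                [
                    ("M", M[i, j] + gap_open),
                    ("Ga", Ga[i, j] + gap_open),
                    ("Gb", Gb[i, j] + gap_extend),
                ]
            )
            check = {
                "M": M[i, j] + gap_open,
                "Ga": Ga[i, j] + gap_open,
                "Gb": Gb[i, j] + gap_extend,
            }[state]
            assert abs(check - target) < tol
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


# -- primer picking ----------------------------------------------------------


def pick_primer_regions(
    windows: ConservedWindows,
    flank_up: str,
    flank_down: str,
    len_range: tuple[int, int] = (18, 25),
    gc_range: tuple[float, float] = (0.40, 0.60),
    max_pairs: int = 10,
) -> list[PrimerPair]:
    """Candidate primer pairs from conserved windows on the two flanks.

    Forward primers are substrings of upstream conserved windows; reverse
    primers are reverse complements of downstream-window substrings. Each
    must satisfy the length and GC bounds and occur exactly once in its
    flank (neither strand elsewhere). Candidates are ranked by source
    window length (desc), then GC proximity to 0.5, then sequence; pairs
    are emitted in combined-rank order.
    """
    fwd = _window_candidates(windows.upstream, flank_up, len_range, gc_range)
    rev = _window_candidates(windows.downstream, flank_down, len_range, gc_range)
    if not fwd or not rev:
        return []
    pairs = []
    for fi, f in enumerate(fwd[:max_pairs]):
        for ri, r in enumerate(rev[:max_pairs]):
            pairs.append((fi + ri, fi, f, revcomp(r)))
    pairs.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    return [
        PrimerPair(name=f"pair{i + 1}", forward=f, reverse=r)
        for i, (_, _, f, r) in enumerate(pairs[:max_pairs])
    ]


def _window_candidates(
    intervals: Iterable[tuple[int, int]],
    flank: str,
    len_range: tuple[int, int],
    gc_range: tuple[float, float],
) -> list[str]:
    lo, hi = len_range
    out = []
    seen = set()
    for start, end in intervals:
        wlen = end - start
        for L in range(lo, hi + 1):
            for i in range(start, end - L + 1):
                sub = flank[i : i + L]
                if sub in seen:
                    continue
                seen.add(sub)
                gc = gc_content(sub)
                if not (gc_range[0] <= gc <= gc_range[1]):
                    continue
                if flank.count(sub) != 1 or revcomp(sub) in flank:
                    continue
                out.append((-wlen, abs(gc - 0.5), sub))
    out.sort()
    return [sub for _, _, sub in out]
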