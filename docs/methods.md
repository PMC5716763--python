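# Methods

`ymarker` implements desk-scale, fully testable versions of the three
computational steps behind NGS-based sex-marker discovery in an XX/XY
species — subtractive hybridization, enrichment against a pooled-female
library, and counter-parting (homologous cloning of the X allele) — plus
the simulator that generates the study conditions. This note records the
models, the parameters that matter, and the design choices made where the
procedure was genuinely open.

## Matching model

All sequence membership questions are answered by exact canonical k-mer
lookup: a k-mer matches a sequence set iff the lexicographic minimum of the
k-mer and its reverse complement is in the set's canonical k-mer index.
This replaces heuristic read alignment with a reproducible, testable
primitive; strandedness is handled by canonicalization on both sides. An
optional 1-mismatch mode widens a query to its 3k single-substitution
neighbors; it is off by default everywhere, so the pipeline's published
behavior is exact matching. The cost is that a single substitution or
sequencing error makes a k-mer "male-specific"; the coverage-pruning and
pool-screening stages exist to absorb exactly that.

## Quality filter

The read cleaner drops a pair when either mate's mean Phred score is below
`min_mean_q` (default 30, boundary kept). A mean-per-read statistic is the
simplest monotone reading of a "quality under 30" rejection rule; per-base
trimming would change read lengths and hence the fixed k-mer locus, so it
is deliberately not done. Adapter handling is reduced to optional exact
3'-prefix clipping because the simulator emits adapter-free reads and
adapter chemistry is not what this package studies.

## Subtraction

Each mate contributes one fixed-locus 60-mer (1-based read positions
11–70; reads shorter than 70 bp or with an ambiguity code in the window are
skipped and counted). K-mers found in the female reference index are
discarded; the rest are retained *with multiplicity* — the multiset is what
makes coverage pruning possible downstream. Both raw and distinct unaligned
counts are reported since de-duplication before assembly is a free choice.

## Assembly

`assemble()` builds a canonical (bidirected) De Bruijn graph whose edges
are the `dbg_k`-mers of the input sequences, prunes edges with multiplicity
below `min_cov` (default 2), and emits unitigs — maximal non-branching
paths. Paths stop at every branch; there is no bubble popping and no
tie-breaking, so a chimeric contig cannot be produced at the price of extra
fragmentation. Output is orientation-normalized and sorted, hence invariant
under input order.

`dbg_k` defaults to the input k-mer length, which reconstructs an exact
k-mer set directly (a repeat-free sequence is recovered in one contig from
its 60-mers). The pipeline instead uses `dbg_k = 17`. The reason is
sampling density: one fixed-locus 60-mer per read at 20-fold coverage gives
a mean per-position 60-mer multiplicity of 20/150 ≈ 0.13, so adjacent
60-mers almost never overlap by 59 bases and a direct 60-mer graph cannot
assemble at all — the same reason iterative short-fragment assemblers start
from small k. A 17-mer inside a 60-mer is covered by any of the 44
surrounding window placements (expected edge coverage ≈ 44·20/150 ≈ 5.9),
which makes `min_cov = 2` satisfiable, while 17 bp is still long enough
that chance repeats among the few tens of kilobases of male-specific
sequence are negligible. A Monte Carlo of the read-start point process
showed that no choice of `dbg_k` makes a single unitig span a ~260 bp locus
reliably at this density (best ≈ 0.6), so contiguity of the marker locus is
*not* assumed anywhere downstream (see marker discovery). `min_cov = 2` is
kept because error-derived edges occur once and, if retained, branch the
graph and shatter true unitigs. The contig length floor is 120 bp (twice
the 60-mer length), below the shortest marker-scale fragments of interest.

## Pool screen

A contig is excluded iff any of its canonical 60-mers occurs in the index
of pooled-female reads (every overlapping 60-mer of every read). This is a
symmetric re-statement of "contig aligns to any pool read → exclude" that
is well defined when the query is longer than the reads. The first matching
(offset, k-mer) pair is recorded per exclusion for audit. Contigs shorter
than the screen k-mer cannot be screened; they are retained but flagged.
The screen is monotone: adding pool reads can only move contigs from
retained to excluded.

## Flank recovery and conserved windows

Flanks are rebuilt from two evidence classes, both exact:

* **Mate anchoring.** A pair is anchored when exactly one mate matches the
  contig (either orientation) within `max_anchor_dist` (default 500, the
  maximum insert) of an end, and the other mate does not match at all. In
  FR geometry, a reverse-complement anchor near the left end implies the
  partner (as sequenced) lies upstream; a forward anchor near the right end
  implies the partner's reverse complement lies downstream.
* **End-overlapping reads.** A read whose exact terminal overlap with a
  contig end is ≥ 30 bp while extending beyond it joins the same pile.
  These reads bridge the junction: with 300–500 bp inserts, an anchored
  partner often lands entirely upstream of the contig with no overlap to
  position it, so without bridge reads the consensus cannot bootstrap.

Because the per-fragment insert length is unknowable (uniform 300–500),
reads are placed by maximal exact suffix/prefix overlap (≥ 15 bp) against
the growing contig+flank consensus, iterated to a fixpoint; reads that
never overlap anything placed are dropped and do not vote. The flank is the
per-column majority vote over the contiguous covered run adjacent to the
contig, capped at one read length (150 bp); vote ties resolve to the
lexicographically smallest base and are counted. A pile with fewer than
`min_support` (default 2) placed reads yields no flank.

Conserved windows then mark every flank position covered by at least one
full-length female 60-mer match — stretches present on both X and Y, the
only places a primer can bind in both sexes.

## Primer design and genotyping

Primer candidates are substrings of conserved windows (length 18–25, GC
0.40–0.60, unique in their flank on either strand), ranked by window length
then GC proximity to 0.5; reverse primers are reverse complements of
downstream-window substrings. Melting temperature is reported by the
Wallace rule only; thermodynamic design is out of scope.

In-silico PCR reports every span where the forward primer matches the plus
strand exactly and the reverse primer's reverse complement matches
downstream, footprints disjoint, span ≤ 3 kb. The pipeline also searches
the template's reverse complement because assembled sequence has arbitrary
orientation. The optional mismatch mode never tolerates mismatches in the
3'-terminal 3 bases, where extension fails in practice.

Marker discovery treats every recovered flank with conserved windows as an
*amplicon arm* (in both orientations) and screens primer pairs from arm
pairs — same candidate first, then across candidates — with the in-silico
analogue of the wet screen: a valid marker amplifies exactly one band in an
XX female and, in the XY male, that same band plus exactly one Y band of a
different length. Pairing arms across candidates is what makes discovery
robust to the assembler fragmenting the divergent locus; it is the
computational version of testing primer combinations on a gel. Genotypes
are then called purely from which allele classes produced products: X only
→ XX, both → XY, Y only → YY, neither → NO_CALL.

## Allele alignment

`align_alleles` is an affine-gap global Needleman–Wunsch implemented with a
running-maximum transform so each DP row vectorizes. Scores default to
match +1, mismatch −1, gap open −2, gap extend −1; a gap run of length L
costs `gap_open + (L−1)·gap_extend` (the open covers the first gapped
base). Traceback ties prefer match/mismatch, then gap-in-A, then gap-in-B,
making the reported alignment — and hence the gap-event lists —
deterministic. Percent identity is matches over alignment columns (gaps
count against identity); a matches-over-shorter-sequence variant is
available because the field uses both denominators. Scores are cross-checked
in tests against exhaustive enumeration (short pairs) and Biopython's
affine-gap aligner (long pairs).

## The simulator

The generator emulates the study design, not sequencing physics:

* **Genome.** One 200 kb autosome and a 100 kb X, i.i.d. uniform bases. The
  Y is the X with a 2 kb divergent envelope rewritten, placed at least one
  maximum insert from the chromosome ends. The envelope layout is
  `[diverged block A | 200 bp conserved gap | marker core | 200 bp conserved
  gap | diverged block C]`: real validated markers are short Y-specific
  fragments *flanked by* X/Y-conserved sequence (that is where their primers
  sit), which a uniformly diverged envelope would not provide.
* **Divergence.** Substitutions at `y_snp_rate = 0.15` across A, the core
  and C — high enough that a 60 bp SNP-free window (a hole in
  Y-specificity) is vanishingly rare (0.85⁶⁰ ≈ 6·10⁻⁵), and consistent with
  the low-80s% X/Y homology typical of such loci — plus insertions of 16,
  7, 68 and 21 bp planted at evenly spread core positions. The marker X
  allele (core + one conserved arm per side) is 458 bp, the Y allele
  570 bp, and the truth primer pair is the X allele's terminal 20-mers.
* **Population variation.** Biallelic SNP sites at `pop_snp_rate = 2·10⁻⁴`
  with allele frequencies ~ U(0.2, 0.8), drawn once and sampled per
  haplotype. The rate describes a low-diversity aquaculture population: a
  desk pool of 8 females (16 haplotypes) can only represent common
  variation, the role the full-scale 48-female pool plays for a wild
  population. The envelope ± 200 bp carries no sites, emulating the
  conditioning implicit in a validated marker (its primer sites amplified
  in every tested individual). The reference female is the homozygous
  reference; the male and pool females draw genotypes at the shared sites.
* **Reads.** 150 bp FR pairs from fragments uniform in 300–500 bp, r1 the
  plus-strand 5' end; substitution errors only at `error_rate = 0.001`,
  qualities constant Q37 with error positions downgraded to Q11. Expected
  pairs = total haplotype length × coverage / (2 × read length); individual
  libraries default to 20× per haplotype, pool females to 5×. Everything is
  deterministic given the seed (independent libraries use separate seed
  streams).
* **Truth.** Y-specific intervals are *computed*, not assumed: maximal runs
  of Y 60-mers absent from the union of every simulated female haplotype's
  60-mers (the reference k-mers plus, exactly, the windows around each
  carried variant). Runs under 120 bp are below marker scale and excluded.
  Generation self-checks (core inside an interval, truth primers giving the
  single expected product per allele) and redraws up to 10 times before
  raising.

A candidate is scored as a true positive when ≥ 50 % of its length
exact-matches (either orientation) inside one truth interval; recall is the
fraction of intervals hit, precision the fraction of candidates that are
true positives.

### What the simulator does not model

No indel sequencing errors (the exact-matching stages would need tolerant
anchoring; this matches the method's real dependence on exact alignment),
no quality-profile realism, no GC bias or PCR duplicates, no structural
variation beyond the configured divergence, and no recombination or
pedigree structure — pool females are i.i.d. draws at shared sites. Passing
tests therefore show the *logic* of the pipeline is right under its own
assumptions, not that it is robust to real instrument artifacts or to
populations with substantial rare variation (with few pool females, a
male's private rare variant can evade the pool screen, exactly as wild-data
candidates require PCR validation).

## Problem sizes and determinism

The default study (300 kb female genome, 20× individuals, 8-female pool at
5×) runs end-to-end in well under a minute on one core; the test suite
performs one such run plus a smaller one (70 kb, 4 females) for
orchestration and CLI checks. All randomness flows from the single
configured seed; re-running any stage with the same configuration
reproduces byte-identical artifacts, and the run manifest records
count-conservation at every stage boundary.
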