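"""Counter-parting: recover a contig's flanks and design X/Y primers.

Takes a known Y-specific contig, recovers its up/downstream flanks from the
mate pairs of reads anchored at its ends, marks the flank stretches covered
by female 60-mers (conserved on X and Y), and drafts primer pairs inside
those windows.
"""

from ymarker import (
    ConservedWindows, SimConfig, build_index, conserved_windows,
    pick_primer_regions, recover_flanks, simulate_genomes, simulate_reads,
)
from ymarker.assembly import Contig
from ymarker.seqio import filter_pairs

cfg = SimConfig(seed=1, autosome_len=40_000, x_len=30_000,
                y_divergent_region=(14_000, 2_000), n_pool_females=4)
truth = simulate_genomes(cfg)

# use the true marker core as the validated contig
s, e = truth.marker.y_core
contig = Contig(id="marker_core", sequence=truth.y_seq[s:e], stage="validated")
male_pairs, _ = filter_pairs(simulate_reads(truth.individuals["M1"].haplotypes, cfg, stream=1))

fl = recover_flanks(contig, male_pairs)
print(f"upstream flank: {len(fl.upstream)} bp from {fl.support_upstream} mates")
print(f"downstream flank: {len(fl.downstream)} bp from {fl.support_downstream} mates")

female_index = build_index(truth.female_reference, k=60)
cw = ConservedWindows(
    upstream=conserved_windows(fl.upstream, female_index),
    downstream=conserved_windows(fl.downstream, female_index),
)
print(f"conserved windows (0-based on each flank): up={cw.upstream} down={cw.downstream}")

pairs = pick_primer_regions(cw, fl.upstream, fl.downstream)
best = pairs[0]
print(f"top primer pair: F={best.forward}  R={best.reverse}")
print("Both primers sit in sequence shared by X and Y, so they amplify the")
print("X allele in every fish and the longer Y allele only when a Y is present.")
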