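"""Simulate an XY genome pair with a divergent marker locus.

Builds the default desk-scale truth set: an autosome, an X, and a Y whose
2 kb divergent envelope carries a marker core with 16+7+68+21 bp insertions.
Prints the allele pair the locus defines and the Y-specific intervals a
perfect discovery pipeline should find.
"""

from ymarker import SimConfig, simulate_genomes

truth = simulate_genomes(SimConfig(seed=1, n_pool_females=8))

print(f"autosome: {len(truth.autosome_ref):,} bp   X: {len(truth.x_ref):,} bp   "
      f"Y: {len(truth.y_seq):,} bp")
m = truth.marker
print(f"marker X allele: {len(m.x_allele)} bp, Y allele: {len(m.y_allele)} bp "
      f"(difference = {len(m.y_allele) - len(m.x_allele)} bp of Y insertions)")
print(f"truth primers: F={m.primers.forward} R={m.primers.reverse}")
print("Y-specific intervals (0-based, half-open on Y):")
for s, e in truth.y_specific_intervals:
    print(f"  Y:{s}-{e}  ({e - s} bp)")
print("Each interval shares no 60-mer with any simulated female haplotype;")
print("the middle one contains the marker core, the flanking two are the")
print("SNP-diverged blocks of the envelope.")
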