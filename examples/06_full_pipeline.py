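"""The whole study in one call: simulate, discover, validate, genotype.

Runs subtractive hybridization -> assembly -> pool screen -> flank recovery
-> primer design -> in-silico genotyping at the default desk-scale
conditions and prints the manifest counts plus the discovered marker.
"""

from ymarker import default_study_config, run_study

result = run_study(default_study_config(seed=1))

for stage, counts in result.manifest.stages.items():
    print(f"{stage:10s} {counts}")

ev = result.evaluation
print(f"\nplanted-interval recovery: recall={ev.recall:.2f} precision={ev.precision:.2f}")

m = result.marker
print(f"discovered marker (from {m.contig_id}):")
print(f"  F={m.primers.forward}  R={m.primers.reverse}")
print(f"  X band {m.x_band} bp, Y band {m.y_band} bp "
      f"(difference {m.y_band - m.x_band} bp = the planted Y insertions)")
calls = {n: c.call for n, c in sorted(result.genotype_calls.items())}
print(f"  genotype calls: {calls}")
print(f"  all correct: {result.genotypes_correct}")
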