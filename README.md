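# ymarker

Subtractive k-mer discovery of Y-chromosome-specific markers, with
in-silico PCR genotyping of XX / XY / YY individuals and a deterministic
XY-genome read simulator.

## The problem

In many farmed fishes one sex grows much faster, so hatcheries want
all-male (or all-female) stock. Producing all-males through YY "super-male"
breeding requires telling XX, XY and YY fish apart — but young sex
chromosomes carry no visible heteromorphism, and test crosses take years.
A sequence marker that distinguishes X from Y turns sexing into a single
PCR.

`ymarker` implements the NGS-based discovery scheme for such markers in a
species with male heterogamety (XX/XY), built for researchers who want to
prototype, test, or teach the method at desk scale:

1. **Subtractive hybridization.** From every male read, cut the fixed-locus
   60-mer (read positions 11–70, each mate an independent locus). Discard
   every k-mer whose canonical form (min of k-mer and reverse complement)
   occurs in the female reference genome; what remains is enriched for Y.
2. **Enrichment.** Assemble the surviving k-mers into unitig contigs with a
   minimal De Bruijn assembler (coverage pruning suppresses
   sequencing-error k-mers; paths stop at every branch, so no chimeras).
   Exclude any contig that shares a 60-mer with reads from a pooled-female
   library — those sequences exist in females and are merely individual or
   population variation. Survivors are candidate Y-specific fragments.
3. **Counter-parting.** For a validated candidate, recover its flanking
   sequence from the mates of reads anchored at the contig ends, mark the
   flank windows covered by female 60-mers (conserved between X and Y), and
   place primers there. Such a primer pair amplifies the X allele in every
   individual and the longer Y allele only when a Y is present, so band
   patterns read out genotypes directly:

   | genotype | bands |
   |----------|-----------------|
   | XX       | X allele only   |
   | XY       | X and Y alleles |
   | YY       | Y allele only   |

The bundled simulator generates the study conditions end-to-end: a diploid
XX female, an XY male whose Y carries a divergent region (SNPs plus
insertions of 16, 7, 68 and 21 bp — so the X allele of the marker locus is
458 bp and the Y allele 570 bp), a pool of females, and 150 bp paired-end
reads with 300–500 bp inserts. Ground truth (Y-specific intervals, allele
pair, expected genotypes) comes with it, so the whole pipeline is testable
with no downloads.

## Worked example

```python
from ymarker import default_study_config, run_study

result = run_study(default_study_config(seed=1))
ev = result.evaluation
print(ev.recall, ev.precision)            # 1.0 1.0
m = result.marker
print(m.x_band, m.y_band)                 # 402 514
print({n: c.call for n, c in result.genotype_calls.items()})
```

prints recall and precision of 1.0 (every planted Y-specific interval was
recovered and every candidate is truly Y-derived), a discovered marker
whose X band is 402 bp and Y band 514 bp — the 112 bp difference is exactly
the planted Y insertions — and genotype calls `XX` for the nine simulated
females, `XY` for the male and `YY` for the super-male, all matching the
simulated truth. Exact band lengths depend on where the validated primers
landed in the conserved flanks; the 112 bp spacing does not.

The `examples/` scripts walk each capability separately (simulation,
subtraction + assembly, pool screening, flank recovery + primer design,
genotyping, full pipeline) and print what the numbers mean. A thin CLI
mirrors the stages for file-based use:

```sh
ymarker simulate --seed 1 --out sim/
ymarker subtract --male-r1 sim/M1_R1.fastq.gz --male-r2 sim/M1_R2.fastq.gz \
    --female-ref sim/female_reference.fasta --out-kmers unaligned.txt.gz
ymarker assemble --kmers unaligned.txt.gz --out contigs.fasta --dbg-k 17 --min-len 120
ymarker poolfilter --contigs contigs.fasta --pool-r1 sim/pool_R1.fastq.gz \
    --pool-r2 sim/pool_R2.fastq.gz --out candidates.fasta
ymarker run-all --seed 1 --out run/   # everything, plus manifest.json
```

See `docs/methods.md` for the model, parameter defaults, and limitations.

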