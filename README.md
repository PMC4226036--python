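# plastrep

Comparative repeat-landscape analysis of organellar genomes (chloroplasts and
mitochondria): detection and annotation of the repeat structures that shape
these genomes, and the statistics used to compare them across algal lineages.

Algal organellar genomes are small circular molecules whose architecture is
dominated by a few repeat classes: small (<200 bp) inverted repeats
(stem-loops) and tandem arrays scattered through intergenic space, the large
ribosomal inverted repeat (IR) that duplicates the 16S–ISR–23S–5S rRNA operon
in most plastids, and occasional multi-kilobase composite tandem-repeat
regions in mitochondria. `plastrep` provides, as a library and a CLI:

- **Small repeat detection.** Inverted repeats found by an exact banded
  local-alignment dynamic programme of the sequence against its reverse
  complement (einverted-default scoring: match +3, mismatch −4, gap −12,
  threshold 50; loop ≤ 30 bp; footprint < 200 bp). Tandem arrays found by
  period-wise self-comparison and scored against their own consensus
  (Tandem Repeats Finder-default weights: match 2, mismatch 7, min score 50,
  period ≤ 200).
- **Large IR analysis.** The ribosomal IR is located by exact k-mer
  self-comparison (k = 21) chained along anti-diagonals and extended until
  windowed identity between the copies drops below 90%; the duplicated rRNA
  genes are globally aligned and each SNP and each inserted/deleted base is
  counted separately; the 16S–23S intergenic spacer (ISR) is classified
  canonical (tRNA-Ile + tRNA-Ala in both copies) or non-canonical.
- **Gene–repeat association.** A repeat is associated with a gene when their
  nearest boundaries lie within 300 bp of either gene end with no annotated
  feature in between; per-gene conservation fractions are tabulated across a
  genome panel.
- **Lineage statistics.** Fisher's exact test on tandem-majority versus
  inverted-majority genomes between taxon groups (CASH, rhodophyte, green),
  and OLS regressions of repeat number/size on genome size and mean
  intergenic distance.
- **Gene-order rearrangement.** Exact signed reversal distance between two
  genomes' shared gene orders via the breakpoint graph,
  d = n + 1 − c + h + f (cycles, hurdles, fortress), validated against
  breadth-first search.
- **Composite repeat regions.** Greedy decomposition of a region into repeat
  unit classes (e.g. the B-A-A-A-B flanking domains of a mitochondrial repeat
  region) at an 80% identity threshold.
- **Synthetic genomes.** A generator that plants all of the above with exact
  ground-truth coordinates and divergence counts, so every stage is testable
  without downloads.

## Worked example

Generate a chloroplast-like genome carrying a known repeat landscape, then
analyse it:

```python
from plastrep import (SyntheticSpec, PlantedIR, PlantedTR, LargeIRSpec,
                      generate_genome, find_inverted_repeats,
                      find_tandem_repeats, analyze_large_ir)

spec = SyntheticSpec(
    seed=11, genome_length=60_000, gc=0.363,
    planted_irs=tuple(PlantedIR(stem=25, loop=6) for _ in range(16)),
    planted_trs=(PlantedTR(period=15, copies=2),),
    large_ir=LargeIRSpec(length=4656, snps_16s=6, snps_23s=5,
                         isr_layout="ctobin"),
    n_genes=30, genome_id="demo_cp",
)
genome, truth = generate_genome(spec)

irs = find_inverted_repeats(genome)
trs = find_tandem_repeats(genome)
rep = analyze_large_ir(genome)
print(len(irs), "inverted repeats,", len(trs), "tandem repeat")
print("IR length:", rep.ir_length,
      "| 16S SNPs:", rep.per_gene_divergence["16S"][0],
      "| 23S SNPs:", rep.per_gene_divergence["23S"][0],
      "| ISR:", rep.isr_label, rep.isr_trnas)
```

prints

```
16 inverted repeats, 1 tandem repeat
IR length: 4656 | 16S SNPs: 6 | 23S SNPs: 5 | ISR: non-canonical {'A': ['tRNA-Ala'], 'B': ['tRNA-Ile']}
```

i.e. the scan recovers all 16 planted stem-loops and the single duplicated
15-mer at exact coordinates; the large-IR module recovers the planted
4,656 bp repeat, the six SNPs between the 16S copies and five between the 23S
copies, and recognises the asymmetric spacer arrangement (tRNA-Ala in one
copy, tRNA-Ile in the other) as non-canonical.

The same operations are available from the shell on GenBank or FASTA+GFF3
inputs:

```bash
plastrep scan genome.gb                          # small repeats -> TSV
plastrep scan genome.gb --sweep                  # census across thresholds
plastrep ir genome.gb                            # large IR + copy divergence
plastrep assoc genome.gb --genes clpC,rbcS       # gene-repeat associations
plastrep rearrange a.gb b.gb                     # signed reversal distance
plastrep region genome.gb --start 12000 --end 21500
plastrep survey manifest.tsv --out results/      # the whole pipeline
```

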