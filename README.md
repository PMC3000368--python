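# islandkit

Toolkit for linking GC-rich sequence elements to repressive-chromatin
occupancy: CpG-island discovery in arbitrary genomes, PWM motif scanning at
a significance threshold, windowed ChIP-Seq enrichment calling against a
randomized-read empirical null, promoter chromatin-state and CpG-class
stratification, TSS methylation composites, and ChIP-qPCR fold-enrichment
quantification — all exercisable end-to-end on synthetic data with known
ground truth.

## Modules

| module              | what it does |
|---------------------|--------------|
| `islandkit.core`    | genomic intervals (0-based half-open) and genome sequences |
| `islandkit.io`      | FASTA / BED / bedGraph / WIG / PWM / TSV readers and writers |
| `islandkit.config`  | run configuration, YAML loading, seed + digest logging |
| `islandkit.seqscan` | sliding-window GC / CpG O-E, CpG-island calling, GC-rich motif-depleted element discovery |
| `islandkit.motifs`  | PWM scanning with exact score distributions, hit counting, asymmetry and depletion scoring |
| `islandkit.enrichment` | read densities, randomized-read null, enrichment calling, region merging, promoter mark classification, heat-map matrices, spreading extent |
| `islandkit.expression_meth` | promoter HCP/ICP/LCP classes, exonic expression scores, repressor stratification, methylation summaries |
| `islandkit.qpcr`    | ChIP-qPCR fold enrichment, negative-control normalization, replicate SEM |
| `islandkit.simulate` | synthetic genomes (first-order Markov, plantable GC/O-E segments and motifs), ChIP/RNA-Seq reads, methylation calls, qPCR tables — each with a serialisable truth record |

Key statistical choices (all configurable): enrichment windows are 1 kb and
calls use p < 1e-3 against an empirical null built from 10 uniform
re-placements of the same reads (add-one-smoothed upper tail, one null per
dataset); enriched windows within 1 kb are merged; motif matches use
per-position p-values at alpha 5e-5 from an exact (millibit-discretised)
score convolution; island criteria default to GC >= 0.5, O/E >= 0.6,
length >= 200 bp. No multiple-testing correction is applied beyond the
fixed threshold, and there is no input-chromatin correction — calls are
against the randomized self-background only.

## CLI

```sh
islandkit simulate --preset ecoli-like --seed 1 --outdir sim/
islandkit scan-islands --fasta sim/genome.fa --out islands.bed
islandkit scan-motifs --fasta sim/genome.fa --pwm motifs.pwm --alpha 5e-5 --out hits.bed
islandkit find-elements --fasta sim/genome.fa --pwm motifs.pwm --max-hits 2 --out elements.bed
islandkit call-enrichment --reads sim/chip_reads.bed --fasta sim/genome.fa --seed 2 --out regions.bed
islandkit classify-promoters --marks K4me3=k4.bed --marks K27me3=k27.bed \
    --promoters tss.tsv --fasta genome.fa --out calls.tsv
islandkit expression-score --rnaseq rna.bed --exons exons.tsv --out scores.tsv
islandkit meth-profile --meth meth.tsv --tss tss.tsv --out profile.tsv
islandkit qpcr --table qpcr.tsv --normalize-marks K27me3,Ezh2 --out results.tsv
```

Mapped reads are 4+ column BED where `start` is the 5' position; PWM files
are `>name` headers followed by one A/C/G/T probability row per position;
methylation TSVs carry `contig position methylated total`. Every subcommand
logs its seed, effective config and input SHA-256 digests.

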