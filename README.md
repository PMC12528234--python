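# metasat

Detection of (possibly rare) bacterial species in shotgun metagenomes via
competitive read recruitment and coverage-breadth saturation curves, plus the
whole-genome indices used for species delimitation — with a synthetic
community simulator so the entire pipeline is testable without external data.

## What it does

1. **simulate** — generate random genomes with tunable G+C, derive
   conspecific strains (shared core, distinct accessory regions) or more
   distant relatives (with conserved islands), and draw uniform 150 bp
   single-end reads with substitution errors from a community at fixed
   relative abundances. Fully deterministic per seed.
2. **recruit** — build a concatenated reference set with masked intervals
   (e.g. ribosomal operons) excised, and competitively assign each read
   full-length (ungapped, both strands, exact k-mer seeding) to at most one
   genome at ≥ 95% identity. SAM import/export for interoperability with
   external mappers (identity from the NM tag over query length).
3. **coverage** — per-base depth, coverage breadth (% positions covered) and
   mean depth per covered position; seeded, order-independent alignment
   subsampling.
4. **calibrate** — stepwise-reduce mapped reads, record breadth at each
   level, fit the saturating curve `B(n) = b_max · (1 − exp(−n/τ))` per
   genome, and select the smallest asymptote (the core-genome ceiling) as the
   calibration curve. Calibration mappings must exceed 100× depth and 70%
   breadth.
5. **detect / survey** — call a species present when the observed breadth is
   at least `b_min` (default 10%) *and* above the calibrated curve at the
   same mapped-read count (an alternative "≥ fold × predicted" rule is
   selectable; the criterion's phrasing is ambiguous and every output records
   which rule was applied).
6. **genome indices** — fragment-based whole-genome average nucleotide
   identity (gANI, 1020 bp fragments, 70%/70% qualification) with alignment
   fractions, the 95% species demarcation classifier, marker-gene (gyrB-style)
   identity typing at 97%, genome summary statistics, and labelled
   intra-/inter-species gANI–AF scatter data.

## CLI

```bash
# simulate a community (genomes + reads + truth table)
metasat simulate --config community.yaml --outdir sim/

# competitive recruitment at >= 95% identity, rRNA operons excised
metasat recruit ref1.fasta ref2.fasta --reads sim/reads.fastq \
    --masks rrna.bed --min-identity 95 --out aln.tsv

# coverage summaries
metasat coverage ref1.fasta ref2.fasta --alignments aln.tsv \
    --total-reads 28200000 --out coverage.tsv

# saturation calibration -> fit JSON
metasat calibrate ref1.fasta --alignments aln.tsv --genome-id ref1 \
    --fit-out fit.json --points-out points.tsv

# presence/absence in one metagenome, or a survey over many
metasat detect ref1.fasta --reads metagenome.fastq --fit fit.json --out det.tsv
metasat survey ref1.fasta --metagenome river1=r1.fastq \
    --metagenome river2=r2.fastq --fit fit.json --out survey.tsv

# genome indices
metasat ani genomeA.fasta genomeB.fasta
metasat stats genomeA.fasta genomeB.fasta
metasat marker gyrB_isolate.fasta gyrB_type_strain.fasta
```

Each reference FASTA is one genome (records are its contigs). BED masks use
contig ids (or `genome:contig`) with 0-based half-open intervals.

A community config for `simulate` looks like:

```yaml
genomes:
  - {id: ref, length: 2400000, gc: 0.42, n_contigs: 1, seed: 1}
  - {id: strain, parent: ref, substitution_rate: 0.0075,
     accessory_swap_fraction: 0.05, seed: 2}
community:
  members:
    - {genome: strain, abundance: 0.002}
    - {genome: ref, abundance: 0.998}
  read_length: 150
  error_rate: 0.002
  n_reads: 1000000
  seed: 7
```

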