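# pirnasv

A toolkit for the computational analyses linking pachytene piRNA loci to
structural-variation (SV) hotspots in amniote genomes:

- **piRNA locus detection** — iterative dynamic-programming segmentation of
  1-kb window abundance with a top-5%-mean penalty, per-base boundary
  refinement, and a unique-read filter (`pirna_clusters`).
- **SV hotspot calling** — two-caller consensus filtering, Gaussian
  kernel-density hotspot detection with a uniform-replacement permutation
  null (family-wise, per-trial maximum reference), per-chromosome-class
  bandwidths, and a parsimony bandwidth selector (`sv_hotspots`).
- **Interval shuffling tests** — same-chromosome length-preserving
  shuffles with count / overlap / nearest-distance / mean-score statistics
  and both the printed P = min{1, max{Pl, Pu}} and the one-tailed
  empirical p (`shuffle_stats`).
- **Small-RNA signatures** — ping-pong 5'–5' overlap spectra with the
  10-bp Z-score, and ribosome-footprint periodicity spectra (`signatures`).
- **Small-RNA quantification** — miRNA-sum normalization, oxidized-library
  calibration, per-feature ppm/rpkm with fractional multi-mappers, Shannon
  diversity, strand bias, LOESS-residual expression variance, and
  Wootton–Federhen sequence complexity (`smallrna_quant`).
- **TE insertion classification and dating** — 80-80-80 hit filtering,
  the solo-LTR / intact-ERV / non-LTR structural decision cascade,
  active-family calling with LTR↔internal expansion, and JC69 age
  estimation at 1.9 × 10⁻³ substitutions/site/My (`te_pipeline`).
- **Synthetic data** — deterministic generators for genomes with
  macro/intermediate/micro chromosomes, SV call sets with planted
  hotspots, collapsed small-RNA reads with planted clusters and ping-pong
  pairs, and labeled TE insertions of every structural category, so every
  stage is testable offline (`synthetic_data`).

All coordinates are 0-based half-open; I/O covers BED, chrom.sizes,
minimal VCF, collapsed FASTA with count-encoded headers, bedGraph, and
tabular hit/SV formats (`core_model`).

## CLI

A single entry point with one subcommand per stage:

```sh
pirnasv simulate --config config.yaml --seed 1 --outdir sim/
pirnasv clusters --reads sim/reads.fa --mappings sim/mappings.tsv \
    --sizes sim/genome.chrom.sizes --out clusters.bed
pirnasv pingpong --reads sim/reads.fa --mappings sim/mappings.tsv --out pp.tsv
pirnasv sv-consensus --calls-a sim/sv_callerA.tsv --calls-b sim/sv_callerB.tsv \
    --sizes sim/genome.chrom.sizes --out consensus.tsv
pirnasv hotspots --calls consensus.tsv --sizes sim/genome.chrom.sizes \
    --bw 20000 --trials 1000 --seed 1 --out hotspots.bed
pirnasv shuffle-test --query hotspots.bed --features genes.bed \
    --sizes sim/genome.chrom.sizes --stat distance --direction less \
    --trials 10000 --seed 1 --out shuffle.json
pirnasv te-classify --hits sim/te_hits.tsv --consensus-meta sim/te_consensus_meta.tsv \
    --insertions sim/te_insertions.fa --reference-solo-ltrs sim/reference_solo_ltrs.bed \
    --out te_calls.tsv
pirnasv te-age --hits sim/te_hits.tsv --consensus-meta sim/te_consensus_meta.tsv \
    --out te_ages.tsv
```

`quant`, `variance`, `complexity`, and `periodicity` cover the remaining
quantification stages; every subcommand documents its options via
`--help`.

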