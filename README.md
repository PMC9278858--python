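# polterm

Genome-wide annotation of RNA polymerase III terminators (T-tracts) and
quantification of transcription read-through (RT) from strand-specific
single-nucleotide occupancy tracks, with a stochastic polymerase-elongation
simulator providing fully ground-truthed synthetic data.

The pipeline:

1. **Terminator annotation** (`polterm.genome_annotation`) — scan a genome
   FASTA for maximal runs of ≥4 sense-strand Ts on both strands, assign each
   gene the first downstream tract as its *primary terminator* (recording the
   spacer to the gene 3′ end), collect *secondary terminators* in the 700 bp
   downstream window, and classify tracts as weak (4–5 Ts) or strong (≥6 Ts).
2. **Coverage** (`polterm.coverage`) — load strand pairs of bedGraph files
   into dense per-base tracks, CPM-normalise by the joint strand total,
   query region signals, average replicates, and rank-correlate samples over
   gene ± 500 bp windows.
3. **RT calling** (`polterm.rt_calling`) — estimate a background threshold
   as the 95% quantile of total signal in 20-bp nonoverlapping windows over
   protein-coding genes, then call each gene's RT region in the 1 kb
   downstream of its primary terminator using overlapping 20-bp windows,
   strict above-threshold marking, fragment union and small-gap merging.
4. **Termination statistics** (`polterm.termination_stats`) — RT index
   (RT-region signal as % of gene-body signal), RT length, per-base log2
   fold-change tracks, scaled metagene and heatmap matrices, ranking of
   genes by mutant-dependency with quartile assignment, per-quartile
   secondary-terminator composition, Kruskal-Wallis / Mann-Whitney /
   paired-Wilcoxon group tests, and Pearson condition correlations.
5. **Synthetic data** (`polterm.synthetic_data`) — builds a tract-free
   random genome with designed terminators and simulates polymerase walks
   with length-dependent release at tract 3′ edges and condition-dependent
   fail-safe release at downstream pause sites, emitting bedGraph/BED/FASTA
   inputs plus exact per-gene truth.

All coordinates are 0-based half-open (BED convention); "downstream" is
always in transcription orientation.

## CLI

```sh
# generate a ground-truthed synthetic input set
polterm simulate --seed 7 --outdir fixtures/

# write a pipeline config (paths + parameters; see polterm/config.py)
polterm annotate --config config.yaml            # tract BED + terminator TSV
polterm rt-call  --config config.yaml --condition WT
polterm stats    --config config.yaml --figures  # summaries, matrices, tests
polterm all      --config config.yaml            # everything, both conditions
polterm coverage --plus f.bedgraph --minus r.bedgraph --chrom-sizes cs.tsv
```

A minimal `config.yaml`:

```yaml
genome_fasta: fixtures/genome.fa
genes_bed: fixtures/genes.bed
coding_bed: fixtures/coding.bed
chrom_sizes: fixtures/chrom.sizes
coverage:
  WT:     {plus: fixtures/WT_plus.bedgraph,     minus: fixtures/WT_minus.bedgraph}
  mutant: {plus: fixtures/mutant_plus.bedgraph, minus: fixtures/mutant_minus.bedgraph}
outdir: out
```

Every stage writes a provenance file (config echo, version, input
checksums) and logs per-stage counts, including genes flagged for having no
primary terminator within the search window.

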