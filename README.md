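# conslift

Cross-genome projection of regulatory elements (REs) through UCSC alignment
chains, and hierarchical classification of their evolutionary constraint.

Given a set of RE intervals on a reference genome and one pairwise chain
file per target genome, `conslift`:

1. projects every RE through every chain set and records the fraction of its
   bases that fall inside ungapped alignment blocks (the conservation
   matrix);
2. computes per-RE N1/N2 statistics (number of genomes with >= 90% / <= 10%
   alignable bases) and assigns each RE to one of four tiers:
   cross-species constrained, clade-specific, reference-species-specific, or
   unclassified;
3. characterizes REs by genomic context (TSS-proximal / genic / intergenic
   and promoter / exonic / intronic / intergenic), nearest gene, per-base
   conservation-score aggregates, transposable-element coverage and class
   composition, motif presence, and QTL overlap (QTLs > 1 Mb excluded);
4. regresses per-genome high/low alignment counts on divergence time and
   runs PCA on the conservation matrix;
5. ships a coordinate-level genome-evolution simulator that emits chain
   files with divergence-dependent alignment loss and truth-labelled REs, so
   the whole pipeline is testable offline with known ground truth.

Reported percentages are floor-truncated (not rounded) at print time, and
threshold comparisons against 0.9 / 0.1 are rational-exact.

## CLI

All stages are subcommands of one entry point:

```sh
conslift simulate --seed 1 --out data/            # synthetic dataset
conslift project  --re data/res.bed --chains data/chains --out matrix.tsv
conslift classify --matrix matrix.tsv --groups groups.yaml --out classes.tsv
conslift summarize --classes classes.tsv          # count/percentage table
conslift annotate --re data/res.bed --genes data/genes.gff3 \
                  --scores data/scores.bedgraph --classes classes.tsv --out annot.tsv
conslift overlaps --re data/res.bed --classes classes.tsv --te data/te.bed \
                  --motifs data/motifs.bed --qtl data/qtl.bed --out overlaps/
conslift trends   --matrix matrix.tsv --divergence data/divergence.tsv --out trends.tsv
conslift pca      --matrix matrix.tsv --components 2 --out pca.tsv
conslift run      --input data/ --out results/    # everything end to end
```

`groups.yaml` lists `clade_members` and `outgroup_members` (the two sets
must partition the matrix columns used for interspecific classification).
`conslift run` consumes a simulator-layout directory, writes every stage
output plus `report.json` and a `manifest.json` with input checksums, and
reports truth-recovery accuracy when the input REs carry truth labels.

## Input formats

BED3/BED6 (REs, motifs, QTLs), GFF3 gene models, RepeatMasker `.out` or
labelled TE BED, bedGraph / fixed-step wig score tracks, UCSC chain files,
and a TSV divergence table with header `taxon  divergence_mya  clade`
(clade is one of `clade` / `outgroup` / `conspecific`). All readers accept
gzip-compressed files and normalize to 0-based half-open coordinates.

## Layout

```
src/conslift/
  intervals.py   coordinate model + BED/GFF3/.out/bedGraph/TSV I/O
  chains.py      chain parsing, validation, indexing, projection, matrix
  classify.py    N1/N2, tier assignment, truncated-percentage summaries
  context.py     genomic-context labels, nearest gene, score aggregation
  overlaps.py    TE coverage/composition, motif and QTL statistics
  trends.py      OLS divergence regression and conservation-matrix PCA
  simulate.py    coordinate-level genome-evolution simulator
  pipeline.py    end-to-end orchestration with manifest
  cli.py         click command-line interface
```
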