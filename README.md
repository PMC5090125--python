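# msreseq

MSRE-seq DNA methylation profiling toolkit. Reconstructs per-CpG
methylation state from methyl-sensitive restriction digestion signatures
(HpaII `C^CGG`) in single-end short-read data, then discriminates sample
groups with differential-methylation statistics, methylation-load
aggregation, NMDS ordination, and bootstrap-supported hierarchical
clustering. A seeded read simulator provides planted ground truth for
every stage, so the whole pipeline is testable offline.

## How it works

Cutting by a methyl-sensitive enzyme is blocked when the internal CpG of
the recognition site is methylated. After digestion, random shearing and
fixed-length sequencing, every recognition site leaves two read-evidence
channels:

- **M channel** (`m_metric`): reads spanning the intact motif, normalised
  by trough-masked local coverage — proportional to the fraction of genome
  copies fully methylated at the site.
- **U channel** (`u_metric`): excess read termini at the cut boundary over
  the random-shearing background, calibrated per sample — proportional to
  the fully unmethylated fraction.

The reported `%MET` score is the inverse-variance combination of the two
channels. Downstream, scores become pseudo-counts for a conditional
negative-binomial exact test with moment/shrinkage dispersion estimation
and Benjamini–Hochberg FDR; region-level shifts are summarised as signed
differential methylation load (reference group minus comparison group);
sample-level structure is assessed with Bray–Curtis NMDS (Kruskal
stress-1, isotonic regression, random restarts), mean-confidence ellipses
and an exhaustive/Monte-Carlo label-permutation test; and the
top-discriminating sites are clustered with average linkage on
correlation dissimilarity with bootstrap branch support.

## CLI

All functionality is exposed through the `profiler` command:

```sh
profiler simulate --config sim.yaml --outdir sim/ --seed 7
profiler sites    --fasta sim/genome.fa --out sites.bed
profiler quantify --sam sim/A1.sam --sites sites.bed --out A1.metrics.tsv
profiler diff     --matrix matrix.tsv --manifest manifest.tsv --fdr 0.05 --out diff.tsv
profiler load     --matrix matrix.tsv --manifest manifest.tsv --regions genes.bed --classes classes.tsv --out ml.tsv
profiler ordinate --matrix matrix.tsv --manifest manifest.tsv --out ord/
profiler cluster  --matrix matrix.tsv --top 60 --nboot 1000 --seed 1 --out tree.nwk
profiler run      --config run.yaml      # full pipeline + report directory
```

`profiler run` consumes a YAML config (unknown keys rejected), e.g.:

```yaml
manifest: sim/manifest.tsv
alignments:
  A1: sim/A1.sam
  A2: sim/A2.sam
  A3: sim/A3.sam
  B1: sim/B1.sam
  B2: sim/B2.sam
  B3: sim/B3.sam
sites: sim/sites.bed
outdir: report/
seed: 7
```

and writes `sites.bed`, `matrix.tsv`, `matrix.filtered.tsv`, `diff.tsv`,
`ml.tsv` (when regions are given), `distances.tsv`, `ordination.tsv`,
`ellipses.tsv`, `site_ranking.tsv`, `tree.nwk`, `bipartitions.tsv`,
`histogram.tsv`, `summary.tsv` and a `run_manifest.json` with parameters,
seed and input checksums. Re-running a config yields byte-identical
tables. Exit codes: 0 success, 2 validation error, 1 runtime error.

In `diff.tsv`, `response` "up" means a higher methylation signal in the
**second** group of the manifest order; in `ml.tsv`, positive load means
higher methylation in the **first** (reference) group.

## Layout

```
src/msreseq/
  reference.py    motif scanning, CpG census, site ids, BED I/O
  simulate.py     genome/methylome/library simulator with ground truth
  quantify.py     QC filter, evidence tabulation, calibration, M/U metrics,
                  matrix assembly, group-difference filter
  diff.py         pseudo-counts, dispersion estimation, NB exact test, BH
  load.py         differential methylation load over regions/domains/classes
  ordination.py   distances, NMDS, ellipses, permutation test, site ranking
  cluster.py      correlation average-linkage tree, bootstrap branch support
  pipeline.py     config validation, stage orchestration, report assembly
  evaluation.py   simulation-based acceptance measurements
  cli.py          the `profiler` command group
```
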