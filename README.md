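# remodelmap

Integrative chromatin-state analysis of SMARCB1 restoration in rhabdoid-tumor
cells. Malignant rhabdoid tumors are driven by biallelic loss of SMARCB1, a
core subunit of the BAF (SWI/SNF) chromatin-remodeling complex; re-expressing
SMARCB1 re-activates typical enhancers, redirects BAF-family occupancy, and
leaves an independent layer of lineage-gene silencing by promoter CpG
methylation. `remodelmap` implements the complete computational pipeline
behind that analysis as a tested, reusable library with a CLI, exercised end
to end on synthetic data with planted ground truth.

## What it computes

- **Differential binding** between two coverage tracks (bedGraph) with a
  signed Poisson log10 likelihood ratio per bin. With pseudocounted bin means
  *x*, *y* and *m* = (*x* + *y*)/2:

  LLR = sign(*y* − *x*) · (*x* ln(*x*/*m*) + *y* ln(*y*/*m*)) / ln 10

  Bins above +threshold become condition-2 ("gained") regions, below
  −threshold condition-1-specific regions, and high-signal bins inside the
  threshold band become "common" regions; regions are then filtered by
  requiring a called peak summit of the matching condition.
- **Chromatin states**: a gained H3K27ac region overlapping H3K4me3 is an
  active promoter; overlapping H3K4me1 without H3K4me3, an active enhancer.
- **Superenhancers** by stitch-and-rank: TSS-distal H3K27ac peaks stitched at
  12.5 kb, ranked by background-subtracted signal; the cutoff sits where the
  slope of the min-max-scaled rank curve first exceeds 1.
- **Complex occupancy**: SWI/SNF targets are loci where BRG1, BAF155, BAF170
  and SS18 peaks co-occur; PBAF adds BAF180/ARID2/BRD7, ncBAF is
  BRG1+BAF155+BRD9. Targets are partitioned into gained / common /
  mock-specific between conditions and intersected with top-ranked activated
  elements and BRD9±BRG1 sites.
- **Peak-gene association**: each element is assigned to its nearest TSS
  within ±100 kb; enrichment of associated genes among up-/down-regulated
  genes (FDR < 0.05, |log2FC| > 0.5) uses the hypergeometric upper tail, and
  up-vs-down |log2FC| is contrasted with a Wilcoxon rank-sum test.
  Tissue-specific enhancers (H3K27ac∩H3K4me1 unique to one of ten tissues)
  rank tissues by overlap with the activated enhancers.
- **Methylation-expression**: per-probe M-values (log2 methylated/unmethylated),
  replicate means, tumor-methylated probes (M > 1 in tumor, M < 0 in normal
  kidney), probe-to-gene assignment within ±5 kb, a 0.5-CPM gene filter,
  pseudocount-4 median-of-ratios normalization, and a rank-sum contrast of the
  hypermethylated cohort against a seeded 100-gene random control.

Every input the pipeline consumes can be generated by the `simulate` module
with planted ground truth, so all stages are testable with no downloads.

## Worked example

```python
from remodelmap import SimConfig, run_pipeline

report = run_pipeline(SimConfig(seed=1), outdir="out")
print(report["percentages"])
```

prints

```
{'up_associated_pct': 59, 'down_associated_pct': 36, 'promoter_pct': 11, 'enhancer_pct': 89}
```

meaning: 59% of upregulated genes (71/120) and 36% of downregulated genes
(12/33) carry at least one gained active enhancer within 100 kb of their TSS,
and the gained H3K27ac regions split 11% promoters / 89% enhancers. The same
run recovers 100% of the 210 planted differential windows with zero direction
swaps, classifies 523 tumor-methylated and 642 normal-methylated probes
(exactly the planted counts), finds the hypermethylated-gene cohort
suppressed in tumor libraries at p ≈ 10⁻¹⁹ while the random control stays
null (p = 0.65), and ranks brain as the top tissue for the activated
enhancers. `out/report.json` carries all stage counts;
`remodelmap verify --outdir out` re-derives every count from the stage output
files.

The same stages are exposed as subcommands:

```sh
remodelmap simulate --seed 1 --outdir sim/
remodelmap diffbind --track1 sim/track_mock.bedgraph --track2 sim/track_dox.bedgraph \
    --chrom-sizes sizes.tsv --llr-threshold 2 --outdir diff/
remodelmap run --seed 1 --outdir out/
```

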