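# Methods

## Coordinate conventions

All coordinates are 0-based, half-open (BED convention), for intervals and
bedGraph runs alike. Touching intervals — `[0,10)` and `[10,20)` — do not
overlap but do merge at `gap=0`. Overlap between peaks from different
experiments means ≥ 1 shared bp (a `min_overlap_bp` knob exists for
sensitivity checks). Nearest-feature distance is measured from the closest
interval edge to the TSS (0 when the TSS lies inside the interval); ties
break by smaller distance, then lexicographically smaller gene id, so every
proximity rule is deterministic. Strand is carried but ignored by proximity
rules. Chromosome names are compared verbatim — no `chr`-prefix coercion —
and a complete mismatch between two inputs raises a warning rather than
silently producing empty intersections.

## Differential binding model

The caller contrasts two coverage tracks under a per-bin Poisson model with
a common-rate null. Bin means are pseudocounted (`pseudocount`, default 1.0,
which stabilizes the logs at zero coverage), track 2 is rescaled to track 1's
total signal (switchable), and each bin is scored

```
x = mean1 + pc ; y = mean2 + pc ; m = (x + y) / 2
llr = sign(y - x) * (x*ln(x/m) + y*ln(y/m)) / ln(10)
```

This statistic is zero iff the bins agree, antisymmetric under swapping
conditions, and its magnitude is the log10 generalized-likelihood-ratio of
"two Poisson rates" against "one shared rate". Defaults: 200 bp bins
(nucleosome-scale resolution), threshold 2 (the more stringent of the two
per-cell-line choices used for the rhabdoid lines: 2 for BT16, 1 for G401),
`max_gap` = one bin, `min_region_length` = two bins.

Region assembly merges consecutive same-class bins, bridging only unlabeled
gaps up to `max_gap`; a gap containing a bin claimed by another class is
never bridged, which makes the three output classes provably disjoint on the
genome. A region's llr is its extremal bin llr (not the mean), matching the
summit-centric downstream filtering. "Common" regions additionally require
both conditions to clear a signal floor — by default the 90th percentile of
pooled bin coverage divided by 4 — so empty background is never called a
common peak. The summit filter retains a gained region only if it contains a
called peak summit from the gained condition (condition-1-specific regions
analogously; common regions accept either); missing summits are imputed as
interval midpoints with a warning.

Known limitation: the exact internal normalization and null model of the
upstream peak-caller workflow this re-states are not published, so region
counts from real deposited data will not numerically match counts produced
by that workflow; the formula above is this package's explicit, closed-form
definition.

## Chromatin states and superenhancers

Promoter takes precedence: a gained H3K27ac region overlapping H3K4me3 is an
active promoter even if H3K4me1 also overlaps (the enhancer definition is
"H3K4me1 without H3K4me3"). The genomic-distribution bins are an explicit
choice: promoter ≤ 1 kb, proximal 1–10 kb, distal > 10 kb from the nearest
TSS.

Superenhancer calling follows the stitch-and-rank convention: peaks within
±2.5 kb of a TSS are excluded, survivors are stitched at 12.5 kb, and each
stitched region is scored by its summed coverage minus region-length ×
genome-median per-base coverage, floored at 0. Both the rank axis and the
signal axis are min-max scaled to [0,1]; the cutoff is the unscaled signal at
the left endpoint of the first ascending segment whose discrete slope
exceeds 1, and regions strictly above the cutoff are superenhancers. Two
degenerate cases are defined explicitly: all-equal signals (scaling
undefined) and a curve whose slope never exceeds 1 both yield zero
superenhancers; fewer than three stitched regions is an error because the
curve has no interior. Adding a constant to every signal provably leaves
membership unchanged.

## Complex occupancy

"Overlap of core subunits with X" is read as mutual co-occurrence anchored
on BRG1, the shared ATPase: a BRG1 peak is a complex target iff every
required subunit peak set overlaps it by ≥ 1 bp, and targets are reported at
BRG1 peak boundaries (merged where they touch). The alternative
coverage-intersection reading (a common shared bp across all sets
simultaneously) is stricter; the anchor reading gives a deterministic
reporting unit that matches how co-occupancy is presented and verified here
against an exhaustive per-anchor oracle. The condition partition reports
dox-only targets as gained, mock-only as mock-specific, and overlapping
pairs once, as the dox interval.

Top-decile overlap ranks activated regions by their differential llr (the
pipeline's read-depth-difference statistic), ties broken by genomic order,
and reports the fraction of the top 10% carrying ≥ 1 gained SWI/SNF target.
At the synthetic problem size the top decile is only 15 regions, so this
fraction carries roughly ±15-point seed noise around its planted value; the
pipeline therefore also reports the same overlap across all activated
elements, which is the stable rendition of the quantity at this scale.

## Association and enrichment

The canonical association rule is nearest-gene-within-±100 kb (an
`all_within_window` switch associates every gene in the window instead; the
two readings disagree in general and one default had to be fixed). DE
filtering is strict on both cuts: `adj_p < 0.05` and `|log2FC| > 0.5`, so
boundary values are excluded. The enrichment universe is the supplied gene
annotation, not the genome, and is recorded in the output. The rank-sum
contrast uses exact enumeration when both samples have n ≤ 12 and no ties,
otherwise the normal approximation with tie correction and no continuity
correction (identical samples give p = 1); fully tied input returns p = 1.

Tissue-specific enhancers are H3K27ac∩H3K4me1 co-occurrence regions unique
to one tissue — a single shared bp with any other tissue's candidate
disqualifies an element, so the per-tissue outputs are pairwise disjoint by
construction. The tissue ranking statistic is a hypergeometric upper tail
over the pooled tissue-specific elements (configurable to raw counts); no
established ranking statistic exists for this comparison, so the choice is
declared rather than inherited.

## Methylation and expression

M = log2((meth + 1) / (unmeth + 1)); the offset guards zero intensities and
is negligible at array-scale intensities (~10³). Replicates are merged by
the arithmetic mean per group. Classification is strict: tumor-methylated
requires merged M > 1 in tumor and < 0 in normal kidney; normal-methylated
is the mirror (only the tumor direction is canonical; the mirror is this
package's declared rule); both-above-1 is "both"; everything else
"neither" — the four classes always partition the probes. Probes map to the
nearest TSS within ±5 kb by default (an unwindowed nearest-gene switch
exists, since both rules are in circulation).

Expression: genes need ≥ 0.5 CPM in ≥ 1 library; a pseudocount of 4 is added
before median-of-ratios normalization, re-implemented here with the raw-space
median of entry / row-geometric-mean ratios so the module has no external
statistical dependency. Note that with the per-row geometric mean as
reference, rescaling one of *m* libraries by *c* shifts every size factor by
c^(±1/m): the normalized matrix is invariant up to one global constant, the
scaled library's factor relative to the others absorbs exactly *c*, and
between-sample ratios are fully restored — that is the precise form of the
scale-removal property, and the form the tests assert. The contrast pools
per-gene group means of log10 normalized counts and applies the two-sided
rank-sum test; the random control draws 100 genes from the
non-hypermethylated complement with an explicit seed recorded in the report.

## Synthetic cohort

The generators are pure functions of `SimConfig`; a master seed derives
per-generator child seeds by fixed offsets, so adding a generator never
perturbs existing outputs, and every planted object is serialized in a truth
JSON that downstream recovery checks read back.

Noise models are the simplest consistent with each data type: Poisson bin
counts for ChIP coverage, Poisson-lognormal for RNA counts, lognormal for
array intensities. The ChIP arm is a desk-scale rendition of a genome-wide
experiment: a 10 Mb two-chromosome genome, 150 gained / 60 lost / 60 common
1 kb windows at 8× rate enrichment over a background of 10 per 200 bp bin,
and 600 genes. The planted fractions are the study conditions: 11.5% of
gained windows are promoter elements, 59% of the 120 upregulated and 36% of
the 33 downregulated genes are enhancer-linked, and 54% of activated
elements carry a gained SWI/SNF target (each subunit present at a truth
locus with probability 0.95, at each of 400 decoy loci with probability
0.02). Linked DE genes sit inside their enhancer window, so the
nearest-gene rule must recover the link; every remaining gained window hosts
a bystander gene, which guarantees no outside gene can be spuriously
associated and keeps the planted association counts exact. The methylation
arm keeps real-array scale: 27,578 probes, 523 tumor- and 642
normal-methylated planted with margin 1.0 beyond the thresholds (target
group-mean M of +2 / −1), three replicates per group with per-replicate
M-noise of 0.3, and twelve RNA libraries (six per group) in which the
tumor-methylated genes are suppressed 2-fold.

What the generators do not emulate — and what passing tests therefore do not
show about real data: mappability and GC bias, copy-number structure,
fragment-size effects, overdispersion beyond Poisson-lognormal, probe
cross-hybridization, and batch effects. Real-study genome-wide counts
(tens of thousands of peaks, hundreds of superenhancers) are deliberately
out of reach at this problem size; what the synthetic cohort validates is
the statistical machinery — recovery, calibration, partition arithmetic —
not the biology of any particular dataset.

## Numerical choices

Window means are computed from an exact prefix-integral of the coverage
runs, so signal matrices equal per-base averaging to 1e-9 regardless of how
runs align with query windows. Rows of a sorted signal matrix order by
descending row sum with a stable sort. Superenhancer ranks break ties by
genomic order. Percentage reporting rounds half-up to the nearest integer,
with raw fractions retained alongside. The hypergeometric tail is clamped to
(0, 1]; reported fractions are also rounded to two decimals next to their
raw counts.
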