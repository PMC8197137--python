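"""Peak-to-gene association, DE filtering, and enrichment statistics.

The association rule is nearest-gene-within-a-window (default ±100 kb of
a TSS): an element is assigned to the single gene whose TSS is closest,
and a gene is "associated" when at least one element is assigned to it.
An ``all_within_window`` switch associates every gene within the window
instead.  Enrichment of associated genes among differentially expressed
genes uses the hypergeometric upper tail over the supplied annotation
universe.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    GeneAnnotation,
    PeakSet,
    ValidationError,
    intersect_sets,
    intersection_regions,
    merge_intervals,
    nearest_feature,
)

__all__ = [
    "EnrichmentResult",
    "TissueEnhancerSet",
    "filter_de",
    "associate_genes",
    "hypergeom_enrichment",
    "rank_sum_test",
    "fc_contrast",
    "tissue_specific",
    "tissue_overlap_ranking",
]


@dataclass(frozen=True)
class EnrichmentResult:
    universe_n: int
    marked_n: int
    sample_n: int
    overlap_k: int
    p_upper: float


@dataclass
class TissueEnhancerSet:
    tissue: str
    elements: PeakSet


# ---------------------------------------------------------------------------
# DE table
# ---------------------------------------------------------------------------

def filter_de(
    table: pd.DataFrame, fdr: float = 0.05, min_abs_log2fc: float = 0.5
) -> tuple[set[str], set[str]]:
    """Split a DE table into up- and down-regulated gene sets.

    Both cuts are strict: ``adj_p < fdr`` and ``|log2fc| > min_abs_log2fc``.
    Expects columns ``gene_id``, ``log2fc``, ``adj_p``.
    """
    required = {"gene_id", "log2fc", "adj_p"}
    if not required.issubset(table.columns):
        raise ValidationError(f"DE table must have columns {sorted(required)}")
    if table["gene_id"].duplicated().any():
        dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].head(5).tolist()
        raise ValidationError(f"duplicate gene_id(s) in DE table: {dupes}")
    if ((table["adj_p"] < 0) | (table["adj_p"] > 1)).any():
        raise ValidationError("adj_p outside [0, 1]")
    sig = table["adj_p"] < fdr
    up = set(table.loc[sig & (table["log2fc"] > min_abs_log2fc), "gene_id"])
    down = set(table.loc[sig & (table["log2fc"] < -min_abs_log2fc), "gene_id"])
    return up, down


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

def associate_genes(
    elements: PeakSet,
    genes: GeneAnnotation,
    window: int = 100_000,
    all_within_window: bool = False,
) -> dict[str, int]:
    """Map gene id → number of associated elements (count >= 1 only).

    Default rule: each element is assigned to its nearest gene within
    *window* bp.  With ``all_within_window=True`` every gene whose TSS is
    within *window* of the element is associated instead.
    """
    if window <= 0:
        raise ValidationError("window must be positive")
    counts: dict[str, int] = {}
    for iv in elements:
        if all_within_window:
            tss, gids = genes.tss_on(iv.chrom)
            lo = bisect_left(tss, iv.start - window)
            hi = bisect_right(tss, iv.end + window)
            for j in range(lo, hi):
                d = max(iv.start - tss[j], tss[j] - iv.end, 0)
                if d <= window:
                    counts[gids[j]] = counts.get(gids[j], 0) + 1
        else:
            gid = nearest_feature(iv, genes, window)
            if gid is not None:
                counts[gid] = counts.get(gid, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def hypergeom_enrichment(
    universe: set[str], marked: set[str], sample: set[str]
) -> EnrichmentResult:
    """Upper-tail hypergeometric P(X >= k) for the marked/sample overlap."""
    if not marked <= universe:
        raise ValidationError("marked set is not a subset of the universe")
    if not sample <= universe:
        raise ValidationError("sample set is not a subset of the universe")
    N, K, n = len(universe), len(marked), len(sample)
    k = len(marked & sample)
    p_upper = float(stats.hypergeom.sf(k - 1, N, K, n))
    p_upper = min(1.0, max(p_upper, np.nextafter(0.0, 1.0)))
    return EnrichmentResult(N, K, n, k, p_upper)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both samples have n <= 12 and the pooled data
    carry no ties; otherwise the normal approximation with tie correction
    (no continuity correction, so identical samples give p = 1).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("rank-sum test requires two non-empty samples")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(a) <= 12 and len(b) <= 12 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(1.0, res.pvalue))


def fc_contrast(
    up_assoc: pd.DataFrame, down_assoc: pd.DataFrame
) -> dict[str, float]:
    """Contrast |log2fc| of enhancer-associated up- vs down-regulated genes.

    Returns the two-sided rank-sum p and the median |log2fc| per group.
    """
    for name, df in (("up", up_assoc), ("down", down_assoc)):
        if len(df) == 0:
            raise ValidationError(f"{name}-regulated associated set is empty")
    up_fc = np.abs(up_assoc["log2fc"].to_numpy())
    down_fc = np.abs(down_assoc["log2fc"].to_numpy())
    return {
        "p_value": rank_sum_test(up_fc, down_fc),
        "median_abs_log2fc_up": float(np.median(up_fc)),
        "median_abs_log2fc_down": float(np.median(down_fc)),
        "n_up": len(up_fc),
        "n_down": len(down_fc),
    }


# ---------------------------------------------------------------------------
# Tissue-specific enhancers
# ---------------------------------------------------------------------------

def _candidates(marks: Mapping[str, PeakSet], tissue: str) -> PeakSet:
    try:
        k27, k4 = marks["H3K27ac"], marks["H3K4me1"]
    except KeyError as exc:
        raise ValidationError(
            f"tissue {tissue!r} is missing mark {exc.args[0]!r}"
        ) from None
    return merge_intervals(intersection_regions(k27, k4))


def tissue_specific(
    enhancer_marks: Mapping[str, Mapping[str, PeakSet]], focal: str
) -> TissueEnhancerSet:
    """Enhancer elements unique to the focal tissue.

    Candidates are regions where the tissue's H3K27ac and H3K4me1 peaks
    co-occur; a focal candidate is retained iff it overlaps no candidate
    of any other tissue (a single shared bp disqualifies it).
    """
    if len(enhancer_marks) < 2:
        raise ValidationError("need >= 2 tissues to derive tissue-specific elements")
    if focal not in enhancer_marks:
        raise ValidationError(f"unknown focal tissue {focal!r}")
    focal_cand = _candidates(enhancer_marks[focal], focal)
    kept = focal_cand
    for tissue, marks in enhancer_marks.items():
        if tissue == focal:
            continue
        other = _candidates(marks, tissue)
        _, kept = intersect_sets(kept, other)
    return TissueEnhancerSet(focal, merge_intervals(kept))


def tissue_overlap_ranking(
    activated_enhancers: PeakSet,
    tissue_sets: Sequence[TissueEnhancerSet],
    use_hypergeom: bool = True,
) -> pd.DataFrame:
    """Per-tissue overlap of activated enhancers with tissue-specific sets.

    ``overlap_count`` is the number of activated enhancers overlapping at
    least one tissue-specific element.  The enrichment p (hypergeometric)
    treats the pooled tissue-specific elements as the universe of marked
    draws: N = pooled elements, K = the tissue's elements, n = activated
    enhancers with any tissue hit, k = this tissue's hits.  With
    ``use_hypergeom=False`` raw counts rank the table instead.
    Tissues are returned sorted by ascending p then descending count.
    """
    if len(tissue_sets) < 2:
        raise ValidationError("need >= 2 tissue sets")
    pooled_n = sum(len(ts.elements) for ts in tissue_sets)
    hits = {}
    for ts in tissue_sets:
        overlapping, _ = intersect_sets(activated_enhancers, ts.elements)
        hits[ts.tissue] = len(overlapping)
    n_any = len(
        intersect_sets(
            activated_enhancers,
            PeakSet(
                [iv for ts in tissue_sets for iv in ts.elements], label="pooled"
            ),
        )[0]
    )
    rows = []
    for ts in tissue_sets:
        k = hits[ts.tissue]
        if use_hypergeom and pooled_n > 0 and n_any > 0:
            p = float(stats.hypergeom.sf(k - 1, pooled_n, len(ts.elements), n_any))
            p = min(1.0, p)
        else:
            p = 1.0 if k == 0 else np.nan
        rows.append(
            {
                "tissue": ts.tissue,
                "n_tissue_elements": len(ts.elements),
                "overlap_count": k,
                "p_upper": p,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["p_upper", "overlap_count"], ascending=[True, False]
    ).reset_index(drop=True)
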