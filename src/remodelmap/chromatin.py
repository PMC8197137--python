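"""Chromatin-state classification of differential H3K27ac regions.

Active-promoter vs active-enhancer calls follow the histone-mark
co-occurrence rule: a region overlapping H3K4me3 is an active promoter
(promoter takes precedence when both marks are present); one overlapping
H3K4me1 without H3K4me3 is an active enhancer; anything else is left
unclassified.  Superenhancers are called by ROSE-style stitch-and-rank:
TSS-proximal peaks are excluded, survivors are stitched, and the stitched
regions are ranked by background-subtracted summed H3K27ac signal; the
cutoff sits where the slope of the min-max-scaled rank curve first
exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .genome import (
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    ValidationError,
    intersect_sets,
    merge_intervals,
    nearest_tss_distance,
)
from .signal import SignalTrack

__all__ = [
    "ElementState",
    "RegulatoryElement",
    "SuperEnhancer",
    "classify_elements",
    "genomic_distribution",
    "signal_matrix",
    "se_rank_cutoff",
    "call_superenhancers",
]


class ElementState(str, Enum):
    ACTIVE_PROMOTER = "active_promoter"
    ACTIVE_ENHANCER = "active_enhancer"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class RegulatoryElement:
    interval: GenomicInterval
    state: ElementState
    dependent_on_condition: bool = True


@dataclass(frozen=True)
class SuperEnhancer:
    interval: GenomicInterval
    constituent_count: int
    signal: float
    rank: int  # 1 = highest signal
    is_se: bool


def classify_elements(
    gained_k27ac: PeakSet, k4me3: PeakSet, k4me1: PeakSet
) -> list[RegulatoryElement]:
    """Assign each gained H3K27ac peak exactly one chromatin state."""
    with_me3, without_me3 = intersect_sets(gained_k27ac, k4me3)
    promoter = {id(iv) for iv in with_me3}
    with_me1, _ = intersect_sets(without_me3, k4me1)
    enhancer = {id(iv) for iv in with_me1}
    out: list[RegulatoryElement] = []
    for iv in gained_k27ac:
        if id(iv) in promoter:
            state = ElementState.ACTIVE_PROMOTER
        elif id(iv) in enhancer:
            state = ElementState.ACTIVE_ENHANCER
        else:
            state = ElementState.UNCLASSIFIED
        out.append(RegulatoryElement(iv, state))
    return out


def state_counts(elements: list[RegulatoryElement]) -> dict[str, int]:
    counts = {s.value: 0 for s in ElementState}
    for el in elements:
        counts[el.state.value] += 1
    return counts


def genomic_distribution(
    peaks: PeakSet,
    genes: GeneAnnotation,
    promoter_bp: int = 1_000,
    proximal_bp: int = 10_000,
) -> dict[str, int]:
    """Bin peaks by nearest-TSS distance: promoter (<=1 kb), proximal
    (1-10 kb), distal (>10 kb).  Counts sum to ``len(peaks)``."""
    if len(genes) == 0:
        raise ValidationError("empty gene annotation")
    counts = {"promoter": 0, "proximal": 0, "distal": 0}
    for iv in peaks:
        hit = nearest_tss_distance(iv, genes)
        d = hit[1] if hit is not None else np.inf
        if d <= promoter_bp:
            counts["promoter"] += 1
        elif d <= proximal_bp:
            counts["proximal"] += 1
        else:
            counts["distal"] += 1
    return counts


def signal_matrix(
    track: SignalTrack,
    centers: PeakSet,
    half_window: int,
    bins: int,
    sort: bool = False,
) -> tuple[np.ndarray, list[int]]:
    """Mean coverage in *bins* equal subwindows of ``center +/- half_window``.

    The center of each region is its summit when present, else its
    midpoint.  Windows truncated by chromosome bounds are averaged over
    their truncated extent; fully out-of-bounds subwindows read 0.
    Returns ``(matrix, row_order)``; with ``sort=True`` rows are ordered
    by descending row sum and ``row_order`` maps rows back to input
    indices.
    """
    if half_window <= 0 or bins <= 0:
        raise ValidationError("half_window and bins must be positive")
    mat = np.zeros((len(centers), bins))
    width = 2 * half_window / bins
    for i, iv in enumerate(centers):
        center = iv.summit if iv.summit is not None else iv.midpoint
        length = track.genome.get(iv.chrom)
        if length is None:
            raise ValidationError(f"center on unknown chromosome {iv.chrom!r}")
        lo = center - half_window
        edges = lo + np.arange(bins + 1) * width
        clamped = np.clip(edges, 0, length)
        for j in range(bins):
            a, b = clamped[j], clamped[j + 1]
            if b - a < 1e-9:
                continue
            # integer-resolution clamp keeps the integral exact
            mat[i, j] = track.integral(iv.chrom, int(round(a)), int(round(b))) / (
                int(round(b)) - int(round(a))
            )
    order = list(range(len(centers)))
    if sort:
        order = list(np.argsort(-mat.sum(axis=1), kind="stable"))
        mat = mat[order]
    return mat, order


def se_rank_cutoff(signals: np.ndarray) -> tuple[float | None, np.ndarray]:
    """Rank-curve cutoff over stitched-region signals.

    Both axes are min-max scaled to [0,1]; the cutoff is the (unscaled)
    signal at the left endpoint of the first ascending-rank segment whose
    discrete slope exceeds 1.  Regions strictly above the cutoff are
    superenhancers.  Degenerate scaling (all signals equal) or a curve
    whose slope never exceeds 1 yields zero superenhancers.
    """
    signals = np.asarray(signals, dtype=np.float64)
    n = len(signals)
    if n < 3:
        raise ValidationError("rank curve undefined for < 3 stitched regions")
    order = np.argsort(signals, kind="stable")
    s = signals[order]
    lo, hi = s[0], s[-1]
    if hi - lo <= 0:
        return None, np.zeros(n, dtype=bool)
    y = (s - lo) / (hi - lo)
    x = np.arange(n) / (n - 1)
    slopes = np.diff(y) / np.diff(x)
    above = np.flatnonzero(slopes > 1.0)
    if len(above) == 0:
        return None, np.zeros(n, dtype=bool)
    cutoff = float(s[above[0]])
    return cutoff, signals > cutoff


def call_superenhancers(
    k27ac_peaks: PeakSet,
    signal: SignalTrack,
    genes: GeneAnnotation,
    stitch_gap: int = 12_500,
    tss_exclude: int = 2_500,
) -> tuple[list[SuperEnhancer], float | None]:
    """Stitch-and-rank superenhancer calling from H3K27ac peaks.

    Peaks within ``tss_exclude`` bp of a TSS are removed, survivors are
    stitched at ``stitch_gap``, and each stitched region is scored by its
    summed coverage minus length x genome-median coverage, floored at 0.
    Returns every stitched region (flagged ``is_se``) plus the cutoff.
    """
    if stitch_gap <= 0:
        raise ValidationError("stitch_gap must be positive")
    survivors = []
    for iv in k27ac_peaks:
        hit = nearest_tss_distance(iv, genes)
        if hit is None or hit[1] > tss_exclude:
            survivors.append(iv)
    stitched = merge_intervals(PeakSet(survivors, label=k27ac_peaks.label),
                               gap=stitch_gap)
    background = signal.median_coverage()
    sigs = np.empty(len(stitched))
    counts = []
    for i, iv in enumerate(stitched):
        raw = signal.integral(iv.chrom, iv.start, iv.end)
        sigs[i] = max(0.0, raw - iv.length * background)
        counts.append(int((iv.name or "n=1")[2:]))
    cutoff, is_se = se_rank_cutoff(sigs)
    # rank 1 = highest signal; ties broken by genomic order (stable sort)
    order = np.argsort(-sigs, kind="stable")
    rank = np.empty(len(stitched), dtype=int)
    rank[order] = np.arange(1, len(stitched) + 1)
    out = [
        SuperEnhancer(iv, counts[i], float(sigs[i]), int(rank[i]), bool(is_se[i]))
        for i, iv in enumerate(stitched)
    ]
    return out, cutoff
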