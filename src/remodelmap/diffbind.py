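"""Differential binding between two coverage tracks.

The caller scans the genome in fixed bins and scores each bin with a
signed Poisson log10 likelihood ratio contrasting the two conditions
under a common-rate null.  With pseudocounted bin means ``x`` and ``y``
and ``m = (x + y) / 2``::

    llr = sign(y - x) * (x*ln(x/m) + y*ln(y/m)) / ln(10)

Bins exceeding ``+threshold`` are condition-2-enriched ("gained"), bins
below ``-threshold`` are condition-1-specific, and bins with ``|llr|``
at or under the threshold whose coverage clears a signal floor in both
conditions are "common" occupied regions (background stays unlabeled).
Consecutive same-class bins are assembled into regions, bridging only
unlabeled gaps up to ``max_gap`` bp, and short regions are dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomicInterval, PeakSet, ValidationError
from .signal import SignalTrack

__all__ = [
    "Direction",
    "DifferentialRegion",
    "DiffCallConfig",
    "llr_score",
    "call_differential",
    "summit_filter",
]

LN10 = math.log(10.0)


class Direction(str, Enum):
    GAINED = "gained_in_condition2"
    CONDITION1_SPECIFIC = "specific_to_condition1"
    COMMON = "common"


@dataclass(frozen=True)
class DifferentialRegion:
    """A genomic region with a signed log10 LR and its condition label."""

    interval: GenomicInterval
    llr: float
    direction: Direction

    def __post_init__(self) -> None:
        if self.direction is Direction.GAINED and self.llr <= 0:
            raise ValidationError("gained region must have llr > 0")
        if self.direction is Direction.CONDITION1_SPECIFIC and self.llr >= 0:
            raise ValidationError("condition-1-specific region must have llr < 0")


@dataclass
class DiffCallConfig:
    """Tuning knobs of the differential caller.

    ``llr_threshold`` follows the per-cell-line choices used for the two
    rhabdoid lines (2 for BT16, 1 for G401).  ``min_region_length`` and
    ``max_gap`` default to two bins and one bin respectively.  The common
    floor defaults to the 90th percentile of pooled bin coverage / 4 so
    empty background is never called "common"; set ``common_floor`` to
    override.  ``scale_libraries`` rescales track 2 to track 1's total
    signal before scoring.
    """

    bin_size: int = 200
    pseudocount: float = 1.0
    llr_threshold: float = 2.0
    min_region_length: int | None = None  # default: 2 * bin_size
    max_gap: int | None = None  # default: bin_size
    common_floor: float | None = None
    scale_libraries: bool = True

    def __post_init__(self) -> None:
        if self.min_region_length is None:
            self.min_region_length = 2 * self.bin_size
        if self.max_gap is None:
            self.max_gap = self.bin_size
        for name in ("bin_size", "pseudocount", "llr_threshold",
                     "min_region_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.max_gap < 0:
            raise ValidationError("max_gap must be >= 0")


def llr_score(count1, count2, pseudocount: float = 1.0):
    """Signed Poisson log10 likelihood ratio of two bin counts.

    Positive when condition 2 is enriched; antisymmetric under swapping
    the conditions.  Accepts scalars or numpy arrays.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    c1 = np.asarray(count1, dtype=np.float64)
    c2 = np.asarray(count2, dtype=np.float64)
    if not (np.all(np.isfinite(c1)) and np.all(np.isfinite(c2))):
        raise ValidationError("non-finite bin count")
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ValidationError("negative bin count")
    x = c1 + pseudocount
    y = c2 + pseudocount
    m = (x + y) / 2.0
    mag = (x * np.log(x / m) + y * np.log(y / m)) / LN10
    signed = np.sign(y - x) * mag
    if np.isscalar(count1) and np.isscalar(count2):
        return float(signed)
    return signed


def _assemble(
    chrom: str,
    labeled: np.ndarray,  # bool: bins of the class being assembled
    blocked: np.ndarray,  # bool: bins claimed by any other class
    llr: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    max_gap: int,
    min_len: int,
) -> list[tuple[GenomicInterval, float]]:
    """Merge runs of labeled bins, bridging unlabeled-unblocked gaps <= max_gap."""
    idx = np.flatnonzero(labeled)
    if len(idx) == 0:
        return []
    regions: list[tuple[GenomicInterval, float]] = []
    run = [idx[0]]
    for j in idx[1:]:
        prev = run[-1]
        gap_bp = starts[j] - ends[prev]
        bridge = gap_bp <= max_gap and not blocked[prev + 1 : j].any()
        if bridge:
            run.append(j)
        else:
            regions.append(_finish_run(chrom, run, llr, starts, ends))
            run = [j]
    regions.append(_finish_run(chrom, run, llr, starts, ends))
    return [(iv, v) for iv, v in regions if iv.length >= min_len]


def _finish_run(chrom, run, llr, starts, ends) -> tuple[GenomicInterval, float]:
    vals = llr[run]
    extremal = vals[np.argmax(np.abs(vals))]
    return (
        GenomicInterval(chrom, int(starts[run[0]]), int(ends[run[-1]])),
        float(extremal),
    )


def call_differential(
    track1: SignalTrack, track2: SignalTrack, cfg: DiffCallConfig | None = None
) -> list[DifferentialRegion]:
    """Call gained / condition-1-specific / common regions between two tracks.

    Returns a list of :class:`DifferentialRegion`; the three direction
    classes are mutually disjoint on the genome.
    """
    cfg = cfg or DiffCallConfig()
    if track1.genome != track2.genome:
        raise ValidationError("tracks are on different genomes")
    bins1 = track1.binned_means(cfg.bin_size)
    bins2 = track2.binned_means(cfg.bin_size)

    scale = 1.0
    if cfg.scale_libraries:
        t1, t2 = track1.total_signal(), track2.total_signal()
        if t1 > 0 and t2 > 0:
            scale = t1 / t2

    if cfg.common_floor is not None:
        floor = cfg.common_floor
    else:
        pooled = np.concatenate(
            [bins1[c] for c in bins1] + [bins2[c] * scale for c in bins2]
        )
        floor = float(np.percentile(pooled, 90)) / 4.0

    out: list[DifferentialRegion] = []
    for chrom, length in track1.genome.items():
        b1 = bins1[chrom]
        b2 = bins2[chrom] * scale
        n = len(b1)
        starts = np.arange(n, dtype=np.int64) * cfg.bin_size
        ends = np.minimum(starts + cfg.bin_size, length)
        llr = llr_score(b1, b2, cfg.pseudocount)
        gained = llr > cfg.llr_threshold
        specific = llr < -cfg.llr_threshold
        common = (~gained) & (~specific) & (b1 >= floor) & (b2 >= floor)
        for mask, others, direction in (
            (gained, specific | common, Direction.GAINED),
            (specific, gained | common, Direction.CONDITION1_SPECIFIC),
            (common, gained | specific, Direction.COMMON),
        ):
            for iv, v in _assemble(
                chrom, mask, others, llr, starts, ends,
                cfg.max_gap, cfg.min_region_length,
            ):
                out.append(DifferentialRegion(iv, v, direction))
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return out


def _summits(peaks: PeakSet) -> dict[str, np.ndarray]:
    """Per-chromosome sorted summit positions; midpoints impute absent summits."""
    imputed = any(iv.summit is None for iv in peaks)
    if imputed and len(peaks):
        warnings.warn(
            f"peak set {peaks.label!r}: imputing missing summits as interval "
            "midpoints",
            stacklevel=3,
        )
    per: dict[str, list[int]] = {}
    for iv in peaks:
        pos = iv.summit if iv.summit is not None else iv.midpoint
        per.setdefault(iv.chrom, []).append(pos)
    return {c: np.sort(np.array(p, dtype=np.int64)) for c, p in per.items()}


def _contains_summit(iv: GenomicInterval, summits: dict[str, np.ndarray]) -> bool:
    pos = summits.get(iv.chrom)
    if pos is None:
        return False
    j = np.searchsorted(pos, iv.start, side="left")
    return bool(j < len(pos) and pos[j] < iv.end)


def summit_filter(
    regions: Iterable[DifferentialRegion], peaks1: PeakSet, peaks2: PeakSet
) -> list[DifferentialRegion]:
    """Keep regions containing a peak summit from the matching condition.

    Gained regions must contain a summit from the condition-2 peak set,
    condition-1-specific regions from the condition-1 set, and common
    regions from either.
    """
    regions = list(regions)
    if len(peaks1) == 0 and len(peaks2) == 0:
        warnings.warn("summit_filter: both peak sets empty; all regions dropped",
                      stacklevel=2)
    s1 = _summits(peaks1)
    s2 = _summits(peaks2)
    kept: list[DifferentialRegion] = []
    for r in regions:
        if r.direction is Direction.GAINED:
            ok = _contains_summit(r.interval, s2)
        elif r.direction is Direction.CONDITION1_SPECIFIC:
            ok = _contains_summit(r.interval, s1)
        else:
            ok = _contains_summit(r.interval, s1) or _contains_summit(r.interval, s2)
        if ok:
            kept.append(r)
    return kept
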