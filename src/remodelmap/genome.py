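"""Genomic interval data model, BED-family I/O, and overlap algebra.

Coordinates are 0-based, half-open everywhere (BED convention).  Two
intervals that merely touch — ``[0,10)`` and ``[10,20)`` — do NOT overlap,
but they DO merge at ``gap=0``.  Chromosome names are compared verbatim;
no ``chr``-prefix coercion is attempted (a mismatch between two inputs is
surfaced as a warning listing the unshared chromosomes).
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GeneAnnotation",
    "ValidationError",
    "BedParseError",
    "parse_bed",
    "write_bed",
    "read_chrom_sizes",
    "intersect_sets",
    "merge_intervals",
    "subtract_blacklist",
    "intersection_regions",
    "nearest_feature",
    "nearest_tss_distance",
]


class ValidationError(ValueError):
    """An input violated a structural invariant (coordinates, signs, order)."""


class BedParseError(ValidationError):
    """A BED-family file could not be parsed; the message names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` with optional metadata.

    ``summit`` is an absolute base-pair position (not an offset) and must
    lie inside the interval; ``score`` is a non-negative real.
    """

    chrom: str
    start: int
    end: int
    score: float | None = None
    summit: int | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"summit {self.summit} outside {self.chrom}:{self.start}-{self.end}"
            )
        if self.score is not None and self.score < 0:
            raise ValidationError(f"negative score {self.score}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


class PeakSet:
    """An ordered collection of :class:`GenomicInterval`, sorted by
    ``(chrom, start)``, with an antibody/condition label.

    ``merged`` records whether the set has been through :func:`merge_intervals`
    and is therefore guaranteed non-overlapping.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        label: str = "",
        merged: bool = False,
    ) -> None:
        self.intervals: list[GenomicInterval] = sorted(intervals, key=_sort_key)
        self.label = label
        self.merged = merged
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __repr__(self) -> str:
        return f"PeakSet(label={self.label!r}, n={len(self)})"

    def chromosomes(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def total_bp(self) -> int:
        """Total covered base pairs (overlaps counted once)."""
        covered = 0
        for iv in merge_intervals(self, gap=0):
            covered += iv.length
        return covered

    def _tree(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self.intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            self._trees = trees
        return self._trees.get(chrom, IntervalTree())

    def max_overlap_bp(self, query: GenomicInterval) -> int:
        """Largest single-interval overlap (bp) between *query* and this set."""
        best = 0
        for hit in self._tree(query.chrom).overlap(query.start, query.end):
            ov = min(query.end, hit.end) - max(query.start, hit.begin)
            if ov > best:
                best = ov
        return best

    def overlaps(self, query: GenomicInterval, min_overlap_bp: int = 1) -> bool:
        return self.max_overlap_bp(query) >= min_overlap_bp


@dataclass
class GeneAnnotation:
    """TSS-anchored gene annotation: the anchor for every proximity rule.

    Strand is carried but ignored by the proximity rules.
    """

    gene_ids: list[str]
    chroms: list[str]
    tss: list[int]
    strands: list[str] = field(default_factory=list)

    _by_chrom: dict[str, tuple[list[int], list[str]]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted(
                {g for g in self.gene_ids if self.gene_ids.count(g) > 1}
            )[:5]
            raise ValidationError(f"duplicate gene_id(s): {dupes}")
        if not self.strands:
            self.strands = ["+"] * len(self.gene_ids)
        per: dict[str, list[tuple[int, str]]] = {}
        for gid, chrom, t in zip(self.gene_ids, self.chroms, self.tss):
            per.setdefault(chrom, []).append((t, gid))
        for chrom, pairs in per.items():
            pairs.sort()
            self._by_chrom[chrom] = ([p[0] for p in pairs], [p[1] for p in pairs])

    def __len__(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int] | tuple[str, str, int, str]]
    ) -> "GeneAnnotation":
        gene_ids, chroms, tss, strands = [], [], [], []
        for rec in records:
            gene_ids.append(rec[0])
            chroms.append(rec[1])
            tss.append(int(rec[2]))
            strands.append(rec[3] if len(rec) > 3 else "+")
        return cls(gene_ids, chroms, tss, strands)

    def tss_on(self, chrom: str) -> tuple[list[int], list[str]]:
        """Sorted TSS positions and matching gene ids on one chromosome."""
        return self._by_chrom.get(chrom, ([], []))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DIALECT_MIN_COLS = {"bed3": 3, "bed6": 3, "narrowPeak": 10}


def parse_bed(path: str | Path, dialect: str = "bed6", label: str | None = None) -> PeakSet:
    """Read a BED3/BED6/narrowPeak file into a sorted :class:`PeakSet`.

    narrowPeak summit offsets (column 10) are converted to absolute
    coordinates; an offset of ``-1`` is recorded as an absent summit.
    For narrowPeak the ``score`` carried is the signalValue (column 7).
    """
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < _DIALECT_MIN_COLS[dialect]:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= {_DIALECT_MIN_COLS[dialect]} "
                    f"tab-separated columns, got {len(cols)}"
                )
            try:
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: bad coordinates: {exc}") from None
            name = score = summit = None
            if dialect in ("bed6", "narrowPeak") and len(cols) >= 4:
                name = cols[3] if cols[3] not in (".", "") else None
            if dialect == "bed6" and len(cols) >= 5 and cols[4] not in (".", ""):
                score = float(cols[4])
            if dialect == "narrowPeak":
                score = float(cols[6])
                offset = int(cols[9])
                summit = start + offset if offset >= 0 else None
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, score=score, summit=summit, name=name)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return PeakSet(intervals, label=label or path.stem)


def write_bed(peaks: PeakSet, path: str | Path, score_attr: str = "score") -> None:
    """Write a PeakSet as BED6 (name, score, strand '.')."""
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks):
            score = getattr(iv, score_attr, None)
            fh.write(
                "\t".join(
                    (
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name or f"{peaks.label or 'region'}_{i + 1}",
                        "0" if score is None else f"{score:g}",
                        ".",
                    )
                )
                + "\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column ``chrom<TAB>length`` table → mapping."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise BedParseError(f"{path}:{lineno}: expected two columns")
            genome[cols[0]] = int(cols[1])
    return genome


def _warn_chrom_mismatch(a: PeakSet, b: PeakSet) -> None:
    ca, cb = a.chromosomes(), b.chromosomes()
    if ca and cb and not (ca & cb):
        warnings.warn(
            "no shared chromosome names between sets "
            f"({sorted(ca)[:4]} vs {sorted(cb)[:4]}); names are compared verbatim",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# Overlap algebra
# ---------------------------------------------------------------------------

def intersect_sets(
    a: PeakSet, b: PeakSet, min_overlap_bp: int = 1
) -> tuple[PeakSet, PeakSet]:
    """Partition *a* by overlap with *b*.

    An interval of *a* lands in the first output iff it overlaps at least
    one interval of *b* by ``>= min_overlap_bp``.  Input order is preserved
    and the two outputs partition *a*.
    """
    if min_overlap_bp < 1:
        raise ValidationError(f"min_overlap_bp must be >= 1, got {min_overlap_bp}")
    _warn_chrom_mismatch(a, b)
    hit: list[GenomicInterval] = []
    miss: list[GenomicInterval] = []
    for iv in a:
        (hit if b.overlaps(iv, min_overlap_bp) else miss).append(iv)
    return (
        PeakSet(hit, label=a.label, merged=a.merged),
        PeakSet(miss, label=a.label, merged=a.merged),
    )


def merge_intervals(a: PeakSet, gap: int = 0) -> PeakSet:
    """Merge intervals whose separation is ``<= gap`` bp.

    At ``gap=0`` touching intervals merge (half-open convention).  Each
    merged interval's ``name`` records the constituent count as
    ``n=<k>`` and its score is the sum of constituent scores (when any
    constituent carries one).
    """
    if gap < 0:
        raise ValidationError(f"gap must be >= 0, got {gap}")
    merged: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    count = 0
    score_sum: float | None = None
    for iv in a:
        if cur is not None and iv.chrom == cur.chrom and iv.start - cur.end <= gap:
            count += 1
            if iv.score is not None:
                score_sum = (score_sum or 0.0) + iv.score
            if iv.end > cur.end:
                cur = replace(cur, end=iv.end, summit=None)
        else:
            if cur is not None:
                merged.append(replace(cur, name=f"n={count}", score=score_sum))
            cur = replace(iv, name=None)
            count = 1
            score_sum = iv.score
    if cur is not None:
        merged.append(replace(cur, name=f"n={count}", score=score_sum))
    return PeakSet(merged, label=a.label, merged=True)


def subtract_blacklist(a: PeakSet, blacklist: PeakSet) -> PeakSet:
    """Drop every interval of *a* overlapping the blacklist (>=1 bp)."""
    _, kept = intersect_sets(a, blacklist)
    return kept


def intersection_regions(a: PeakSet, b: PeakSet) -> PeakSet:
    """Regions covered by BOTH sets (coverage intersection), merged."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    out: list[GenomicInterval] = []
    for iv in ma:
        for hit in sorted(mb._tree(iv.chrom).overlap(iv.start, iv.end)):
            s, e = max(iv.start, hit.begin), min(iv.end, hit.end)
            if s < e:
                out.append(GenomicInterval(iv.chrom, s, e))
    return PeakSet(out, label=f"{a.label}&{b.label}", merged=True)


# ---------------------------------------------------------------------------
# Proximity
# ---------------------------------------------------------------------------

def _edge_distance(start: int, end: int, tss: int) -> int:
    """bp distance from the closest interval edge of ``[start,end)`` to *tss*.

    Zero when the TSS lies inside the interval.
    """
    if tss < start:
        return start - tss
    if tss >= end:
        return tss - end
    return 0


def nearest_feature(
    query: GenomicInterval, genes: GeneAnnotation, window: int
) -> str | None:
    """Gene whose TSS is closest to *query*; ``None`` beyond *window* bp.

    Ties break by smaller distance then lexicographically smaller gene id
    (deterministic).
    """
    gid_dist = nearest_tss_distance(query, genes)
    if gid_dist is None:
        return None
    gid, dist = gid_dist
    return gid if dist <= window else None


def nearest_tss_distance(
    query: GenomicInterval, genes: GeneAnnotation
) -> tuple[str, int] | None:
    """``(gene_id, edge_distance)`` for the nearest TSS, or ``None``."""
    tss, gids = genes.tss_on(query.chrom)
    if not tss:
        return None
    best: tuple[int, str] | None = None
    # candidates: TSSs bracketing the interval plus any inside it
    lo = bisect_left(tss, query.start)
    hi = bisect_left(tss, query.end)
    first = max(0, lo - 1)
    # genes sharing the left-bracket TSS position sit at earlier indices;
    # include them so the lexicographic tie-break sees every candidate
    while first > 0 and tss[first - 1] == tss[first]:
        first -= 1
    for j in range(first, min(len(tss), hi + 1)):
        d = _edge_distance(query.start, query.end, tss[j])
        cand = (d, gids[j])
        if best is None or cand < best:
            best = cand
    assert best is not None
    return best[1], best[0]
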