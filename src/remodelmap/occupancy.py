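"""SWI/SNF-family complex target definitions and condition partitions.

A complex "target" is a locus where every required subunit's ChIP peaks
co-occur.  Targets are anchored on BRG1 (the shared ATPase): a BRG1 peak
is a target of a complex iff every required subunit peak set overlaps it
by at least 1 bp.  Reported intervals are the anchoring BRG1 peak
boundaries, merged where they overlap or touch.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .genome import GenomicInterval, PeakSet, intersect_sets, merge_intervals
from .genome import ValidationError
from .diffbind import DifferentialRegion

__all__ = [
    "ComplexName",
    "COMPLEX_DEFINITIONS",
    "ConditionStatus",
    "OccupancyCall",
    "complex_targets",
    "condition_partition",
    "top_decile_overlap",
    "brd9_partition",
]


class ComplexName(str, Enum):
    SWI_SNF = "SWI_SNF"
    PBAF = "PBAF"
    NCBAF = "ncBAF"


#: Required subunits per complex family: the shared core plus the
#: signature subunits that distinguish canonical BAF (SS18), PBAF
#: (BAF180/ARID2/BRD7) and non-canonical BAF (BRD9).
COMPLEX_DEFINITIONS: dict[ComplexName, tuple[str, ...]] = {
    ComplexName.SWI_SNF: ("BRG1", "BAF155", "BAF170", "SS18"),
    ComplexName.PBAF: ("BRG1", "BAF155", "BAF170", "BAF180", "ARID2", "BRD7"),
    ComplexName.NCBAF: ("BRG1", "BAF155", "BRD9"),
}

ANCHOR_SUBUNIT = "BRG1"


class ConditionStatus(str, Enum):
    GAINED = "gained"
    COMMON = "common"
    MOCK_SPECIFIC = "mock_specific"


@dataclass(frozen=True)
class OccupancyCall:
    interval: GenomicInterval
    complex_name: ComplexName
    condition_status: ConditionStatus


class ConfigurationError(ValidationError):
    pass


def complex_targets(
    subunit_peaks: Mapping[str, PeakSet],
    definition: ComplexName | Sequence[str],
) -> PeakSet:
    """Genomic targets of a complex from its subunit peak sets.

    *definition* is a :class:`ComplexName` or an explicit subunit list.
    """
    if isinstance(definition, ComplexName):
        required = COMPLEX_DEFINITIONS[definition]
        label = definition.value
    else:
        required = tuple(definition)
        label = "+".join(required)
    missing = [s for s in required if s not in subunit_peaks]
    if missing:
        raise ConfigurationError(f"missing subunit peak set(s): {missing}")
    anchor = subunit_peaks.get(ANCHOR_SUBUNIT)
    if anchor is None:
        raise ConfigurationError(f"missing anchor subunit {ANCHOR_SUBUNIT!r}")
    current = PeakSet(list(anchor), label=label)
    for sub in required:
        if sub == ANCHOR_SUBUNIT:
            continue
        current, _ = intersect_sets(current, subunit_peaks[sub])
    return merge_intervals(current, gap=0)


def condition_partition(
    targets_mock: PeakSet, targets_dox: PeakSet,
    complex_name: ComplexName = ComplexName.SWI_SNF,
) -> list[OccupancyCall]:
    """Partition targets between conditions.

    Dox targets not overlapping any mock target are *gained*; mock
    targets not overlapping any dox target are *mock-specific*;
    overlapping pairs are *common*, reported once as the dox interval.
    """
    common_dox, gained = intersect_sets(targets_dox, targets_mock)
    _, mock_only = intersect_sets(targets_mock, targets_dox)
    calls = [
        OccupancyCall(iv, complex_name, ConditionStatus.GAINED) for iv in gained
    ]
    calls += [
        OccupancyCall(iv, complex_name, ConditionStatus.COMMON) for iv in common_dox
    ]
    calls += [
        OccupancyCall(iv, complex_name, ConditionStatus.MOCK_SPECIFIC)
        for iv in mock_only
    ]
    return calls


def top_decile_overlap(
    activated: Sequence[DifferentialRegion],
    gained_targets: PeakSet,
    fraction: float = 0.10,
) -> float:
    """Fraction of the top-*fraction* activated regions (by llr) carrying
    at least one gained complex target.

    Ranking is by descending llr, ties broken by genomic order.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    activated = list(activated)
    if not activated:
        raise ValidationError("empty activated region set")
    ranked = sorted(
        activated,
        key=lambda r: (-r.llr, r.interval.chrom, r.interval.start),
    )
    k = max(1, int(len(ranked) * fraction))
    top = ranked[:k]
    hit = sum(1 for r in top if gained_targets.overlaps(r.interval))
    return hit / k


def brd9_partition(
    brd9: PeakSet, brg1: PeakSet, k4me3: PeakSet, baf180: PeakSet
) -> list[dict]:
    """Split BRD9 peaks by BRG1 co-binding and profile each subset.

    Returns one record per subset (``BRD9_BRG1`` and ``BRD9_only``) with
    its size and the fractions overlapping H3K4me3 (promoter proxy) and
    BAF180 (PBAF co-localization).  Fractions are also rounded to two
    decimals alongside the raw counts.
    """
    co, only = intersect_sets(brd9, brg1)
    records = []
    for name, subset in (("BRD9_BRG1", co), ("BRD9_only", only)):
        n = len(subset)
        k4_hits = len(intersect_sets(subset, k4me3)[0]) if n else 0
        baf_hits = len(intersect_sets(subset, baf180)[0]) if n else 0
        records.append(
            {
                "subset": name,
                "n": n,
                "k4me3_n": k4_hits,
                "baf180_n": baf_hits,
                "promoter_fraction": k4_hits / n if n else 0.0,
                "baf180_fraction": baf_hits / n if n else 0.0,
                "promoter_fraction_2dp": round(k4_hits / n, 2) if n else 0.0,
                "baf180_fraction_2dp": round(baf_hits / n, 2) if n else 0.0,
            }
        )
    return records
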