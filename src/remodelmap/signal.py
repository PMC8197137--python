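"""Piecewise-constant per-base coverage tracks (bedGraph semantics).

A :class:`SignalTrack` stores sorted, non-overlapping runs per chromosome;
gaps between runs carry implicit coverage 0.  All aggregation goes through
a prefix-integral so window means are exact regardless of how runs align
with query windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .genome import ValidationError

__all__ = ["SignalTrack", "parse_bedgraph", "write_bedgraph"]


@dataclass
class _ChromRuns:
    starts: np.ndarray  # int64, sorted
    ends: np.ndarray
    values: np.ndarray  # float64, >= 0
    cum: np.ndarray = field(init=False)  # cum[i] = integral over runs [0, i)

    def __post_init__(self) -> None:
        areas = self.values * (self.ends - self.starts)
        self.cum = np.concatenate(([0.0], np.cumsum(areas)))

    def integral_at(self, pos: np.ndarray) -> np.ndarray:
        """Integral of coverage over ``[0, pos)`` for each position."""
        pos = np.asarray(pos, dtype=np.int64)
        i = np.searchsorted(self.ends, pos, side="right")
        out = np.empty(pos.shape, dtype=np.float64)
        last = i >= len(self.starts)
        out[last] = self.cum[-1]
        j = i[~last]
        p = pos[~last]
        inside = p >= self.starts[j]
        partial = np.where(
            inside, self.values[j] * (p - self.starts[j]), 0.0
        )
        out[~last] = self.cum[j] + partial
        return out


class SignalTrack:
    """Genome-wide coverage as sorted non-overlapping (start, end, value) runs."""

    def __init__(
        self,
        runs: Iterable[tuple[str, int, int, float]],
        genome: Mapping[str, int],
    ) -> None:
        self.genome: dict[str, int] = dict(genome)
        per: dict[str, list[tuple[int, int, float]]] = {c: [] for c in self.genome}
        for chrom, start, end, value in runs:
            if chrom not in self.genome:
                raise ValidationError(f"run on unknown chromosome {chrom!r}")
            if value < 0:
                raise ValidationError(f"negative coverage {value} at {chrom}:{start}")
            if start >= end:
                raise ValidationError(f"empty run {chrom}:{start}-{end}")
            if end > self.genome[chrom]:
                raise ValidationError(
                    f"run {chrom}:{start}-{end} beyond chromosome length "
                    f"{self.genome[chrom]}"
                )
            per[chrom].append((start, end, value))
        self._chroms: dict[str, _ChromRuns] = {}
        for chrom, lst in per.items():
            lst.sort()
            for (s1, e1, _), (s2, _, _) in zip(lst, lst[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"overlapping runs on {chrom}: [{s1},{e1}) and start {s2}"
                    )
            if lst:
                arr = np.array(lst, dtype=np.float64)
                self._chroms[chrom] = _ChromRuns(
                    arr[:, 0].astype(np.int64),
                    arr[:, 1].astype(np.int64),
                    arr[:, 2],
                )

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_bin_values(
        cls, per_chrom_bins: Mapping[str, np.ndarray], bin_size: int,
        genome: Mapping[str, int],
    ) -> "SignalTrack":
        """Build a track from dense per-bin values (last bin may be short)."""
        runs: list[tuple[str, int, int, float]] = []
        for chrom, vals in per_chrom_bins.items():
            length = genome[chrom]
            for i, v in enumerate(vals):
                if v > 0:
                    runs.append(
                        (chrom, i * bin_size, min((i + 1) * bin_size, length), float(v))
                    )
        return cls(runs, genome)

    # -- queries ---------------------------------------------------------------

    def total_signal(self) -> float:
        """Integral of coverage over the whole genome."""
        return float(sum(cr.cum[-1] for cr in self._chroms.values()))

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Integral of coverage over ``[start, end)`` (clamped to bounds)."""
        if chrom not in self.genome:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        cr = self._chroms.get(chrom)
        if cr is None:
            return 0.0
        length = self.genome[chrom]
        a, b = max(0, start), min(length, end)
        if a >= b:
            return 0.0
        vals = cr.integral_at(np.array([a, b]))
        return float(vals[1] - vals[0])

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean coverage over ``[start, end)`` within chromosome bounds."""
        length = self.genome.get(chrom)
        if length is None:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        a, b = max(0, start), min(length, end)
        if a >= b:
            return 0.0
        return self.integral(chrom, a, b) / (b - a)

    def binned_means(self, bin_size: int) -> dict[str, np.ndarray]:
        """Mean coverage per fixed-width bin for every chromosome."""
        if bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        out: dict[str, np.ndarray] = {}
        for chrom, length in self.genome.items():
            edges = np.arange(0, length + bin_size, bin_size, dtype=np.int64)
            edges[-1] = min(edges[-1], length)
            if edges[-1] == edges[-2]:
                edges = edges[:-1]
            cr = self._chroms.get(chrom)
            if cr is None:
                out[chrom] = np.zeros(len(edges) - 1)
                continue
            cum = cr.integral_at(edges)
            widths = np.diff(edges).astype(np.float64)
            out[chrom] = np.diff(cum) / widths
        return out

    def value_quantile(self, q: float) -> float:
        """Per-base coverage quantile, counting implicit-zero gaps."""
        pieces: list[tuple[float, int]] = []
        for chrom, length in self.genome.items():
            cr = self._chroms.get(chrom)
            covered = 0
            if cr is not None:
                for s, e, v in zip(cr.starts, cr.ends, cr.values):
                    pieces.append((float(v), int(e - s)))
                    covered += int(e - s)
            if length - covered > 0:
                pieces.append((0.0, length - covered))
        pieces.sort()
        total = sum(w for _, w in pieces)
        target = q * total
        acc = 0
        for v, w in pieces:
            acc += w
            if acc >= target:
                return v
        return pieces[-1][0] if pieces else 0.0

    def median_coverage(self) -> float:
        return self.value_quantile(0.5)

    def runs(self) -> list[tuple[str, int, int, float]]:
        out = []
        for chrom in sorted(self._chroms):
            cr = self._chroms[chrom]
            for s, e, v in zip(cr.starts, cr.ends, cr.values):
                out.append((chrom, int(s), int(e), float(v)))
        return out


def parse_bedgraph(path: str | Path, genome: Mapping[str, int]) -> SignalTrack:
    """Read a 4-column bedGraph; gaps are implicit zero coverage."""
    path = Path(path)
    runs: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 columns")
            try:
                runs.append((cols[0], int(cols[1]), int(cols[2]), float(cols[3])))
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    try:
        return SignalTrack(runs, genome)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.runs():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
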