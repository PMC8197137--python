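"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator is a pure function of :class:`SimConfig` (seed included):
a master seed derives per-generator child seeds by fixed offsets, so
adding a generator never perturbs existing outputs.  The generators
emulate the statistical structure of the real inputs — Poisson coverage
tracks with spiked differential windows, histone-mark and SWI/SNF-subunit
peak sets with configurable co-occupancy, a DESeq2-style differential
expression table with planted enhancer-linked genes, per-tissue enhancer
marks, and a 27k-style methylation array with planted tumor- and
normal-methylated probe sets whose genes are suppressed in the matching
expression libraries.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, GenomicInterval, PeakSet, ValidationError
from .signal import SignalTrack
from .methylation import MethylationDataset
from .diffbind import DifferentialRegion, Direction

__all__ = [
    "SimConfig",
    "GroundTruth",
    "gen_tracks",
    "gen_mark_and_subunit_peaks",
    "gen_expression_and_de",
    "gen_methylation",
    "score_recovery",
]

# fixed child-seed offsets, one per generator
_SEED_TRACKS = 11
_SEED_MARKS = 22
_SEED_EXPR = 33
_SEED_METH = 44

TISSUES = (
    "kidney", "adrenal", "brain", "breast", "heart",
    "liver", "lung", "ovary", "placenta", "skeletal_muscle",
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Track/peak scale is a desk-scale rendition of a genome-wide ChIP
    experiment (two chromosomes, 10 Mb); the methylation arm keeps the
    27k-array scale with 523/642 planted probe classes, three array
    replicates per group and six RNA libraries per group.
    """

    seed: int = 0
    genome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 6_000_000, "chr2": 4_000_000}
    )
    bin_size: int = 200
    window_size: int = 1_000
    n_gained: int = 150
    n_lost: int = 60
    n_common: int = 60
    rate_background: float = 10.0
    rate_ratio: float = 8.0
    # chromatin-state structure
    frac_promoter: float = 2303 / 20050
    n_decoy_marks: int = 100
    # genes / differential expression (ChIP arm)
    n_genes: int = 600
    n_up: int = 120
    n_down: int = 33
    frac_up_assoc: float = 694 / 1175
    frac_down_assoc: float = 58 / 159
    de_effect_scale: float = 0.8  # exponential tail above the 0.5 cut
    # complex co-occupancy
    p_true: float = 0.95
    p_false: float = 0.02
    n_decoys: int = 400
    n_extra_targets: int = 60
    n_brd9_only: int = 50
    frac_targets_on_activated: float = 0.54
    subunit_peak_width: int = 600
    # tissue-specific enhancers
    tissues: tuple[str, ...] = TISSUES
    focal_tissue: str = "brain"
    n_tissue_elements: int = 120
    n_focal_overlap: int = 30
    # methylation arm
    n_probes: int = 27_578
    n_tumor_meth: int = 523
    n_normal_meth: int = 642
    meth_margin: float = 1.0
    meth_rep_sd: float = 0.3
    n_meth_reps: int = 3
    base_intensity: float = 1_000.0
    # expression arm (MRTK vs NK libraries)
    n_meth_genes: int = 5_000
    n_rna_per_group: int = 6
    rna_mean_log: float = 4.0
    rna_sd_log: float = 1.0
    meth_suppression_fold: float = 2.0

    def __post_init__(self) -> None:
        if self.rate_ratio <= 1:
            raise ValidationError("rate_ratio must be > 1")
        for name in ("n_gained", "n_lost", "n_common", "n_genes", "n_probes"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("p_true", "p_false"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.n_tumor_meth + self.n_normal_meth > self.n_probes:
            raise ValidationError("planted probe classes exceed n_probes")
        if self.focal_tissue not in self.tissues:
            raise ValidationError(f"focal tissue {self.focal_tissue!r} not in tissues")


def _ivl(t: tuple) -> list:
    return [t[0], int(t[1]), int(t[2])]


@dataclass
class GroundTruth:
    """Planted truth serialized alongside the synthetic outputs."""

    gained_windows: list = field(default_factory=list)
    lost_windows: list = field(default_factory=list)
    common_windows: list = field(default_factory=list)
    promoter_elements: list = field(default_factory=list)
    enhancer_elements: list = field(default_factory=list)
    complex_truth: dict = field(default_factory=dict)  # condition -> complex -> loci
    targets_on_activated: list = field(default_factory=list)
    brd9_only_loci: list = field(default_factory=list)
    tissue_truth: dict = field(default_factory=dict)
    focal_overlap_windows: list = field(default_factory=list)
    chip_genes: list = field(default_factory=list)  # [gid, chrom, tss]
    linked_up_genes: list = field(default_factory=list)
    linked_down_genes: list = field(default_factory=list)
    nonassoc_up_genes: list = field(default_factory=list)
    nonassoc_down_genes: list = field(default_factory=list)
    meth_genes: list = field(default_factory=list)
    tumor_meth_probes: list = field(default_factory=list)
    normal_meth_probes: list = field(default_factory=list)
    tumor_meth_genes: list = field(default_factory=list)
    normal_meth_genes: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def chip_gene_annotation(self) -> GeneAnnotation:
        return GeneAnnotation.from_records(
            [(g, c, t) for g, c, t in self.chip_genes]
        )

    def meth_gene_annotation(self) -> GeneAnnotation:
        return GeneAnnotation.from_records(
            [(g, c, t) for g, c, t in self.meth_genes]
        )


class _Placer:
    """Rejection-samples non-overlapping windows on a genome."""

    def __init__(self, genome: Mapping[str, int], rng: np.random.Generator,
                 buffer: int = 2_000) -> None:
        self.genome = dict(genome)
        self.rng = rng
        self.buffer = buffer
        self._occupied: dict[str, list[tuple[int, int]]] = {
            c: [] for c in self.genome
        }
        chroms = sorted(self.genome)
        lens = np.array([self.genome[c] for c in chroms], dtype=np.float64)
        self._chroms = chroms
        self._weights = lens / lens.sum()

    def is_free(self, chrom: str, start: int, end: int, buffer: int | None = None) -> bool:
        buf = self.buffer if buffer is None else buffer
        occ = self._occupied[chrom]
        i = bisect_left(occ, (start, start))
        for j in (i - 1, i):
            if 0 <= j < len(occ):
                s, e = occ[j]
                if start - buf < e and s < end + buf:
                    return False
        return True

    def register(self, chrom: str, start: int, end: int) -> None:
        insort(self._occupied[chrom], (start, end))

    def place(self, width: int, align: int = 1, max_tries: int = 10_000
              ) -> tuple[str, int, int]:
        for _ in range(max_tries):
            chrom = self._chroms[self.rng.choice(len(self._chroms), p=self._weights)]
            hi = (self.genome[chrom] - width) // align
            if hi <= 0:
                continue
            start = int(self.rng.integers(0, hi)) * align
            if self.is_free(chrom, start, start + width):
                self.register(chrom, start, start + width)
                return chrom, start, start + width
        raise ValidationError(
            "could not place a window: planted windows exceed genome capacity"
        )


def _window_peaks(windows: list, label: str, pad: int = 0) -> PeakSet:
    ivs = [
        GenomicInterval(c, max(0, s - pad), e + pad,
                        summit=(s + e) // 2)
        for c, s, e in windows
    ]
    return PeakSet(ivs, label=label)


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

def gen_tracks(
    cfg: SimConfig, truth: GroundTruth | None = None
) -> tuple[SignalTrack, SignalTrack, GroundTruth]:
    """Poisson mock/dox coverage tracks with spiked differential windows.

    Background bins draw Poisson(rate_background) in both conditions; at
    gained windows the dox rate is ``rate_ratio x`` background, at lost
    windows the mock rate is, and at common windows both are.
    """
    truth = truth or GroundTruth()
    rng = np.random.default_rng(cfg.seed + _SEED_TRACKS)
    placer = _Placer(cfg.genome, rng, buffer=4 * cfg.bin_size)

    windows: dict[str, list] = {"gained": [], "lost": [], "common": []}
    for kind, n in (("gained", cfg.n_gained), ("lost", cfg.n_lost),
                    ("common", cfg.n_common)):
        for _ in range(n):
            c, s, e = placer.place(cfg.window_size, align=cfg.bin_size)
            windows[kind].append([c, s, e])
    truth.gained_windows = windows["gained"]
    truth.lost_windows = windows["lost"]
    truth.common_windows = windows["common"]

    rate_mock: dict[str, np.ndarray] = {}
    rate_dox: dict[str, np.ndarray] = {}
    for chrom, length in cfg.genome.items():
        nbins = math.ceil(length / cfg.bin_size)
        rate_mock[chrom] = np.full(nbins, cfg.rate_background)
        rate_dox[chrom] = np.full(nbins, cfg.rate_background)
    spike = cfg.rate_background * cfg.rate_ratio
    for c, s, e in truth.gained_windows:
        rate_dox[c][s // cfg.bin_size : math.ceil(e / cfg.bin_size)] = spike
    for c, s, e in truth.lost_windows:
        rate_mock[c][s // cfg.bin_size : math.ceil(e / cfg.bin_size)] = spike
    for c, s, e in truth.common_windows:
        rate_dox[c][s // cfg.bin_size : math.ceil(e / cfg.bin_size)] = spike
        rate_mock[c][s // cfg.bin_size : math.ceil(e / cfg.bin_size)] = spike

    bins_mock = {c: rng.poisson(r).astype(float) for c, r in rate_mock.items()}
    bins_dox = {c: rng.poisson(r).astype(float) for c, r in rate_dox.items()}
    track_mock = SignalTrack.from_bin_values(bins_mock, cfg.bin_size, cfg.genome)
    track_dox = SignalTrack.from_bin_values(bins_dox, cfg.bin_size, cfg.genome)
    return track_mock, track_dox, truth


# ---------------------------------------------------------------------------
# Marks, subunits, tissue enhancers
# ---------------------------------------------------------------------------

def gen_mark_and_subunit_peaks(
    cfg: SimConfig, truth: GroundTruth
) -> dict[str, PeakSet]:
    """Histone-mark, SWI/SNF-subunit and per-tissue enhancer peak sets.

    Returns a flat label → PeakSet mapping.  Conditions are suffixed
    (``BRG1_dox``), tissue marks are ``tissue:<name>:<mark>``.  Histone
    marks for state classification (``H3K4me3``/``H3K4me1``) reflect the
    dox condition.
    """
    rng = np.random.default_rng(cfg.seed + _SEED_MARKS)
    placer = _Placer(cfg.genome, rng, buffer=2_000)
    for lst in (truth.gained_windows, truth.lost_windows, truth.common_windows):
        for c, s, e in lst:
            placer.register(c, s, e)

    # element states for the gained windows
    n_prom = int(round(cfg.frac_promoter * len(truth.gained_windows)))
    order = rng.permutation(len(truth.gained_windows))
    prom_idx = set(order[:n_prom].tolist())
    truth.promoter_elements = [
        w for i, w in enumerate(truth.gained_windows) if i in prom_idx
    ]
    truth.enhancer_elements = [
        w for i, w in enumerate(truth.gained_windows) if i not in prom_idx
    ]

    out: dict[str, PeakSet] = {}
    out["H3K27ac_dox"] = _window_peaks(
        truth.gained_windows + truth.common_windows, "H3K27ac_dox"
    )
    out["H3K27ac_mock"] = _window_peaks(
        truth.lost_windows + truth.common_windows, "H3K27ac_mock"
    )

    decoy_me3 = [list(placer.place(800)) for _ in range(cfg.n_decoy_marks)]
    decoy_me1 = [list(placer.place(800)) for _ in range(cfg.n_decoy_marks)]
    out["H3K4me3"] = _window_peaks(truth.promoter_elements + decoy_me3,
                                   "H3K4me3", pad=200)
    out["H3K4me1"] = _window_peaks(truth.enhancer_elements + decoy_me1,
                                   "H3K4me1", pad=200)

    # complex-target truth loci per condition
    truth.complex_truth = {"mock": {}, "dox": {}}
    activated = [list(w) for w in truth.gained_windows]
    n_on = int(round(cfg.frac_targets_on_activated * len(activated)))
    on_idx = rng.choice(len(activated), size=n_on, replace=False)
    swi_dox = [activated[i] for i in sorted(on_idx)]
    truth.targets_on_activated = swi_dox
    extras = lambda n: [list(placer.place(cfg.subunit_peak_width)) for _ in range(n)]
    truth.complex_truth["dox"] = {
        "SWI_SNF": swi_dox + extras(cfg.n_extra_targets),
        "PBAF": extras(cfg.n_extra_targets),
        "ncBAF": extras(cfg.n_extra_targets),
    }
    mock_pool = [list(w) for w in truth.lost_windows + truth.common_windows]
    n_mock = min(len(mock_pool), cfg.n_extra_targets)
    pick = rng.choice(len(mock_pool), size=n_mock, replace=False)
    truth.complex_truth["mock"] = {
        "SWI_SNF": [mock_pool[i] for i in sorted(pick)] + extras(cfg.n_extra_targets // 2),
        "PBAF": extras(cfg.n_extra_targets),
        "ncBAF": extras(cfg.n_extra_targets),
    }
    truth.brd9_only_loci = extras(cfg.n_brd9_only)

    decoy_loci = extras(cfg.n_decoys)
    membership = {
        "BRG1": ("SWI_SNF", "PBAF", "ncBAF"),
        "BAF155": ("SWI_SNF", "PBAF", "ncBAF"),
        "BAF170": ("SWI_SNF", "PBAF"),
        "SS18": ("SWI_SNF",),
        "BAF180": ("PBAF",),
        "ARID2": ("PBAF",),
        "BRD7": ("PBAF",),
        "BRD9": ("ncBAF",),
    }
    w = cfg.subunit_peak_width
    for cond in ("mock", "dox"):
        loci_of = truth.complex_truth[cond]
        for subunit, complexes in membership.items():
            ivs = []
            for cx in complexes:
                for c, s, e in loci_of[cx]:
                    if rng.random() < cfg.p_true:
                        mid = (s + e) // 2
                        ivs.append(GenomicInterval(c, max(0, mid - w // 2),
                                                   mid + w // 2, summit=mid))
            if subunit == "BRD9" and cond == "mock":
                for c, s, e in truth.brd9_only_loci:
                    mid = (s + e) // 2
                    ivs.append(GenomicInterval(c, max(0, mid - w // 2),
                                               mid + w // 2, summit=mid))
            for c, s, e in decoy_loci:
                if rng.random() < cfg.p_false:
                    ivs.append(GenomicInterval(c, s, e))
            out[f"{subunit}_{cond}"] = PeakSet(ivs, label=f"{subunit}_{cond}")

    # per-tissue enhancer marks; placer keeps tissue loci mutually disjoint
    truth.tissue_truth = {}
    enh_pool = [w for w in truth.enhancer_elements]
    n_focal = min(cfg.n_focal_overlap, len(enh_pool))
    focal_pick = rng.choice(len(enh_pool), size=n_focal, replace=False)
    truth.focal_overlap_windows = [enh_pool[i] for i in sorted(focal_pick)]
    for tissue in cfg.tissues:
        if tissue == cfg.focal_tissue:
            loci = [list(w) for w in truth.focal_overlap_windows]
            loci += extras(max(0, cfg.n_tissue_elements - n_focal))
        else:
            loci = extras(cfg.n_tissue_elements)
        truth.tissue_truth[tissue] = loci
        out[f"tissue:{tissue}:H3K27ac"] = _window_peaks(
            loci, f"{tissue}_H3K27ac", pad=100
        )
        out[f"tissue:{tissue}:H3K4me1"] = _window_peaks(
            loci, f"{tissue}_H3K4me1", pad=100
        )
    return out


def tissue_marks_from_labels(
    peaks: Mapping[str, PeakSet]
) -> dict[str, dict[str, PeakSet]]:
    """Regroup ``tissue:<name>:<mark>`` labels into a nested mapping."""
    nested: dict[str, dict[str, PeakSet]] = {}
    for label, ps in peaks.items():
        if label.startswith("tissue:"):
            _, tissue, mark = label.split(":")
            nested.setdefault(tissue, {})[mark] = ps
    return nested


# ---------------------------------------------------------------------------
# Expression / DE
# ---------------------------------------------------------------------------

def gen_expression_and_de(
    cfg: SimConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """RNA count matrix (MRTK/NK libraries) and a dox-vs-mock DE table.

    DE genes planted as enhancer-linked have their TSS inside a planted
    gained enhancer window (so the nearest-gene rule must recover the
    link); non-linked DE genes are kept >110 kb from every planted
    window.  The count matrix covers the methylation-arm gene universe,
    with tumor-methylated genes suppressed ``meth_suppression_fold``-fold
    in the MRTK libraries (Poisson-lognormal noise).
    """
    rng = np.random.default_rng(cfg.seed + _SEED_EXPR)

    # --- ChIP-arm gene annotation + DE table -------------------------------
    enh = [list(w) for w in truth.enhancer_elements]
    n_up_assoc = int(round(cfg.frac_up_assoc * cfg.n_up))
    n_down_assoc = int(round(cfg.frac_down_assoc * cfg.n_down))
    if n_up_assoc + n_down_assoc > len(enh):
        raise ValidationError(
            "not enough planted enhancer windows to host the linked DE genes"
        )
    slots = rng.permutation(len(enh))
    genes: list[tuple[str, str, int]] = []
    gid = 0

    def new_gene(chrom: str, tss: int) -> str:
        nonlocal gid
        name = f"G{gid:05d}"
        gid += 1
        genes.append((name, chrom, tss))
        return name

    def inside(window: list) -> tuple[str, int]:
        c, s, e = window
        return c, int(rng.integers(s + 100, e - 100))

    # every gained window hosts exactly one resident gene at TSS distance 0:
    # linked DE genes occupy their enhancer windows, bystander genes the rest.
    # A resident always wins the nearest-gene rule, so a gene placed outside
    # the windows can never be spuriously associated.
    linked_up = [new_gene(*inside(enh[slots[i]])) for i in range(n_up_assoc)]
    linked_down = [
        new_gene(*inside(enh[slots[n_up_assoc + i]])) for i in range(n_down_assoc)
    ]
    for i in range(n_up_assoc + n_down_assoc, len(enh)):
        new_gene(*inside(enh[slots[i]]))
    for w in truth.promoter_elements:
        new_gene(*inside(w))

    gained_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in truth.gained_windows:
        gained_by_chrom.setdefault(c, []).append((s, e))
    for c in gained_by_chrom:
        gained_by_chrom[c].sort()

    def outside_gained(chrom: str, pos: int, margin: int = 1_000) -> bool:
        wins = gained_by_chrom.get(chrom, [])
        i = bisect_left(wins, (pos, pos))
        for j in (i - 1, i):
            if 0 <= j < len(wins):
                s, e = wins[j]
                if s - margin < pos < e + margin:
                    return False
        return True

    chroms = sorted(cfg.genome)
    lens = np.array([cfg.genome[c] for c in chroms], dtype=np.float64)
    chrom_p = lens / lens.sum()

    def sample_pos() -> tuple[str, int]:
        while True:
            c = chroms[rng.choice(len(chroms), p=chrom_p)]
            pos = int(rng.integers(0, cfg.genome[c]))
            if outside_gained(c, pos):
                return c, pos

    nonassoc_up = [new_gene(*sample_pos())
                   for _ in range(cfg.n_up - n_up_assoc)]
    nonassoc_down = [new_gene(*sample_pos())
                     for _ in range(cfg.n_down - n_down_assoc)]
    n_null = cfg.n_genes - len(genes)
    if n_null < 0:
        raise ValidationError("n_genes too small for the planted DE structure")
    for _ in range(n_null):
        new_gene(*sample_pos())

    truth.chip_genes = [[g, c, t] for g, c, t in genes]
    truth.linked_up_genes = linked_up
    truth.linked_down_genes = linked_down
    truth.nonassoc_up_genes = nonassoc_up
    truth.nonassoc_down_genes = nonassoc_down

    records = []
    up_set = set(linked_up + nonassoc_up)
    down_set = set(linked_down + nonassoc_down)
    for name, _, _ in genes:
        if name in up_set:
            fc = 0.6 + rng.exponential(cfg.de_effect_scale)
            padj = 10.0 ** (-rng.uniform(2, 8))
        elif name in down_set:
            fc = -(0.6 + rng.exponential(cfg.de_effect_scale))
            padj = 10.0 ** (-rng.uniform(2, 8))
        else:
            fc = rng.normal(0, 0.2)
            padj = rng.uniform(0.05, 1.0)
        records.append({"gene_id": name, "log2fc": fc, "adj_p": padj})
    de_table = pd.DataFrame(records)

    # --- methylation-arm RNA count matrix -----------------------------------
    if not truth.meth_genes:
        _make_meth_genes(cfg, truth)
    meth_gene_ids = [g for g, _, _ in truth.meth_genes]
    suppressed = set(truth.tumor_meth_genes)
    base = rng.lognormal(cfg.rna_mean_log, cfg.rna_sd_log, len(meth_gene_ids))
    samples = [f"MRTK_{i+1}" for i in range(cfg.n_rna_per_group)] + [
        f"NK_{i+1}" for i in range(cfg.n_rna_per_group)
    ]
    groups = {s: ("MRTK" if s.startswith("MRTK") else "NK") for s in samples}
    lib_factor = rng.lognormal(0.0, 0.2, len(samples))
    counts = np.empty((len(meth_gene_ids), len(samples)))
    supp_mask = np.array([g in suppressed for g in meth_gene_ids])
    for j, s in enumerate(samples):
        mu = base * lib_factor[j]
        if groups[s] == "MRTK":
            mu = np.where(supp_mask, mu / cfg.meth_suppression_fold, mu)
        noisy = mu * rng.lognormal(0.0, 0.25, len(mu))
        counts[:, j] = rng.poisson(noisy)
    count_matrix = pd.DataFrame(counts, index=meth_gene_ids, columns=samples)
    return count_matrix, groups, de_table


def _make_meth_genes(cfg: SimConfig, truth: GroundTruth) -> None:
    """Grid-with-jitter gene annotation for the methylation/RNA arm."""
    rng = np.random.default_rng(cfg.seed + _SEED_METH)
    spacing = 10_000
    genes = []
    for i in range(cfg.n_meth_genes):
        chrom = f"k{i % 4 + 1}"
        tss = (i // 4) * spacing + int(rng.integers(1_000, 9_000))
        genes.append([f"M{i:05d}", chrom, tss])
    truth.meth_genes = genes


# ---------------------------------------------------------------------------
# Methylation array
# ---------------------------------------------------------------------------

def gen_methylation(cfg: SimConfig, truth: GroundTruth) -> MethylationDataset:
    """27k-style array with planted tumor-/normal-methylated probe sets.

    Planted tumor probes target group-mean M of ``1 + margin`` in MRTK
    and ``-margin`` in NK (mirrored for normal-methylated); background
    probes center at M = 0 in both groups.  Intensities are lognormal
    around ``base_intensity`` with per-replicate M-noise ``meth_rep_sd``.
    """
    rng = np.random.default_rng(cfg.seed + _SEED_METH + 1)
    if not truth.meth_genes:
        _make_meth_genes(cfg, truth)

    n = cfg.n_probes
    gene_idx = rng.permutation(len(truth.meth_genes))
    tumor_g = gene_idx[: cfg.n_tumor_meth]
    normal_g = gene_idx[cfg.n_tumor_meth : cfg.n_tumor_meth + cfg.n_normal_meth]

    probe_ids, chroms, poss = [], [], []
    m_mrtk_target = np.zeros(n)
    m_nk_target = np.zeros(n)
    hi = 1.0 + cfg.meth_margin
    lo = -cfg.meth_margin

    def add_probe(i: int, gene_row: list | None) -> None:
        probe_ids.append(f"cg{i:06d}")
        if gene_row is not None:
            _, c, t = gene_row
            chroms.append(c)
            poss.append(int(t + rng.integers(-2_000, 2_001)))
        else:
            row = truth.meth_genes[int(rng.integers(0, len(truth.meth_genes)))]
            chroms.append(row[1])
            poss.append(int(row[2] + rng.integers(-2_000, 2_001)))

    k = 0
    tumor_probe_ids, normal_probe_ids = [], []
    for gi in tumor_g:
        add_probe(k, truth.meth_genes[gi])
        m_mrtk_target[k], m_nk_target[k] = hi, lo
        tumor_probe_ids.append(probe_ids[-1])
        k += 1
    for gi in normal_g:
        add_probe(k, truth.meth_genes[gi])
        m_mrtk_target[k], m_nk_target[k] = lo, hi
        normal_probe_ids.append(probe_ids[-1])
        k += 1
    while k < n:
        add_probe(k, None)
        k += 1

    samples = [f"MRTK_r{i+1}" for i in range(cfg.n_meth_reps)] + [
        f"NK_r{i+1}" for i in range(cfg.n_meth_reps)
    ]
    groups = {s: ("MRTK" if s.startswith("MRTK") else "NK") for s in samples}
    base = rng.lognormal(math.log(cfg.base_intensity), 0.4, n)
    meth = {}
    unmeth = {}
    for s in samples:
        target = m_mrtk_target if groups[s] == "MRTK" else m_nk_target
        m = target + rng.normal(0.0, cfg.meth_rep_sd, n)
        meth[s] = base * np.power(2.0, m / 2.0)
        unmeth[s] = base * np.power(2.0, -m / 2.0)

    probes = pd.DataFrame({"probe_id": probe_ids, "chrom": chroms, "pos": poss})
    idx = pd.Index(probe_ids, name="probe_id")
    data = MethylationDataset(
        probes=probes,
        meth=pd.DataFrame(meth, index=idx),
        unmeth=pd.DataFrame(unmeth, index=idx),
        groups=groups,
    )
    truth.tumor_meth_probes = tumor_probe_ids
    truth.normal_meth_probes = normal_probe_ids
    truth.tumor_meth_genes = sorted(truth.meth_genes[i][0] for i in tumor_g)
    truth.normal_meth_genes = sorted(truth.meth_genes[i][0] for i in normal_g)
    return data


# ---------------------------------------------------------------------------
# Recovery scoring against the planted truth
# ---------------------------------------------------------------------------

def score_recovery(
    truth: GroundTruth, regions: list[DifferentialRegion]
) -> dict[str, float]:
    """Fraction of planted windows recovered with the correct direction.

    A planted gained window counts as recovered when a called gained
    region overlaps it; a direction swap is a planted window overlapped
    by a call of the opposite direction.
    """
    gained_calls = PeakSet(
        [r.interval for r in regions if r.direction is Direction.GAINED], "g"
    )
    lost_calls = PeakSet(
        [r.interval for r in regions
         if r.direction is Direction.CONDITION1_SPECIFIC], "l"
    )
    recovered = swaps = 0
    planted = [(w, "gained") for w in truth.gained_windows] + [
        (w, "lost") for w in truth.lost_windows
    ]
    for (c, s, e), kind in planted:
        iv = GenomicInterval(c, s, e)
        in_gained = gained_calls.overlaps(iv)
        in_lost = lost_calls.overlaps(iv)
        if (kind == "gained" and in_gained) or (kind == "lost" and in_lost):
            recovered += 1
        if (kind == "gained" and in_lost) or (kind == "lost" and in_gained):
            swaps += 1
    n = len(planted)
    return {
        "n_planted": n,
        "recovered": recovered,
        "recovery_fraction": recovered / n if n else float("nan"),
        "direction_swaps": swaps,
    }
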