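"""Methylation M-values, probe classification, and the expression contrast.

An M-value is the log2 ratio of methylated to unmethylated array signal,
``log2((meth + offset) / (unmeth + offset))`` with a default offset of 1
to guard zero intensities.  Replicates are merged by the arithmetic mean
per group; a probe is *tumor-methylated* when its merged M exceeds 1 in
the tumor group (MRTK) while staying below 0 in normal kidney (NK), and
*normal-methylated* under the mirrored rule.  Probes where both groups
exceed 1 are *both*; everything else is *neither*.

The expression arm filters genes at 0.5 counts per million, adds a
pseudocount of 4, normalizes libraries with median-of-ratios size
factors, and contrasts log10 normalized counts of a gene cohort between
groups with a two-sided rank-sum test, optionally against a seeded
random-gene control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, GenomicInterval, ValidationError
from .association import rank_sum_test

__all__ = [
    "MethylationDataset",
    "m_value",
    "merge_replicates",
    "classify_probes",
    "assign_probe_gene",
    "cpm_filter",
    "normalize_counts",
    "expression_contrast",
    "random_control_cohort",
]

CLASSES = ("tumor_methylated", "normal_methylated", "both", "neither")


@dataclass
class MethylationDataset:
    """Probe coordinates plus per-sample methylated/unmethylated intensities.

    ``probes`` has columns ``probe_id``, ``chrom``, ``pos``; ``meth`` and
    ``unmeth`` are probe x sample intensity frames sharing an index with
    ``probes['probe_id']``; ``groups`` maps each sample to MRTK or NK.
    """

    probes: pd.DataFrame
    meth: pd.DataFrame
    unmeth: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if list(self.meth.columns) != list(self.unmeth.columns):
            raise ValidationError("meth/unmeth sample columns differ")
        for s in self.meth.columns:
            if s not in self.groups:
                raise ValidationError(f"sample {s!r} has no group assignment")
            if self.groups[s] not in ("MRTK", "NK"):
                raise ValidationError(f"sample {s!r}: group must be MRTK or NK")
        if (self.meth.to_numpy() < 0).any() or (self.unmeth.to_numpy() < 0).any():
            raise ValidationError("negative array intensity")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.meth.columns if self.groups[s] == group]


def m_value(meth, unmeth, offset: float = 1.0):
    """log2 ratio of methylated to unmethylated signal (offset-guarded)."""
    meth = np.asarray(meth, dtype=np.float64)
    unmeth = np.asarray(unmeth, dtype=np.float64)
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise ValidationError("negative array intensity")
    out = np.log2((meth + offset) / (unmeth + offset))
    return float(out) if out.ndim == 0 else out


def merge_replicates(per_sample_m: Mapping[str, float],
                     group_samples: Sequence[str]) -> float:
    """Arithmetic mean of a group's per-sample M-values."""
    vals = [per_sample_m[s] for s in group_samples]
    if not vals:
        raise ValidationError("empty replicate group")
    return float(np.mean(vals))


def classify_probes(
    data: MethylationDataset,
    offset: float = 1.0,
    upper: float = 1.0,
    lower: float = 0.0,
) -> pd.DataFrame:
    """Per-probe merged M-values and tumor/normal methylation class.

    Thresholds are strict: tumor-methylated needs ``m_mrtk > upper`` and
    ``m_nk < lower``; normal-methylated is the mirror; ``both`` needs
    ``m > upper`` in both groups.  Class counts always sum to the probe
    count.
    """
    mrtk = data.samples_in("MRTK")
    nk = data.samples_in("NK")
    if not mrtk or not nk:
        raise ValidationError("both MRTK and NK groups must be represented")
    m = m_value(data.meth.to_numpy(), data.unmeth.to_numpy(), offset)
    m = pd.DataFrame(m, index=data.meth.index, columns=data.meth.columns)
    m_mrtk = m[mrtk].mean(axis=1).to_numpy()
    m_nk = m[nk].mean(axis=1).to_numpy()
    cls = np.full(len(m), "neither", dtype=object)
    cls[(m_mrtk > upper) & (m_nk > upper)] = "both"
    cls[(m_mrtk > upper) & (m_nk < lower)] = "tumor_methylated"
    cls[(m_nk > upper) & (m_mrtk < lower)] = "normal_methylated"
    return pd.DataFrame(
        {
            "probe_id": data.probes["probe_id"].to_numpy(),
            "m_mrtk": m_mrtk,
            "m_nk": m_nk,
            "class": cls,
        }
    )


def assign_probe_gene(
    chrom: str,
    pos: int,
    genes: GeneAnnotation,
    window: int | None = 5_000,
) -> str | None:
    """Nearest-TSS gene for a probe position, within ±window bp.

    ``window=None`` assigns the nearest gene with no distance limit.
    """
    if window is not None and window <= 0:
        raise ValidationError("window must be positive")
    probe = GenomicInterval(chrom, pos, pos + 1)
    from .genome import nearest_tss_distance

    hit = nearest_tss_distance(probe, genes)
    if hit is None:
        return None
    gid, dist = hit
    if window is not None and dist > window:
        return None
    return gid


def cpm_filter(
    counts: pd.DataFrame, min_cpm: float = 0.5, min_libraries: int = 1
) -> pd.DataFrame:
    """Keep genes with CPM >= min_cpm in at least min_libraries samples."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValidationError(f"zero-total librar(ies): {bad}")
    cpm = counts / totals * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_libraries
    return counts.loc[keep]


def normalize_counts(
    counts: pd.DataFrame, pseudocount: float = 4.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios library normalization after adding a pseudocount.

    Size factor of sample j = median over genes of
    ``x[i, j] / geometric_mean_i`` over genes whose geometric mean is
    positive.  Returns the normalized matrix and the factors.
    """
    x = counts.to_numpy(dtype=np.float64) + pseudocount
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    finite_rows = np.all(np.isfinite(logx), axis=1)
    if not finite_rows.any():
        raise ValidationError("no gene with all-positive entries after pseudocount")
    geo = np.exp(logx[finite_rows].mean(axis=1))
    factors = np.median(x[finite_rows] / geo[:, None], axis=0)
    normalized = pd.DataFrame(
        x / factors[None, :], index=counts.index, columns=counts.columns
    )
    return normalized, pd.Series(factors, index=counts.columns, name="size_factor")


def expression_contrast(
    normalized: pd.DataFrame,
    gene_cohort: Iterable[str],
    groups: Mapping[str, str],
) -> dict[str, float]:
    """Contrast log10 normalized expression of a cohort between groups.

    Pools per-gene group means of log10 normalized counts into one MRTK
    and one NK sample and applies the two-sided rank-sum test.
    """
    cohort = sorted(set(gene_cohort))
    if not cohort:
        raise ValidationError("empty gene cohort")
    missing = [g for g in cohort if g not in normalized.index]
    if missing:
        raise ValidationError(
            f"cohort gene(s) absent from the expression matrix: {missing[:10]}"
        )
    mrtk = [s for s in normalized.columns if groups[s] == "MRTK"]
    nk = [s for s in normalized.columns if groups[s] == "NK"]
    if not mrtk or not nk:
        raise ValidationError("both MRTK and NK groups must be represented")
    sub = np.log10(normalized.loc[cohort])
    a = sub[mrtk].mean(axis=1).to_numpy()
    b = sub[nk].mean(axis=1).to_numpy()
    return {
        "p_value": rank_sum_test(a, b),
        "median_log10_mrtk": float(np.median(a)),
        "median_log10_nk": float(np.median(b)),
        "n_genes": len(cohort),
    }


def random_control_cohort(
    normalized: pd.DataFrame,
    exclude: Iterable[str],
    k: int = 100,
    seed: int = 0,
) -> list[str]:
    """Seeded draw of *k* genes from the non-hypermethylated complement."""
    pool = sorted(set(normalized.index) - set(exclude))
    if len(pool) < k:
        raise ValidationError(
            f"complement has only {len(pool)} genes; cannot draw {k}"
        )
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(pool, size=k, replace=False).tolist())
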