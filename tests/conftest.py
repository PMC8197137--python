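import numpy as np
import pytest

from remodelmap import GeneAnnotation, GenomicInterval, PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(20210713)


def random_peakset(rng, n, chroms=("chr1", "chr2"), span=100_000, label="x"):
    """Random (possibly overlapping) intervals for oracle comparisons."""
    ivs = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, span - 1))
        end = start + int(rng.integers(1, 2_000))
        ivs.append(GenomicInterval(chrom, start, end))
    return PeakSet(ivs, label=label)


def random_genes(rng, n, chroms=("chr1", "chr2"), span=100_000):
    recs = []
    for i in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        recs.append((f"G{i:04d}", chrom, int(rng.integers(0, span))))
    return GeneAnnotation.from_records(recs)
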