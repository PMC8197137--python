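"""DE filtering, peak-gene association, enrichment and contrast statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from remodelmap import (
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    TissueEnhancerSet,
    ValidationError,
    associate_genes,
    fc_contrast,
    filter_de,
    hypergeom_enrichment,
    rank_sum_test,
    tissue_overlap_ranking,
    tissue_specific,
)

from conftest import random_genes, random_peakset


def _peak(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestFilterDE:
    def test_boundary_log2fc_excluded(self):
        t = pd.DataFrame(
            {"gene_id": ["a"], "log2fc": [0.5], "adj_p": [0.01]}
        )
        up, down = filter_de(t)
        assert up == set() and down == set()

    def test_boundary_fdr_excluded(self):
        t = pd.DataFrame({"gene_id": ["a"], "log2fc": [2.0], "adj_p": [0.05]})
        up, _ = filter_de(t)
        assert up == set()

    def test_down_gene(self):
        t = pd.DataFrame({"gene_id": ["a"], "log2fc": [-2.0], "adj_p": [0.049]})
        up, down = filter_de(t)
        assert down == {"a"} and up == set()

    def test_duplicate_gene_id_rejected(self):
        t = pd.DataFrame(
            {"gene_id": ["a", "a"], "log2fc": [1, 2], "adj_p": [0.1, 0.1]}
        )
        with pytest.raises(ValidationError, match="duplicate"):
            filter_de(t)

    def test_matches_row_predicate_oracle(self, rng):
        n = 500
        t = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "log2fc": rng.normal(0, 1, n),
                "adj_p": rng.uniform(0, 1, n),
            }
        )
        up, down = filter_de(t, fdr=0.05, min_abs_log2fc=0.5)
        for _, row in t.iterrows():
            in_up = row.adj_p < 0.05 and row.log2fc > 0.5
            in_down = row.adj_p < 0.05 and row.log2fc < -0.5
            assert (row.gene_id in up) == in_up
            assert (row.gene_id in down) == in_down
        assert not (up & down)


class TestAssociateGenes:
    def test_gene_within_window(self):
        genes = GeneAnnotation.from_records([("g", "chr1", 60_000)])
        assoc = associate_genes(PeakSet([_peak(5_000, 10_000)]), genes)
        assert assoc == {"g": 1}

    def test_gene_beyond_window(self):
        genes = GeneAnnotation.from_records([("g", "chr1", 200_000)])
        assoc = associate_genes(PeakSet([_peak(5_000, 10_000)]), genes)
        assert assoc == {}

    def test_matches_exhaustive_scan(self, rng):
        genes = random_genes(rng, 20)
        elements = random_peakset(rng, 100)
        assoc = associate_genes(elements, genes, window=10_000)
        expected: dict[str, int] = {}
        for iv in elements:
            best = None
            for gid, chrom, tss in zip(genes.gene_ids, genes.chroms, genes.tss):
                if chrom != iv.chrom:
                    continue
                if iv.start <= tss < iv.end:
                    d = 0
                elif tss < iv.start:
                    d = iv.start - tss
                else:
                    d = tss - iv.end
                if d <= 10_000 and (best is None or (d, gid) < best):
                    best = (d, gid)
            if best:
                expected[best[1]] = expected.get(best[1], 0) + 1
        assert assoc == expected

    def test_shrinking_window_never_adds(self, rng):
        genes = random_genes(rng, 15)
        elements = random_peakset(rng, 60)
        wide = associate_genes(elements, genes, window=50_000)
        narrow = associate_genes(elements, genes, window=5_000)
        assert sum(narrow.values()) <= sum(wide.values())
        assert set(narrow) <= set(wide)

    def test_all_within_window_mode_supersets_nearest(self, rng):
        genes = random_genes(rng, 15)
        elements = random_peakset(rng, 40)
        nearest = associate_genes(elements, genes, window=20_000)
        all_mode = associate_genes(
            elements, genes, window=20_000, all_within_window=True
        )
        assert set(nearest) <= set(all_mode)


class TestHypergeomEnrichment:
    def test_forced_full_overlap_p_one(self):
        u = {f"g{i}" for i in range(10)}
        res = hypergeom_enrichment(u, u, {"g1", "g2", "g3"})
        assert res.p_upper == pytest.approx(1.0)

    def test_worked_example_exact_value(self):
        # N=10, K=4, n=5, k=3: (C(4,3)C(6,2)+C(4,4)C(6,1))/C(10,5) = 66/252
        u = {f"g{i}" for i in range(10)}
        marked = {"g0", "g1", "g2", "g3"}
        sample = {"g0", "g1", "g2", "g4", "g5"}
        res = hypergeom_enrichment(u, marked, sample)
        assert res.overlap_k == 3
        assert res.p_upper == pytest.approx(66 / 252, abs=1e-12)

    def test_subset_violation_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_enrichment({"a"}, {"b"}, {"a"})

    def test_matches_exhaustive_enumeration_all_small_n(self):
        # full scan over every (N, K, n, k) with N <= 25
        for N in range(1, 26):
            for K in range(0, N + 1, 3):
                for n in range(0, N + 1, 3):
                    u = {f"g{i}" for i in range(N)}
                    marked = {f"g{i}" for i in range(K)}
                    sample = {f"g{i}" for i in range(n)}  # overlap k=min(K,n)
                    k = len(marked & sample)
                    res = hypergeom_enrichment(u, marked, sample)
                    expected = sum(
                        math.comb(K, j) * math.comb(N - K, n - j)
                        for j in range(k, min(K, n) + 1)
                        if n - j <= N - K
                    ) / math.comb(N, n)
                    assert res.p_upper == pytest.approx(expected, rel=1e-10)

    def test_matches_urn_sampling(self, rng):
        N, K, n = 40, 12, 15
        u = list(range(N))
        marked = set(range(K))
        sample = set(rng.choice(N, n, replace=False).tolist())
        k = len(marked & sample)
        res = hypergeom_enrichment(
            {str(i) for i in u},
            {str(i) for i in marked},
            {str(i) for i in sample},
        )
        draws = 100_000
        sims = rng.permuted(
            np.tile(np.arange(N) < K, (draws, 1)), axis=1
        )[:, :n].sum(axis=1)
        p_mc = float((sims >= k).mean())
        se = math.sqrt(max(p_mc * (1 - p_mc), 1e-9) / draws)
        assert abs(res.p_upper - p_mc) <= 3 * se + 1e-12


class TestRankSum:
    def test_identical_samples_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_all_tied_degenerate(self):
        assert rank_sum_test([5, 5], [5, 5, 5]) == 1.0

    def test_exact_small_sample_value(self):
        # complete separation of 3 vs 3: one-sided 1/20, two-sided 0.1
        assert rank_sum_test([10, 11, 12], [1, 2, 3]) == pytest.approx(0.1)

    def test_shift_never_increases_p(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, 15)
            b = rng.normal(0, 1, 15)
            p0 = rank_sum_test(a, b)
            p1 = rank_sum_test(a + 5, b)
            assert p1 <= p0 + 1e-12

    def test_fc_contrast_reports_medians(self):
        up = pd.DataFrame({"gene_id": list("abc"), "log2fc": [2.0, 3.0, 4.0]})
        down = pd.DataFrame({"gene_id": list("xyz"), "log2fc": [-0.6, -0.7, -0.8]})
        res = fc_contrast(up, down)
        assert res["median_abs_log2fc_up"] == 3.0
        assert res["median_abs_log2fc_down"] == pytest.approx(0.7)
        assert res["p_value"] == pytest.approx(0.1)

    def test_fc_contrast_empty_rejected(self):
        up = pd.DataFrame({"gene_id": ["a"], "log2fc": [2.0]})
        with pytest.raises(ValidationError):
            fc_contrast(up, up.iloc[:0])


def _marks(elements):
    return {
        "H3K27ac": PeakSet([GenomicInterval(*e) for e in elements]),
        "H3K4me1": PeakSet([GenomicInterval(*e) for e in elements]),
    }


class TestTissueSpecific:
    def test_unique_element_retained(self):
        marks = {
            "kidney": _marks([("chr1", 0, 1_000)]),
            "brain": _marks([("chr1", 50_000, 51_000)]),
        }
        ts = tissue_specific(marks, "kidney")
        assert [(iv.start, iv.end) for iv in ts.elements] == [(0, 1_000)]

    def test_single_bp_overlap_disqualifies(self):
        marks = {
            "kidney": _marks([("chr1", 0, 1_000)]),
            "brain": _marks([("chr1", 999, 2_000)]),
        }
        assert len(tissue_specific(marks, "kidney").elements) == 0

    def test_candidate_needs_both_marks(self):
        marks = {
            "kidney": {
                "H3K27ac": PeakSet([_peak(0, 1_000)]),
                "H3K4me1": PeakSet([_peak(5_000, 6_000)]),
            },
            "brain": _marks([("chr1", 90_000, 91_000)]),
        }
        assert len(tissue_specific(marks, "kidney").elements) == 0

    def test_missing_mark_is_error(self):
        marks = {
            "kidney": {"H3K27ac": PeakSet([_peak(0, 10)])},
            "brain": _marks([("chr1", 50, 60)]),
        }
        with pytest.raises(ValidationError, match="H3K4me1"):
            tissue_specific(marks, "kidney")

    def test_matches_brute_force_three_tissues(self, rng):
        tissues = {}
        for t in ("a", "b", "c"):
            tissues[t] = {
                "H3K27ac": random_peakset(rng, 30, span=50_000),
                "H3K4me1": random_peakset(rng, 30, span=50_000),
            }
        result = tissue_specific(tissues, "a")
        # dense-mask oracle
        def cand_mask(t):
            mask = {}
            for chrom in ("chr1", "chr2"):
                m27 = np.zeros(52_000, dtype=bool)
                m4 = np.zeros(52_000, dtype=bool)
                for iv in tissues[t]["H3K27ac"]:
                    if iv.chrom == chrom:
                        m27[iv.start : iv.end] = True
                for iv in tissues[t]["H3K4me1"]:
                    if iv.chrom == chrom:
                        m4[iv.start : iv.end] = True
                mask[chrom] = m27 & m4
            return mask
        ca, cb, cc = cand_mask("a"), cand_mask("b"), cand_mask("c")
        for iv in result.elements:
            assert ca[iv.chrom][iv.start : iv.end].all()
            assert not (cb[iv.chrom][iv.start : iv.end]).any()
            assert not (cc[iv.chrom][iv.start : iv.end]).any()

    def test_focal_outputs_pairwise_disjoint(self, rng):
        tissues = {
            t: {
                "H3K27ac": random_peakset(rng, 25, span=40_000),
                "H3K4me1": random_peakset(rng, 25, span=40_000),
            }
            for t in ("a", "b", "c")
        }
        sets = [tissue_specific(tissues, t).elements for t in tissues]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                for iv in sets[j]:
                    assert not sets[i].overlaps(iv)


class TestTissueOverlapRanking:
    def test_contained_set_ranks_focal_first(self):
        kidney = TissueEnhancerSet(
            "kidney", PeakSet([_peak(i * 10_000, i * 10_000 + 1_000)
                               for i in range(20)])
        )
        brain = TissueEnhancerSet(
            "brain", PeakSet([_peak(500_000 + i * 10_000, 500_000 + i * 10_000 + 1_000)
                              for i in range(20)])
        )
        activated = PeakSet([_peak(i * 10_000 + 100, i * 10_000 + 200)
                             for i in range(10)])
        df = tissue_overlap_ranking(activated, [kidney, brain])
        assert df.iloc[0]["tissue"] == "kidney"
        assert df.iloc[0]["overlap_count"] == 10

    def test_disjoint_all_zero_p_one(self):
        sets = [
            TissueEnhancerSet("a", PeakSet([_peak(0, 100)])),
            TissueEnhancerSet("b", PeakSet([_peak(500, 600)])),
        ]
        activated = PeakSet([_peak(10_000, 11_000)])
        df = tissue_overlap_ranking(activated, sets)
        assert (df["overlap_count"] == 0).all()
        assert (df["p_upper"] == 1.0).all()

    def test_planted_122_brain_overlaps_recovered(self):
        # 500 synthetic activated enhancers; 122 coincide with brain-specific
        # elements, echoing the planted tissue-overlap structure
        activated = PeakSet(
            [_peak(i * 5_000, i * 5_000 + 1_000) for i in range(500)]
        )
        brain = TissueEnhancerSet(
            "brain",
            PeakSet([_peak(i * 5_000 + 200, i * 5_000 + 700) for i in range(122)]),
        )
        kidney = TissueEnhancerSet(
            "kidney",
            PeakSet([_peak(10_000_000 + i * 3_000, 10_000_000 + i * 3_000 + 500)
                     for i in range(146)]),
        )
        df = tissue_overlap_ranking(activated, [brain, kidney])
        row = df[df["tissue"] == "brain"].iloc[0]
        assert row["overlap_count"] == 122
        assert df.iloc[0]["tissue"] == "brain"
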