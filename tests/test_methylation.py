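"""M-value arithmetic, probe classification, normalization, contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from remodelmap import (
    GeneAnnotation,
    MethylationDataset,
    ValidationError,
    assign_probe_gene,
    classify_probes,
    cpm_filter,
    expression_contrast,
    m_value,
    merge_replicates,
    normalize_counts,
    random_control_cohort,
)


class TestMValue:
    def test_equal_signal_zero(self):
        assert m_value(100, 100) == 0.0

    def test_log2_ratio(self):
        assert m_value(400, 100, offset=0) == pytest.approx(2.0)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValidationError):
            m_value(-1, 10)

    @settings(max_examples=200, derandomize=True)
    @given(a=st.floats(0, 1e6), b=st.floats(0, 1e6))
    def test_antisymmetry(self, a, b):
        assert m_value(a, b) == pytest.approx(-m_value(b, a), abs=1e-12)


class TestMergeReplicates:
    def test_mean(self):
        assert merge_replicates({"a": 1.0, "b": 2.0, "c": 3.0}, ["a", "b", "c"]) == 2.0

    def test_single_sample(self):
        assert merge_replicates({"a": 1.5}, ["a"]) == 1.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            merge_replicates({"a": 1.0}, [])

    def test_split_half_linearity(self, rng):
        vals = {f"s{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 8))}
        keys = list(vals)
        left = merge_replicates(vals, keys[:4])
        right = merge_replicates(vals, keys[4:])
        assert (left + right) / 2 == pytest.approx(merge_replicates(vals, keys))


def _dataset(m_mrtk, m_nk, base=1_000.0, reps=3):
    """Noiseless dataset whose merged M-values equal the given targets."""
    n = len(m_mrtk)
    samples = [f"MRTK_r{i}" for i in range(reps)] + [f"NK_r{i}" for i in range(reps)]
    groups = {s: ("MRTK" if s.startswith("MRTK") else "NK") for s in samples}
    meth, unmeth = {}, {}
    for s in samples:
        target = np.asarray(m_mrtk if groups[s] == "MRTK" else m_nk, dtype=float)
        # offset-free construction: with base >> 1 the offset bias is ~0
        meth[s] = base * np.power(2.0, target / 2)
        unmeth[s] = base * np.power(2.0, -target / 2)
    idx = pd.Index([f"cg{i:05d}" for i in range(n)], name="probe_id")
    probes = pd.DataFrame(
        {"probe_id": idx, "chrom": "k1", "pos": np.arange(n) * 100 + 1_000}
    )
    return MethylationDataset(
        probes=probes,
        meth=pd.DataFrame(meth, index=idx),
        unmeth=pd.DataFrame(unmeth, index=idx),
        groups=groups,
    )


class TestClassifyProbes:
    def test_tumor_methylated(self):
        cls = classify_probes(_dataset([2.0], [-1.0]))
        assert cls["class"].tolist() == ["tumor_methylated"]

    def test_boundary_strictness(self):
        # m_mrtk exactly 1.0 fails the strict > rule (tiny offset bias is
        # negative here, keeping the merged value at or below 1)
        cls = classify_probes(_dataset([1.0], [-1.0]))
        assert cls["class"].tolist() == ["neither"]

    def test_both_and_normal_classes(self):
        cls = classify_probes(_dataset([2.0, -1.5], [2.0, 2.0]))
        assert cls["class"].tolist() == ["both", "normal_methylated"]

    def test_counts_sum_to_total(self, rng):
        m1 = rng.normal(0, 2, 500)
        m2 = rng.normal(0, 2, 500)
        cls = classify_probes(_dataset(m1, m2))
        assert cls["class"].value_counts().sum() == 500

    def test_planted_523_642_recovered_noiselessly(self):
        n_t, n_n, n_bg = 523, 642, 2_000
        m_mrtk = np.concatenate([np.full(n_t, 2.0), np.full(n_n, -1.0),
                                 np.zeros(n_bg)])
        m_nk = np.concatenate([np.full(n_t, -1.0), np.full(n_n, 2.0),
                               np.zeros(n_bg)])
        counts = classify_probes(_dataset(m_mrtk, m_nk))["class"].value_counts()
        assert counts["tumor_methylated"] == 523
        assert counts["normal_methylated"] == 642


class TestAssignProbeGene:
    GENES = GeneAnnotation.from_records(
        [("near", "k1", 10_000), ("far", "k1", 40_000)]
    )

    def test_within_window(self):
        assert assign_probe_gene("k1", 13_000, self.GENES) == "near"

    def test_beyond_window(self):
        assert assign_probe_gene("k1", 17_000, self.GENES) is None

    def test_unwindowed_switch(self):
        assert assign_probe_gene("k1", 17_000, self.GENES, window=None) == "near"

    def test_matches_exhaustive_scan(self, rng):
        genes = GeneAnnotation.from_records(
            [(f"g{i}", "k1", int(p)) for i, p in
             enumerate(sorted(rng.integers(0, 100_000, 30)))]
        )
        for _ in range(100):
            pos = int(rng.integers(0, 100_000))
            got = assign_probe_gene("k1", pos, genes, window=5_000)
            best = None
            for gid, tss in zip(genes.gene_ids, genes.tss):
                d = 0 if tss == pos else (pos - tss - 1 if tss < pos else tss - pos - 1)
                d = max(d, 0)
                if d <= 5_000 and (best is None or (d, gid) < best):
                    best = (d, gid)
            assert got == (best[1] if best else None)


class TestCountMatrix:
    def test_cpm_keeps_one_per_million(self):
        counts = pd.DataFrame({"s1": [1, 0], "s2": [0, 0]},
                              index=["a", "b"]).astype(float)
        counts.loc["filler"] = [999_999, 1_000_000]
        kept = cpm_filter(counts, min_cpm=0.5)
        assert "a" in kept.index and "b" not in kept.index

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValidationError):
            cpm_filter(counts)

    def test_cpm_matches_predicate_oracle(self, rng):
        counts = pd.DataFrame(
            rng.poisson(2.0, (300, 4)).astype(float),
            index=[f"g{i}" for i in range(300)],
            columns=list("abcd"),
        )
        counts += rng.uniform(0, 1, counts.shape).round()  # avoid all-zero libs
        kept = cpm_filter(counts, min_cpm=0.5, min_libraries=2)
        totals = counts.sum(axis=0)
        for g in counts.index:
            n_ok = sum(
                counts.loc[g, s] / totals[s] * 1e6 >= 0.5 for s in counts.columns
            )
            assert (g in kept.index) == (n_ok >= 2)

    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"s1": [10.0, 20.0], "s2": [10.0, 20.0]},
                              index=["a", "b"])
        _, factors = normalize_counts(counts)
        np.testing.assert_allclose(factors, 1.0)

    def test_doubled_sample_scaled_out(self):
        a = np.array([10.0, 50.0, 3.0, 100.0])
        counts = pd.DataFrame({"s1": a, "s2": 2 * (a + 4) - 4})
        norm, factors = normalize_counts(counts, pseudocount=4)
        assert factors["s2"] / factors["s1"] == pytest.approx(2.0)
        np.testing.assert_allclose(norm["s1"], norm["s2"], rtol=1e-12)

    def test_factors_match_independent_recomputation(self, rng):
        counts = pd.DataFrame(
            rng.poisson(30.0, (200, 5)).astype(float),
            columns=list("abcde"),
        )
        _, factors = normalize_counts(counts, pseudocount=4)
        x = counts.to_numpy() + 4
        geo = np.exp(np.log(x).mean(axis=1))
        for j, s in enumerate(counts.columns):
            assert factors[s] == pytest.approx(
                float(np.median(x[:, j] / geo)), rel=1e-12
            )

    def test_scaling_invariance(self, rng):
        # median-of-ratios against the per-row geometric mean removes a
        # per-library scale up to one global constant c^(1/m) (the reference
        # itself drifts by that much); the scaled library's factor relative
        # to the others absorbs exactly c.  Tested with pseudocount 0 on an
        # all-positive matrix so the transform is exact.
        c = 3.7
        counts = pd.DataFrame(
            rng.poisson(30.0, (151, 4)).astype(float) + 1, columns=list("abcd")
        )
        norm1, f1 = normalize_counts(counts, pseudocount=0.0)
        scaled = counts.copy()
        scaled["b"] *= c
        norm2, f2 = normalize_counts(scaled, pseudocount=0.0)
        ratio = (norm2 / norm1).to_numpy()
        np.testing.assert_allclose(ratio, ratio[0, 0], rtol=1e-9)
        assert (f2["b"] / f2["a"]) / (f1["b"] / f1["a"]) == pytest.approx(c)
        # between-sample structure is fully restored
        np.testing.assert_allclose(
            norm2["b"] / norm2["a"], norm1["b"] / norm1["a"], rtol=1e-9
        )


class TestExpressionContrast:
    def _matrix(self, rng, n_genes=400, suppressed=None, fold=2.0):
        samples = [f"MRTK_{i}" for i in range(6)] + [f"NK_{i}" for i in range(6)]
        groups = {s: s.split("_")[0] for s in samples}
        base = rng.lognormal(4, 1, n_genes)
        rows = {}
        supp = set(suppressed or [])
        genes = [f"g{i}" for i in range(n_genes)]
        data = np.empty((n_genes, 12))
        for j, s in enumerate(samples):
            mu = base * rng.lognormal(0, 0.2, n_genes)
            if groups[s] == "MRTK":
                mu = np.where([g in supp for g in genes], mu / fold, mu)
            data[:, j] = rng.poisson(mu) + 4
        return pd.DataFrame(data, index=genes, columns=samples), groups

    def test_planted_suppression_detected(self, rng):
        cohort = [f"g{i}" for i in range(200)]
        norm, groups = self._matrix(rng, suppressed=cohort)
        res = expression_contrast(norm, cohort, groups)
        assert res["median_log10_mrtk"] < res["median_log10_nk"]
        assert res["p_value"] < 0.01

    def test_label_symmetry(self, rng):
        norm, groups = self._matrix(rng)
        cohort = list(norm.index[:100])
        res = expression_contrast(norm, cohort, groups)
        flipped = {s: ("NK" if g == "MRTK" else "MRTK") for s, g in groups.items()}
        res2 = expression_contrast(norm, cohort, flipped)
        assert res["p_value"] == pytest.approx(res2["p_value"])
        assert res["median_log10_mrtk"] == pytest.approx(res2["median_log10_nk"])

    def test_missing_cohort_gene_listed(self, rng):
        norm, groups = self._matrix(rng, n_genes=10)
        with pytest.raises(ValidationError, match="absentgene"):
            expression_contrast(norm, ["absentgene"], groups)

    def test_null_p_not_enriched(self, rng):
        # without a planted effect the contrast stays null-calibrated
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            local = np.random.default_rng(seed)
            norm, groups = self._matrix(local, n_genes=150)
            res = expression_contrast(norm, list(norm.index[:80]), groups)
            hits += res["p_value"] < 0.05
        # binomial bound: expect 2, allow 3 s.e. above
        assert hits <= 0.05 * n_seeds + 3 * np.sqrt(0.05 * 0.95 * n_seeds)

    def test_random_control_seeded_and_excludes_cohort(self, rng):
        norm, _ = self._matrix(rng)
        cohort = list(norm.index[:50])
        c1 = random_control_cohort(norm, cohort, k=100, seed=7)
        c2 = random_control_cohort(norm, cohort, k=100, seed=7)
        assert c1 == c2
        assert not set(c1) & set(cohort)
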