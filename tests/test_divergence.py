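"""FST estimation, outlier detection, PCoA with Cailliez correction, and
consensus-SNP divergence dating."""

import numpy as np
import pandas as pd
import pytest

from micropopgen.annotation import Gene
from micropopgen.divergence import (_hudson_terms, consensus_divergence_time,
                                    fst_outlier_test, gene_fst_table,
                                    hudson_fst_gene, pairwise_mean_fst,
                                    pcoa_cailliez)
from micropopgen.profiling import build_pileup
from micropopgen.simulate import (simulate_deme_pair, simulate_sample_reads,
                                  simulate_strain_pool)

from conftest import make_pileup


class TestHudsonLocus:
    def test_fixed_difference_gives_one(self):
        num, den = _hudson_terms(np.array([20, 0, 0, 0]),
                                 np.array([0, 20, 0, 0]))
        assert num / den == pytest.approx(1.0)

    def test_balanced_site_slightly_negative(self):
        # equal frequencies at depth 21: the finite-depth correction makes
        # the locus estimate exactly -1/20 regardless of the frequency
        num, den = _hudson_terms(np.array([11, 10, 0, 0]),
                                 np.array([11, 10, 0, 0]))
        assert num / den == pytest.approx(-0.05)

    def test_insufficient_depth_undefined(self):
        assert _hudson_terms(np.array([1, 0, 0, 0]),
                             np.array([5, 5, 0, 0])) is None


class TestGeneFst:
    def test_identical_pileups_near_zero(self, tiny_annotation):
        pileup = make_pileup(tiny_annotation, {
            5: {"A": 120, "G": 80},
            9: {"G": 150, "T": 50},
        })
        gene = tiny_annotation.genes[0]
        loci = np.array([5, 9])
        fst = hudson_fst_gene(pileup, pileup, gene, loci)
        assert abs(fst) < 0.02

    def test_pooled_counts_match_haplotype_frequency_oracle(self):
        """Deep pooled counts against the infinite-depth FST computed from
        explicit subpopulation haplotype frequencies (ratio of sums)."""
        rng = np.random.default_rng(8)
        gene = Gene("g", "c", 0, 30, "+")
        depth = 200_000
        for _ in range(10):
            n_loci = rng.integers(2, 10)
            loci = np.sort(rng.choice(30, n_loci, replace=False))
            p1 = rng.uniform(0.05, 0.95, n_loci)
            p2 = rng.uniform(0.05, 0.95, n_loci)
            counts_a = np.zeros((30, 4), dtype=np.int64)
            counts_b = np.zeros((30, 4), dtype=np.int64)
            for pos, q1, q2 in zip(loci, p1, p2):
                counts_a[pos, 0] = round(depth * q1)
                counts_a[pos, 1] = depth - counts_a[pos, 0]
                counts_b[pos, 0] = round(depth * q2)
                counts_b[pos, 1] = depth - counts_b[pos, 0]
            from micropopgen.profiling import PileupTable
            pa = PileupTable("c", counts_a.astype(np.int32))
            pb = PileupTable("c", counts_b.astype(np.int32))
            est = hudson_fst_gene(pa, pb, gene, loci, min_depth=20,
                                  sd_filter=None)
            num = ((p1 - p2) ** 2).sum()
            den = (p1 * (1 - p2) + p2 * (1 - p1)).sum()
            assert abs(est - num / den) < 0.01

    def test_two_deme_recovery(self, annotation):
        dp = simulate_deme_pair(annotation, 40, 0.2, 0.02, seed=11)
        ra = simulate_sample_reads(dp.pool_a, 60, 0.0, seed=1)
        rb = simulate_sample_reads(dp.pool_b, 60, 0.0, seed=2)
        pa = build_pileup(ra, annotation)
        pb = build_pileup(rb, annotation)
        table = gene_fst_table(pa, pb, annotation)
        est = table["fst"].dropna().mean()
        truth = dp.true_mean_fst()
        assert abs(est - truth) / truth < 0.15

    def test_same_pool_two_draws_low_fst(self, annotation, pool):
        ra = simulate_sample_reads(pool, 60, 0.0, seed=31)
        rb = simulate_sample_reads(pool, 60, 0.0, seed=32)
        pa = build_pileup(ra, annotation)
        pb = build_pileup(rb, annotation)
        table = gene_fst_table(pa, pb, annotation)
        assert abs(table["fst"].dropna().mean()) < 0.01


class TestPairwiseMatrix:
    def test_matrix_symmetric_zero_diagonal(self, annotation, pool):
        pileups = {
            f"s{k}": build_pileup(
                simulate_sample_reads(pool, 40, 0.0, seed=40 + k), annotation)
            for k in range(3)}
        mat = pairwise_mean_fst(pileups, annotation)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)

    def test_too_few_deep_samples_rejected(self, annotation, pool):
        shallow = build_pileup(
            simulate_sample_reads(pool, 5, 0.0, seed=1), annotation)
        with pytest.raises(ValueError):
            pairwise_mean_fst({"a": shallow, "b": shallow}, annotation)


class TestOutliers:
    def test_single_elevated_gene_flagged(self):
        rng = np.random.default_rng(3)
        background = pd.Series(rng.normal(0.038, 0.032, 200)).clip(lower=-0.1)
        fsts = pd.concat([background, pd.Series([0.442])], ignore_index=True)
        result = fst_outlier_test(fsts)
        assert bool(result.loc[200, "outlier"])
        assert result.loc[200, "z"] > 8
        assert result["outlier"].sum() <= 3

    def test_identical_values_give_no_outliers(self):
        with pytest.warns(UserWarning):
            result = fst_outlier_test(pd.Series([0.1] * 20))
        assert not result["outlier"].any()

    def test_null_distribution_flags_nothing(self):
        rng = np.random.default_rng(4)
        flagged = []
        for _ in range(20):
            fsts = pd.Series(rng.normal(0.03, 0.02, 150))
            flagged.append(fst_outlier_test(fsts)["outlier"].mean())
        assert np.mean(flagged) <= 0.05


class TestPCoA:
    def test_collinear_points_exactly_euclidean(self):
        d = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float,
                         index=list("abc"), columns=list("abc"))
        res = pcoa_cailliez(d)
        assert res.cailliez_constant == pytest.approx(0.0, abs=1e-6)
        assert res.explained[0] == pytest.approx(1.0, abs=1e-6)
        # embedded distances reproduce the input
        coords = res.coordinates.to_numpy()
        dist = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(dist, d, atol=1e-6)

    def test_zero_matrix_gives_origin(self):
        d = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"),
                         columns=list("abcd"))
        res = pcoa_cailliez(d)
        assert res.coordinates.shape[1] == 0 or \
            np.allclose(res.coordinates, 0)

    def test_correction_makes_gram_psd_and_distances_match(self):
        # a strongly non-Euclidean 4-point dissimilarity
        d = np.array([
            [0, 1, 1, 4],
            [1, 0, 1, 1],
            [1, 1, 0, 1],
            [4, 1, 1, 0],
        ], dtype=float)
        frame = pd.DataFrame(d, index=list("abcd"), columns=list("abcd"))
        res = pcoa_cailliez(frame)
        assert res.cailliez_constant > 0
        dc = d + res.cailliez_constant
        np.fill_diagonal(dc, 0)
        n = 4
        j = np.eye(n) - np.ones((n, n)) / n
        gram = -0.5 * j @ (dc ** 2) @ j
        assert np.linalg.eigvalsh(gram).min() >= -1e-8
        coords = res.coordinates.to_numpy()
        dist = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(dist, dc, atol=1e-6)

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            pcoa_cailliez(d)


class TestDivergenceDating:
    def test_identical_profiles_give_zero(self, annotation, pileup):
        est = consensus_divergence_time(pileup, pileup, annotation)
        assert est.n_consensus_snps == 0
        assert est.generations == 0.0
        assert est.years == 0.0

    def test_arithmetic_scaling(self, tiny_annotation):
        # force exactly one third-position consensus difference and check
        # T = d3 / (2 mu) and the year conversion
        pileup_a = make_pileup(tiny_annotation, {})
        pileup_b = make_pileup(tiny_annotation, {9: {"A": 100}})
        est = consensus_divergence_time(pileup_a, pileup_b, tiny_annotation,
                                        mu=1e-10, generation_days=7)
        assert est.n_consensus_snps == 1
        d3 = 1 / est.n_sites
        assert est.d3 == pytest.approx(d3)
        assert est.generations == pytest.approx(d3 / 2e-10)
        assert est.years == pytest.approx(est.generations * 7 / 365.25)

    def test_known_divergence_recovered(self, annotation):
        # two single-strain populations separated by substitutions at a
        # known fraction of third positions
        rng = np.random.default_rng(9)
        third = annotation.third_codon_positions()
        pool = simulate_strain_pool(annotation, 1, 0.0, seed=1)
        reads_a = simulate_sample_reads(pool, 30, 0.0, seed=2)
        pileup_a = build_pileup(reads_a, annotation)
        counts_b = pileup_a.counts.copy()
        changed = rng.choice(third, size=len(third) // 50, replace=False)
        for pos in changed:
            base = int(annotation.codes[pos])
            counts_b[pos] = 0
            counts_b[pos, (base + 1) % 4] = 30
        from micropopgen.profiling import PileupTable
        pileup_b = PileupTable(annotation.contig_id, counts_b)
        est = consensus_divergence_time(pileup_a, pileup_b, annotation)
        expected_d3 = len(changed) / est.n_sites
        assert est.d3 == pytest.approx(expected_d3, rel=0.05)

    def test_poor_coverage_rejected(self, tiny_annotation):
        empty = make_pileup(
            tiny_annotation,
            {p: {} for p in range(tiny_annotation.length)})
        full = make_pileup(tiny_annotation, {})
        with pytest.raises(ValueError, match="50%"):
            consensus_divergence_time(empty, full, tiny_annotation)
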