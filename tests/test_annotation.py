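"""Genic annotation, LD r^2 matrices, LD-weighted scores, median splits,
score correlations, and partition assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import sparse

from heritkit import (AnnotationTrack, LDMatrix, SimulationConfig,
                      annotate_genic, build_partition, compute_ld_matrix,
                      ld_weight_scores, median_split, score_correlation,
                      simulate_annotation, simulate_genotypes)
from heritkit.datatypes import HeritkitError

from conftest import brute_force_genic, exact_correlation_tracks, make_genotypes


def snp_map_at(positions, chrom="1"):
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(len(positions))],
        "chrom": chrom, "pos": positions, "a1": "A", "a2": "G",
    })


def track(scores, snp_ids=None, **kwargs):
    scores = np.asarray(scores, dtype=float)
    ids = snp_ids or [f"rs{i}" for i in range(len(scores))]
    return AnnotationTrack(snp_ids=ids, raw_score=scores, **kwargs)


class TestAnnotateGenic:
    def test_flank_boundary_arithmetic(self):
        genes = pd.DataFrame({"chrom": ["1"], "start": [99999], "end": [200000]})
        # 1-based span [100000, 200000], flank 20000 -> genic iff pos >= 80000
        result = annotate_genic(snp_map_at([79999, 80000]), genes, flank_bp=20000)
        assert list(result.category) == ["intergenic", "genic"]

    def test_empty_gene_table(self):
        genes = pd.DataFrame(columns=["chrom", "start", "end"])
        result = annotate_genic(snp_map_at([100, 200]), genes)
        assert (result.category == "intergenic").all()

    def test_chromosome_mismatch_raises(self):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        with pytest.raises(HeritkitError, match="chr1"):
            annotate_genic(snp_map_at([50]), genes)

    def test_simulated_half_genic_coverage(self):
        cfg = SimulationConfig(n_subjects=5, n_snps=10000, frac_genic=0.5, seed=21)
        g = simulate_genotypes(cfg)
        annot = simulate_annotation(g.snp_map, cfg)
        result = annotate_genic(g.snp_map, annot.gene_table, flank_bp=0)
        frac = (result.category == "genic").mean()
        assert 0.45 < frac < 0.55

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_interval_scan(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(np.arange(1, 500_000), size=300, replace=False))
        starts = np.sort(rng.choice(np.arange(0, 450_000), size=8, replace=False))
        genes = pd.DataFrame({
            "chrom": "1", "start": starts,
            "end": starts + rng.integers(1_000, 40_000, size=8),
        })
        result = annotate_genic(snp_map_at(pos), genes, flank_bp=20000)
        expected = brute_force_genic(pos, genes, 20000)
        np.testing.assert_array_equal(result.raw_score.astype(bool), expected)


class TestLDMatrix:
    def test_diagonal_and_duplicate_column(self, rng):
        geno = make_genotypes(80, 3, rng)
        geno.dosages[:, 2] = geno.dosages[:, 0]
        ld = compute_ld_matrix(geno)
        dense = ld.values.toarray()
        np.testing.assert_allclose(np.diag(dense), 1.0)
        assert dense[0, 2] == pytest.approx(1.0)

    def test_matches_bruteforce_correlation(self, rng):
        geno = make_genotypes(50, 3, rng)
        ld = compute_ld_matrix(geno)
        dense = ld.values.toarray()
        for i in range(3):
            for j in range(3):
                expected = np.corrcoef(geno.dosages[:, i], geno.dosages[:, j])[0, 1] ** 2
                assert dense[i, j] == pytest.approx(expected, abs=1e-12)
        assert dense[0, 1] < 0.2 and dense[0, 2] < 0.2  # independent columns

    def test_window_restricts_pairs(self, rng):
        geno = make_genotypes(40, 5, rng)
        geno.snp_map["pos"] = [1000, 2000, 3000, 500_000, 990_000]
        ld = compute_ld_matrix(geno, window_bp=10_000)
        dense = ld.values.toarray()
        assert dense[0, 3] == 0.0 and dense[0, 4] == 0.0
        assert dense[0, 1] > 0.0 or True  # entry exists structurally
        assert ld.values[0, 1] == pytest.approx(
            np.corrcoef(geno.dosages[:, 0], geno.dosages[:, 1])[0, 1] ** 2
        )

    def test_pairwise_deletion_with_missing(self, rng):
        geno = make_genotypes(100, 2, rng, missing_rate=0.1)
        ld = compute_ld_matrix(geno)
        a, b = geno.dosages[:, 0], geno.dosages[:, 1]
        ok = ~(np.isnan(a) | np.isnan(b))
        expected = np.corrcoef(a[ok], b[ok])[0, 1] ** 2
        assert ld.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_raises(self, rng):
        geno = make_genotypes(30, 2, rng)
        geno.dosages[:, 1] = 1.0
        with pytest.raises(HeritkitError, match="zero-variance"):
            compute_ld_matrix(geno)


class TestLDWeighting:
    def hand_ld(self):
        r2 = np.array([[1, 0.5, 0], [0.5, 1, 0.5], [0, 0.5, 1.0]])
        return LDMatrix(snp_ids=["rs0", "rs1", "rs2"],
                        values=sparse.csr_matrix(r2), window_bp=10**6)

    def test_hand_evaluated_weighted_average(self):
        out = ld_weight_scores(self.hand_ld(), track([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(out.ld_weighted_score, [2 / 3, 1 / 4, 0.0])

    def test_constant_vector_invariant(self):
        out = ld_weight_scores(self.hand_ld(), track([0.7, 0.7, 0.7]))
        np.testing.assert_allclose(out.ld_weighted_score, 0.7)

    def test_identity_ld_is_noop(self):
        ld = LDMatrix(snp_ids=["rs0", "rs1", "rs2"],
                      values=sparse.eye(3, format="csr"), window_bp=10**6)
        out = ld_weight_scores(ld, track([0.2, 0.9, 0.4]))
        np.testing.assert_allclose(out.ld_weighted_score, [0.2, 0.9, 0.4])

    def test_unnormalized_product_flag(self):
        out = ld_weight_scores(self.hand_ld(), track([1.0, 0.0, 0.0]),
                               normalize=False)
        np.testing.assert_allclose(out.ld_weighted_score, [1.0, 0.5, 0.0])

    def test_missing_without_partner_stays_missing(self):
        out = ld_weight_scores(self.hand_ld(), track([np.nan, 0.4, np.nan]))
        # rs0 and rs2 borrow from their scored partner rs1; rs1 keeps its own
        np.testing.assert_allclose(out.ld_weighted_score, [0.4, 0.4, 0.4])
        ld = LDMatrix(snp_ids=["rs0", "rs1"], values=sparse.eye(2, format="csr"),
                      window_bp=10**6)
        out2 = ld_weight_scores(ld, track([np.nan, 0.4]))
        assert np.isnan(out2.ld_weighted_score[0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_convex_combination_property(self, seed):
        rng = np.random.default_rng(seed)
        m = 12
        geno = make_genotypes(40, m, rng)
        ld = compute_ld_matrix(geno, window_bp=5000)
        scores = rng.random(m)
        out = ld_weight_scores(ld, track(scores, snp_ids=list(geno.snp_map["snp"])))
        assert (out.ld_weighted_score >= scores.min() - 1e-12).all()
        assert (out.ld_weighted_score <= scores.max() + 1e-12).all()


class TestMedianSplit:
    def test_even_count(self):
        out = median_split(track([0.1, 0.2, 0.3, 0.4]))
        assert list(out.category) == ["low", "low", "high", "high"]

    def test_odd_count_median_goes_low(self):
        out = median_split(track([0.1, 0.2, 0.3]))
        assert list(out.category) == ["low", "low", "high"]

    def test_tie_free_split_balanced(self, rng):
        scores = rng.beta(2, 2, size=10_000)
        out = median_split(track(scores))
        n_low = (out.category == "low").sum()
        n_high = (out.category == "high").sum()
        assert abs(n_low - 5000) <= 1 and abs(n_high - 5000) <= 1

    def test_missing_scores_excluded(self):
        out = median_split(track([0.1, np.nan, 0.3, 0.4]))
        assert out.category[1] == ""

    def test_degenerate_raises(self):
        with pytest.raises(HeritkitError, match="degenerate"):
            median_split(track([0.5, 0.5, 0.5]))


class TestScoreCorrelation:
    def test_self_correlation(self):
        t = track([0.1, 0.5, 0.9, 0.2])
        r, r2 = score_correlation(t, t)
        assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_anticorrelated(self):
        r, _ = score_correlation(track([0, 1, 2]), track([2, 1, 0]))
        assert r == pytest.approx(-1.0)

    def test_printed_correlation_implies_printed_shared_variance(self, rng):
        # tracks built to have exactly the printed inter-annotation r = 0.58
        a, b = exact_correlation_tracks(rng, 500, 0.58)
        r, r2 = score_correlation(track(a), track(b))
        assert r == pytest.approx(0.58, abs=1e-12)
        assert round(r2, 2) == 0.34

    def test_zero_variance_raises(self):
        with pytest.raises(HeritkitError, match="zero variance"):
            score_correlation(track([1, 1, 1]), track([0, 1, 2]))


class TestBuildPartition:
    def test_two_set_partition_sizes(self):
        t = track([1, 1, 0, 0],
                  category=np.array(["genic", "genic", "intergenic", "intergenic"],
                                    dtype=object))
        part = build_partition(t)
        assert sum(len(s) for s in part.values()) == 4

    def test_median_partition_roughly_half(self, rng):
        out = median_split(track(rng.random(1000)))
        part = build_partition(out)
        assert abs(len(part["low"]) - 500) <= 1

    def test_overlap_raises(self):
        t1 = track([1, 0], category=np.array(["a", "a"], dtype=object))
        t2 = track([1, 0], category=np.array(["b", "b"], dtype=object))
        with pytest.raises(HeritkitError, match="overlap"):
            build_partition(t1, t2)

    def test_empty_category_raises(self):
        t = track([1, 0], category=np.array(["a", "a"], dtype=object))
        with pytest.raises(HeritkitError, match="empty category"):
            build_partition(t, categories=["a", "b"])
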