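"""Simulator ground truth: LD structure, allele frequencies, phenotype
variance decomposition, twin correlations, planted relatedness."""

import numpy as np
import pandas as pd
import pytest

from heritkit import (SimulationConfig, plant_relatedness, simulate_annotation,
                      simulate_genotypes, simulate_phenotype, simulate_twins,
                      twin_correlations, compute_grm)
from heritkit.annotation import read_bed, write_bed
from heritkit.datatypes import ConfigurationError


def adjacent_corr(dosages: np.ndarray, block_size: int):
    """Mean genotype correlation for within-block and cross-block adjacencies."""
    m = dosages.shape[1]
    within, across = [], []
    for i in range(m - 1):
        r = np.corrcoef(dosages[:, i], dosages[:, i + 1])[0, 1]
        (across if (i + 1) % block_size == 0 else within).append(r)
    return np.mean(within), np.mean(across)


class TestGenotypes:
    def test_independent_snps_uncorrelated(self):
        cfg = SimulationConfig(n_subjects=10000, n_snps=2, ld_rho=0.0, seed=5)
        g = simulate_genotypes(cfg)
        r = np.corrcoef(g.dosages[:, 0], g.dosages[:, 1])[0, 1]
        assert -0.03 < r < 0.03

    def test_block_markov_correlation(self):
        # narrow MAF range keeps rho = 0.8 feasible for every adjacent pair
        cfg = SimulationConfig(n_subjects=5000, n_snps=100, block_size=10,
                               ld_rho=0.8, maf_range=(0.4, 0.5), seed=11)
        g = simulate_genotypes(cfg)
        within, across = adjacent_corr(g.dosages, 10)
        assert within == pytest.approx(0.8, abs=0.05)
        assert across == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    def test_maf_within_binomial_error(self, p):
        n = 2000
        cfg = SimulationConfig(n_subjects=n, n_snps=50, maf_range=(p, p),
                               ld_rho=0.0, seed=3)
        g = simulate_genotypes(cfg)
        freq = g.allele_frequencies()
        se = np.sqrt(p * (1 - p) / (2 * n))
        assert (np.abs(freq - p) < 4 * se).all()
        maf = np.minimum(freq, 1 - freq)
        if p == 0.5:
            assert ((maf > 0.45) & (maf <= 0.5)).all()

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(n_subjects=50, n_snps=100, seed=9)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(SimulationConfig(n_subjects=50, n_snps=100, seed=9))
        assert np.array_equal(a.dosages, b.dosages)
        assert a.snp_map.equals(b.snp_map)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_subjects=0, n_snps=10)
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_subjects=10, n_snps=10, ld_rho=1.0)


class TestAnnotation:
    @pytest.mark.parametrize("frac, label", [(0.0, "intergenic"), (1.0, "genic")])
    def test_boundary_fractions(self, frac, label):
        cfg = SimulationConfig(n_subjects=5, n_snps=200, frac_genic=frac, seed=2)
        g = simulate_genotypes(cfg)
        annot = simulate_annotation(g.snp_map, cfg)
        assert (annot.track.category == label).all()

    def test_missing_score_count_binomial(self):
        cfg = SimulationConfig(n_subjects=5, n_snps=10000,
                               missing_score_fraction=0.02, seed=7)
        g = simulate_genotypes(cfg)
        annot = simulate_annotation(g.snp_map, cfg)
        n_missing = int(np.isnan(annot.track.raw_score).sum())
        assert 170 <= n_missing <= 230

        cfg_all = SimulationConfig(n_subjects=5, n_snps=1000,
                                   missing_score_fraction=0.0, seed=7)
        g2 = simulate_genotypes(cfg_all)
        annot2 = simulate_annotation(g2.snp_map, cfg_all)
        assert not np.isnan(annot2.track.raw_score).any()

    def test_gene_table_bed_roundtrip(self, tmp_path):
        cfg = SimulationConfig(n_subjects=5, n_snps=2000, seed=4)
        g = simulate_genotypes(cfg)
        annot = simulate_annotation(g.snp_map, cfg)
        path = tmp_path / "genes.bed"
        write_bed(annot.gene_table, path)
        back = read_bed(path)
        pd.testing.assert_frame_equal(
            back.astype({"chrom": str}), annot.gene_table.astype({"chrom": str})
        )

    def test_scores_elevated_in_genes(self):
        cfg = SimulationConfig(n_subjects=5, n_snps=5000, frac_genic=0.5,
                               missing_score_fraction=0.0, seed=8)
        g = simulate_genotypes(cfg)
        annot = simulate_annotation(g.snp_map, cfg)
        s = annot.track.raw_score
        genic = annot.track.category == "genic"
        assert s[genic].mean() > s[~genic].mean() + 0.1


class TestPhenotype:
    def test_null_heritability(self):
        cfg = SimulationConfig(n_subjects=500, n_snps=300, h2_total=0.0,
                               h2_by_category={}, seed=6)
        g = simulate_genotypes(cfg)
        ph = simulate_phenotype(g, None, cfg)
        assert np.all(ph.genetic_values == 0)

    def test_variance_ratio_matches_target(self):
        cfg = SimulationConfig(
            n_subjects=2000, n_snps=1000, h2_total=0.45, h2_by_category={},
            causal_fraction_by_category={"all": 0.05}, covariate_effect_sd=0.0,
            seed=10,
        )
        g = simulate_genotypes(cfg)
        ph = simulate_phenotype(g, None, cfg)
        ratio = ph.genetic_values.var() / ph.phenotype.var()
        assert 0.40 < ratio < 0.50
        # exact rescaling: realized genetic variance equals the target
        assert ph.genetic_values.var() == pytest.approx(0.45, abs=1e-12)
        assert ph.phenotype.var() == pytest.approx(1.0, abs=0.1)

    def test_category_variances_in_ratio(self):
        cfg = SimulationConfig(
            n_subjects=1000, n_snps=2000, h2_total=0.40,
            h2_by_category={"genic": 0.30, "intergenic": 0.10},
            covariate_effect_sd=0.0, seed=12,
        )
        g = simulate_genotypes(cfg)
        annot = simulate_annotation(g.snp_map, cfg)
        ph = simulate_phenotype(g, annot.track, cfg)
        v_gen = ph.genetic_by_category["genic"].var()
        v_int = ph.genetic_by_category["intergenic"].var()
        # per-category exact rescale before the common total rescale keeps
        # the ratio at exactly 3:1
        assert v_gen / v_int == pytest.approx(3.0, rel=1e-9)

    def test_rescale_can_be_disabled(self):
        cfg = SimulationConfig(n_subjects=800, n_snps=500, h2_total=0.45,
                               h2_by_category={}, covariate_effect_sd=0.0, seed=13)
        g = simulate_genotypes(cfg)
        ph = simulate_phenotype(g, None, cfg, rescale_exact=False)
        assert ph.genetic_values.var() != pytest.approx(0.45, abs=1e-12)
        assert 0.2 < ph.genetic_values.var() < 0.7

    def test_zero_causal_snps_error(self):
        cfg = SimulationConfig(
            n_subjects=50, n_snps=100, h2_total=0.4, h2_by_category={},
            causal_fraction_by_category={"all": 0.0}, seed=1,
        )
        g = simulate_genotypes(cfg)
        with pytest.raises(ConfigurationError, match="zero causal"):
            simulate_phenotype(g, None, cfg)


class TestTwins:
    def test_perfect_heritability_limit(self):
        cfg = SimulationConfig(n_mz_pairs=2000, n_dz_pairs=2000,
                               ace_true=(1.0, 0.0, 0.0), seed=14)
        tw = simulate_twins(cfg)
        r_mz, r_dz = twin_correlations(tw)
        assert 0.98 < r_mz <= 1.0
        assert r_dz == pytest.approx(0.5, abs=0.05)

    def test_study_truth_recovers_printed_correlations(self):
        cfg = SimulationConfig(n_mz_pairs=5000, n_dz_pairs=5000,
                               ace_true=(0.60, 0.02, 0.38), seed=15)
        r_mz, r_dz = twin_correlations(simulate_twins(cfg))
        assert r_mz == pytest.approx(0.62, abs=0.02)
        assert r_dz == pytest.approx(0.32, abs=0.02)

    def test_no_familial_resemblance(self):
        cfg = SimulationConfig(n_mz_pairs=2000, n_dz_pairs=2000,
                               ace_true=(0.0, 0.0, 1.0), seed=16)
        r_mz, r_dz = twin_correlations(simulate_twins(cfg))
        assert abs(r_mz) < 0.05 and abs(r_dz) < 0.05


class TestPlantedRelatedness:
    def grm_entries(self, cfg):
        g = plant_relatedness(simulate_genotypes(cfg), cfg)
        grm = compute_grm(g)
        return [grm.values[2 * i, 2 * i + 1] for i in range(cfg.n_related_pairs)]

    def test_sibling_like_pairs(self):
        cfg = SimulationConfig(n_subjects=60, n_snps=5000, n_related_pairs=5,
                               related_kinship=0.5, maf_range=(0.2, 0.5), seed=17)
        entries = self.grm_entries(cfg)
        assert all(0.35 < e < 0.65 for e in entries)

    def test_no_pairs_identity(self):
        cfg = SimulationConfig(n_subjects=40, n_snps=200, n_related_pairs=0, seed=18)
        g = simulate_genotypes(cfg)
        assert plant_relatedness(g, cfg) is g

    def test_threshold_straddling_kinship(self):
        # n large enough that the -1/(n-1) in-sample centering bias of the
        # GRM off-diagonal is small against the planted 0.05 kinship
        cfg = SimulationConfig(n_subjects=500, n_snps=20000, block_size=10,
                               n_related_pairs=5, related_kinship=0.05,
                               maf_range=(0.2, 0.5), seed=19)
        entries = self.grm_entries(cfg)
        assert all(0.02 < e < 0.08 for e in entries)

    def test_invalid_kinship_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_subjects=40, n_snps=100, n_related_pairs=2,
                             related_kinship=1.5)
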