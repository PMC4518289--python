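"""Synthetic genotype, annotation, phenotype, relatedness and twin simulators.

Every downstream stage of the toolkit (QC, GRM, LD-weighted annotation,
GREML, twin ACE) is exercised on data from this module, so each generator is
built to have *known* ground truth:

* Genotypes are two haplotypes per subject.  Within an LD block, haplotype
  alleles follow a first-order Markov chain whose lag-1 allele correlation
  targets ``ld_rho`` (clipped, per adjacent pair, to the range attainable for
  binary variables with the two SNPs' allele frequencies); blocks are
  independent.  Genotype correlation between neighbouring SNPs therefore
  equals the haplotype allele correlation.
* The polygenic phenotype is built from standardized genotypes with
  category-specific effect variances, then the realized genetic values are
  rescaled so the realized heritability equals the target exactly
  (disable with ``rescale_exact=False``).
* Twin pairs are exchangeable bivariate normal with the correlations implied
  by the ACE truth: ``rMZ = a2 + c2``, ``rDZ = a2/2 + c2``.

All randomness flows through ``numpy.random.Generator`` streams derived from
``SimulationConfig.seed`` with a fixed per-operation salt, so each operation
is reproducible independently of call order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .datatypes import AnnotationTrack, ConfigurationError, GenotypeMatrix, TwinDataset

__all__ = [
    "simulate_genotypes",
    "simulate_annotation",
    "simulate_phenotype",
    "simulate_twins",
    "plant_relatedness",
    "SimulatedPhenotype",
]

# Per-operation salts for deriving independent substreams from one seed.
_SALT_GENO = 101
_SALT_ANNOT = 202
_SALT_PHENO = 303
_SALT_TWIN = 404
_SALT_RELATED = 505


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([salt, config.seed])


def _block_bounds(n_snps: int, block_size: int) -> np.ndarray:
    """Start indices of each LD block plus the terminal bound."""
    starts = np.arange(0, n_snps, block_size)
    return np.append(starts, n_snps)


def _markov_haplotypes(freqs: np.ndarray, bounds: np.ndarray, rho: float,
                       n_haplotypes: int, rng: np.random.Generator) -> np.ndarray:
    """Binary haplotypes with blockwise lag-1 Markov dependence.

    Margins are preserved exactly: P(allele) = freqs[t] at every site.  The
    lag-1 correlation is min(rho, feasible bound) for each adjacent pair.
    """
    m = len(freqs)
    hap = np.empty((n_haplotypes, m), dtype=np.uint8)
    block_starts = set(bounds[:-1].tolist())
    q = 1.0 - freqs
    for t in range(m):
        u = rng.random(n_haplotypes)
        if t in block_starts or rho == 0.0:
            hap[:, t] = u < freqs[t]
            continue
        p0, p1 = freqs[t - 1], freqs[t]
        # Largest correlation attainable for Bernoulli(p0), Bernoulli(p1)
        # with valid conditional probabilities.
        bound = min(
            np.sqrt(p0 * (1 - p1) / (q[t - 1] * p1)),
            np.sqrt(q[t - 1] * p1 / (p0 * (1 - p1))),
        )
        r = min(rho, bound)
        cov = r * np.sqrt(p0 * q[t - 1] * p1 * (1 - p1))
        prob_given1 = p1 + cov / p0
        prob_given0 = p1 - cov / q[t - 1]
        prev = hap[:, t - 1].astype(bool)
        hap[:, t] = u < np.where(prev, prob_given1, prob_given0)
    return hap


def simulate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Simulate LD-blocked common-SNP genotypes.

    Returns an ``n_subjects x n_snps`` dosage matrix in {0, 1, 2} built from
    two independent haplotypes per subject.  The SNP map places SNPs at
    consecutive 1-based positions (``bp_spacing`` apart) on one synthetic
    chromosome.  Haplotypes and block boundaries are retained on the result
    so that :func:`plant_relatedness` can operate afterwards.
    """
    config.validate()
    rng = rng if rng is not None else _rng(config, _SALT_GENO)
    n, m = config.n_subjects, config.n_snps
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    bounds = _block_bounds(m, config.block_size)
    hap = _markov_haplotypes(freqs, bounds, config.ld_rho, 2 * n, rng)
    dosages = (hap[0::2] + hap[1::2]).astype(float)
    snp_map = pd.DataFrame({
        "snp": [f"snp{i + 1:06d}" for i in range(m)],
        "chrom": config.chrom,
        "pos": (np.arange(m) + 1) * config.bp_spacing,
        "a1": "A",
        "a2": "C",
    })
    geno = GenotypeMatrix(
        subject_ids=[f"id{i + 1:05d}" for i in range(n)],
        snp_map=snp_map,
        dosages=dosages,
    )
    geno.haplotypes = hap
    geno.block_bounds = bounds
    return geno


@dataclass
class SimulatedAnnotation:
    """Conservation track (with genic/intergenic labels) plus the gene table."""

    track: AnnotationTrack
    gene_table: pd.DataFrame  # BED-style: chrom, start (0-based), end, name


def simulate_annotation(snp_map: pd.DataFrame, config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> SimulatedAnnotation:
    """Place synthetic genes and draw spatially structured conservation scores.

    Genes are non-overlapping intervals covering approximately ``frac_genic``
    of the SNP span, emitted as a BED-style table (0-based half-open).  Each
    SNP gets a phastCons-like conservation score drawn from a Beta
    distribution whose mean is elevated inside genes and varies smoothly by
    LD block; a fraction ``missing_score_fraction`` of scores is set missing.
    """
    config.validate()
    rng = rng if rng is not None else _rng(config, _SALT_ANNOT)
    if not snp_map["pos"].is_monotonic_increasing:
        raise ConfigurationError("snp_map positions must be sorted")
    pos = snp_map["pos"].to_numpy()
    m = len(pos)
    chrom = str(snp_map["chrom"].iloc[0])
    span_start, span_end = int(pos[0]), int(pos[-1]) + config.bp_spacing
    span = span_end - span_start

    frac = config.frac_genic
    genes: list[tuple[int, int]] = []
    if frac >= 1.0:
        genes = [(span_start, span_end)]
    elif frac > 0.0:
        # Alternate gene/gap segments with jittered lengths so that genes
        # cover ~frac of the span.
        n_genes = max(1, m // 200)
        mean_gene = span * frac / n_genes
        mean_gap = span * (1 - frac) / (n_genes + 1)
        cursor = float(span_start)
        while cursor < span_end:
            cursor += mean_gap * rng.uniform(0.5, 1.5)
            g0 = cursor
            cursor += mean_gene * rng.uniform(0.5, 1.5)
            g1 = min(cursor, span_end)
            if g1 > g0 and g0 < span_end:
                genes.append((int(g0), int(g1)))
    gene_table = pd.DataFrame(
        {
            "chrom": chrom,
            # internal 1-based closed [g0, g1] -> BED 0-based half-open
            "start": [g0 - 1 for g0, _ in genes],
            "end": [g1 for _, g1 in genes],
            "name": [f"gene{i + 1:04d}" for i in range(len(genes))],
        }
    )

    genic = np.zeros(m, dtype=bool)
    for g0, g1 in genes:
        genic |= (pos >= g0) & (pos <= g1)

    # Block-level smooth mean + genic elevation; Beta concentration kappa.
    bounds = _block_bounds(m, config.block_size)
    block_level = rng.uniform(-0.08, 0.08, size=len(bounds) - 1)
    mean = np.empty(m)
    for b in range(len(bounds) - 1):
        mean[bounds[b]:bounds[b + 1]] = block_level[b]
    mean += np.where(genic, 0.60, 0.30)
    mean = np.clip(mean, 0.05, 0.95)
    kappa = 8.0
    scores = rng.beta(kappa * mean, kappa * (1 - mean))
    if config.missing_score_fraction > 0:
        missing = rng.random(m) < config.missing_score_fraction
        scores[missing] = np.nan

    track = AnnotationTrack(
        snp_ids=list(snp_map["snp"]),
        raw_score=scores,
        category=np.where(genic, "genic", "intergenic").astype(object),
        name="conservation",
    )
    return SimulatedAnnotation(track=track, gene_table=gene_table)


@dataclass
class SimulatedPhenotype:
    """Phenotype + covariates plus the true genetic values for oracle tests."""

    table: pd.DataFrame               # iid, phenotype, age, sex, cohort
    genetic_values: np.ndarray        # total true genetic value per subject
    genetic_by_category: dict[str, np.ndarray]
    causal_snps: dict[str, np.ndarray]

    @property
    def phenotype(self) -> np.ndarray:
        return self.table["phenotype"].to_numpy()


def _standardize(dosages: np.ndarray) -> np.ndarray:
    p = np.nanmean(dosages, axis=0) / 2.0
    return (dosages - 2 * p) / np.sqrt(2 * p * (1 - p))


def simulate_phenotype(genotypes: GenotypeMatrix, annotation: AnnotationTrack | None,
                       config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       rescale_exact: bool = True) -> SimulatedPhenotype:
    """Simulate a polygenic phenotype with category-specific enrichment.

    ``y = sum_c g_c + f(age) + b_sex*sex + cohort effects + e`` where
    ``g_c = Z_c beta_c`` over the causal SNPs of category ``c`` with
    ``beta ~ N(0, h2_c / m_c)`` on standardized genotypes, and
    ``e ~ N(0, 1 - h2_total)``.  With ``rescale_exact`` the realized genetic
    variance is scaled to equal ``h2_total`` exactly (each category is first
    scaled to its own target, then all are scaled jointly).  The age effect
    is quadratic — deliberately nonlinear so that linear-only covariate
    adjustment is detectably insufficient.
    """
    config.validate()
    rng = rng if rng is not None else _rng(config, _SALT_PHENO)
    n = genotypes.n_subjects
    m = genotypes.n_snps

    categories = dict(config.h2_by_category) or {"all": config.h2_total}
    total = sum(categories.values())
    if abs(total - config.h2_total) > 1e-9:
        raise ConfigurationError(
            "h2_by_category must sum to h2_total for phenotype simulation "
            f"(got {total} vs {config.h2_total})"
        )
    labels = (annotation.category if annotation is not None and annotation.category
              is not None else np.array(["all"] * m, dtype=object))

    genetic_by_cat: dict[str, np.ndarray] = {}
    causal_by_cat: dict[str, np.ndarray] = {}
    g_total = np.zeros(n)
    for cat, h2_c in categories.items():
        idx = np.arange(m) if cat == "all" else np.flatnonzero(labels == cat)
        if h2_c == 0.0:
            genetic_by_cat[cat] = np.zeros(n)
            causal_by_cat[cat] = np.array([], dtype=int)
            continue
        if idx.size == 0:
            raise ConfigurationError(f"category {cat!r} absent from annotation")
        frac = config.causal_fraction_by_category.get(cat, 0.05)
        m_causal = int(round(frac * idx.size))
        if m_causal == 0:
            raise ConfigurationError(
                f"causal fraction {frac} yields zero causal SNPs in category "
                f"{cat!r} with h2={h2_c} > 0"
            )
        causal = rng.choice(idx, size=m_causal, replace=False)
        causal.sort()
        beta = rng.normal(0.0, np.sqrt(h2_c / m_causal), size=m_causal)
        z = _standardize(genotypes.dosages[:, causal])
        g_c = z @ beta
        if rescale_exact and g_c.var() > 0:
            g_c = g_c * np.sqrt(h2_c / g_c.var())
        genetic_by_cat[cat] = g_c
        causal_by_cat[cat] = causal
        g_total = g_total + g_c
    if rescale_exact and config.h2_total > 0 and g_total.var() > 0:
        scale = np.sqrt(config.h2_total / g_total.var())
        g_total = g_total * scale
        genetic_by_cat = {c: g * scale for c, g in genetic_by_cat.items()}
    if config.h2_total == 0.0:
        g_total = np.zeros(n)
        genetic_by_cat = {c: np.zeros(n) for c in categories}

    age = rng.uniform(10.0, 80.0, size=n)
    sex = rng.integers(0, 2, size=n)
    cohort = rng.integers(0, config.n_cohorts, size=n)
    c_sd = config.covariate_effect_sd
    cohort_shift = rng.normal(0.0, c_sd, size=config.n_cohorts) if c_sd > 0 else np.zeros(config.n_cohorts)
    covar_effect = (
        c_sd * ((age - 45.0) / 35.0) ** 2
        + 0.5 * c_sd * sex
        + cohort_shift[cohort]
    )
    e = rng.normal(0.0, np.sqrt(max(1.0 - config.h2_total, 0.0)), size=n)
    y = g_total + covar_effect + e

    table = pd.DataFrame({
        "iid": genotypes.subject_ids,
        "phenotype": y,
        "age": age,
        "sex": sex,
        "cohort": [f"cohort{c}" for c in cohort],
    })
    return SimulatedPhenotype(
        table=table,
        genetic_values=g_total,
        genetic_by_category=genetic_by_cat,
        causal_snps=causal_by_cat,
    )


def simulate_twins(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> TwinDataset:
    """Simulate MZ/DZ twin-pair phenotypes under the ACE truth.

    Pairs are exchangeable bivariate normal with unit marginal variance and
    correlation ``a2 + c2`` (MZ) or ``a2/2 + c2`` (DZ).
    """
    config.validate()
    rng = rng if rng is not None else _rng(config, _SALT_TWIN)
    a2, c2, _ = config.ace_true

    def pairs(n: int, r: float) -> np.ndarray:
        shared = rng.normal(size=(n, 1))
        unique = rng.normal(size=(n, 2))
        return np.sqrt(r) * shared + np.sqrt(1.0 - r) * unique

    return TwinDataset(
        mz=pairs(config.n_mz_pairs, a2 + c2),
        dz=pairs(config.n_dz_pairs, 0.5 * a2 + c2),
    )


def plant_relatedness(genotypes: GenotypeMatrix, config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Plant cryptic relatedness by sharing haplotype blocks between pairs.

    For each of ``n_related_pairs`` subject pairs ``(2i, 2i+1)``, the second
    subject's haplotypes are overwritten so that a fraction
    ``2 * related_kinship`` of LD blocks share one haplotype identically with
    the first subject (for kinship > 0.5, both haplotypes are shared on a
    fraction ``2k - 1`` of blocks and one on the rest).  A shared haplotype
    contributes 1/2 to the genomic relationship at the shared SNPs, so the
    expected GRM entry of a planted pair is ``related_kinship``.
    """
    config.validate()
    if config.n_related_pairs == 0:
        return genotypes
    if genotypes.haplotypes is None or genotypes.block_bounds is None:
        raise ConfigurationError(
            "plant_relatedness requires simulator-produced genotypes with haplotypes"
        )
    rng = rng if rng is not None else _rng(config, _SALT_RELATED)
    k = config.related_kinship
    hap = genotypes.haplotypes.copy()
    bounds = genotypes.block_bounds
    n_blocks = len(bounds) - 1
    for pair in range(config.n_related_pairs):
        a, b = 2 * pair, 2 * pair + 1
        u = rng.random(n_blocks)
        if 2 * k <= 1.0:
            n_share = np.where(u < 2 * k, 1, 0)
        else:
            n_share = np.where(u < 2 * k - 1.0, 2, 1)
        for blk in range(n_blocks):
            s, e = bounds[blk], bounds[blk + 1]
            if n_share[blk] >= 1:
                hap[2 * b, s:e] = hap[2 * a, s:e]
            if n_share[blk] == 2:
                hap[2 * b + 1, s:e] = hap[2 * a + 1, s:e]
    out = GenotypeMatrix(
        subject_ids=list(genotypes.subject_ids),
        snp_map=genotypes.snp_map.copy(),
        dosages=(hap[0::2] + hap[1::2]).astype(float),
        family_ids=list(genotypes.family_ids),
    )
    out.haplotypes = hap
    out.block_bounds = bounds
    return out
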