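"""Sample and SNP quality-control filters.

One QC pass applies, in a fixed documented order:

1. sample call-rate: drop samples missing more than ``miss_max`` of SNPs
   (strictly greater — a sample at exactly the threshold is retained);
2. minor allele frequency: drop SNPs with MAF below ``maf_min``;
3. Hardy–Weinberg equilibrium: drop SNPs whose 1-df chi-square test of
   observed vs expected genotype counts has P below ``hwe_alpha``;
4. heterozygosity outliers: drop samples whose heterozygosity rate lies more
   than ``het_sd`` standard deviations from the sample mean.

MAF uses mean dosage / 2 and therefore works for fractional (imputed)
dosages; the HWE and heterozygosity steps use hard calls only.  Because step
4 changes the sample set that steps 2–3 were computed on, a single pass is
not guaranteed idempotent; :func:`qc_filter_fixpoint` iterates to a fixpoint
(at most ``max_passes`` rounds).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, HeritkitError, QCReport

__all__ = ["qc_filter", "qc_filter_fixpoint", "hwe_chisq", "filter_imputation_quality"]


def hwe_chisq(n_hom_a: int, n_het: int, n_hom_b: int) -> tuple[float, float]:
    """1-df chi-square HWE test from genotype counts.

    Returns ``(chi2, p_value)``.  Monomorphic counts fit HWE exactly
    (chi2 = 0); zero-expected cells with zero observed contribute nothing.
    """
    counts = np.array([n_hom_a, n_het, n_hom_b], dtype=float)
    n = counts.sum()
    if n == 0:
        return 0.0, 1.0
    p = (2 * n_hom_a + n_het) / (2 * n)
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _one_pass(genotypes: GenotypeMatrix, miss_max: float, maf_min: float,
              hwe_alpha: float, het_sd: float):
    d = genotypes.dosages
    n, m = d.shape
    removed_samples: list[tuple[str, str]] = []
    removed_snps: list[tuple[str, str]] = []

    # 1. sample missingness (strict >)
    miss_rate = np.isnan(d).mean(axis=1)
    drop_sample = miss_rate > miss_max
    removed_samples += [(genotypes.subject_ids[i], "missingness")
                        for i in np.flatnonzero(drop_sample)]
    keep_s = ~drop_sample
    d = d[keep_s]
    ids = [s for s, k in zip(genotypes.subject_ids, keep_s) if k]
    fids = [s for s, k in zip(genotypes.family_ids, keep_s) if k]

    if d.shape[0] == 0:
        raise HeritkitError("empty after QC: all samples removed by missingness filter")

    # 2. MAF (mean dosage / 2; strict <)
    freq = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    drop_maf = maf < maf_min
    # 3. HWE on hard calls, among SNPs surviving MAF
    hard = np.where(np.isin(d, [0.0, 1.0, 2.0]), d, np.nan)
    n0 = np.nansum(hard == 0, axis=0)
    n1 = np.nansum(hard == 1, axis=0)
    n2 = np.nansum(hard == 2, axis=0)
    drop_hwe = np.zeros(d.shape[1], dtype=bool)
    for j in np.flatnonzero(~drop_maf):
        _, pval = hwe_chisq(int(n2[j]), int(n1[j]), int(n0[j]))
        drop_hwe[j] = pval < hwe_alpha
    snp_ids = genotypes.snp_map["snp"].to_numpy()
    removed_snps += [(snp_ids[j], "maf") for j in np.flatnonzero(drop_maf)]
    removed_snps += [(snp_ids[j], "hwe") for j in np.flatnonzero(drop_hwe)]
    keep_m = ~(drop_maf | drop_hwe)
    d = d[:, keep_m]
    hard = hard[:, keep_m]
    if d.shape[1] == 0:
        raise HeritkitError("empty after QC: all SNPs removed by MAF/HWE filters")

    # 4. heterozygosity outliers on the retained set (hard calls)
    n_called = (~np.isnan(hard)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        het_rate = np.nansum(hard == 1, axis=1) / np.maximum(n_called, 1)
    mu, sd = het_rate.mean(), het_rate.std()
    drop_het = np.zeros(d.shape[0], dtype=bool)
    if sd > 0:
        drop_het = np.abs(het_rate - mu) > het_sd * sd
    removed_samples += [(ids[i], "heterozygosity") for i in np.flatnonzero(drop_het)]
    keep_s2 = ~drop_het
    d = d[keep_s2]
    ids = [s for s, k in zip(ids, keep_s2) if k]
    fids = [s for s, k in zip(fids, keep_s2) if k]
    if d.shape[0] == 0:
        raise HeritkitError("empty after QC: all samples removed by heterozygosity filter")

    out = GenotypeMatrix(
        subject_ids=ids,
        snp_map=genotypes.snp_map.loc[keep_m].reset_index(drop=True),
        dosages=d,
        family_ids=fids,
    )
    return out, removed_samples, removed_snps


def qc_filter(genotypes: GenotypeMatrix, miss_max: float = 0.05,
              maf_min: float = 0.01, hwe_alpha: float = 1e-6,
              het_sd: float = 5.0) -> tuple[GenotypeMatrix, QCReport]:
    """Apply one ordered QC pass; see the module docstring for the order."""
    if genotypes.n_subjects < 2 or genotypes.n_snps < 1:
        raise HeritkitError("QC requires at least 2 subjects and 1 SNP")
    out, rs, rm = _one_pass(genotypes, miss_max, maf_min, hwe_alpha, het_sd)
    report = QCReport(
        removed_samples=pd.DataFrame(rs, columns=["id", "reason"]),
        removed_snps=pd.DataFrame(rm, columns=["id", "reason"]),
        thresholds={"miss_max": miss_max, "maf_min": maf_min,
                    "hwe_alpha": hwe_alpha, "het_sd": het_sd},
        n_samples_before=genotypes.n_subjects,
        n_samples_after=out.n_subjects,
        n_snps_before=genotypes.n_snps,
        n_snps_after=out.n_snps,
    )
    return out, report


def qc_filter_fixpoint(genotypes: GenotypeMatrix, max_passes: int = 5,
                       **thresholds) -> tuple[GenotypeMatrix, QCReport]:
    """Iterate :func:`qc_filter` until nothing more is removed (<= max_passes)."""
    all_samples: list[pd.DataFrame] = []
    all_snps: list[pd.DataFrame] = []
    current = genotypes
    used = {}
    n_pass = 0
    for n_pass in range(1, max_passes + 1):
        nxt, report = qc_filter(current, **thresholds)
        used = report.thresholds
        all_samples.append(report.removed_samples)
        all_snps.append(report.removed_snps)
        if nxt.n_subjects == current.n_subjects and nxt.n_snps == current.n_snps:
            current = nxt
            break
        current = nxt
    else:
        raise HeritkitError(f"QC did not reach a fixpoint in {max_passes} passes")
    return current, QCReport(
        removed_samples=pd.concat(all_samples, ignore_index=True),
        removed_snps=pd.concat(all_snps, ignore_index=True),
        thresholds=used,
        n_samples_before=genotypes.n_subjects,
        n_samples_after=current.n_subjects,
        n_snps_before=genotypes.n_snps,
        n_snps_after=current.n_snps,
        passes=n_pass,
    )


def filter_imputation_quality(genotypes: GenotypeMatrix, r2_min: float = 0.5,
                              column: str = "impute_r2") -> GenotypeMatrix:
    """Drop SNPs whose imputation-quality metric falls at or below ``r2_min``.

    A column filter on an optional per-SNP quality field in the SNP map;
    SNPs without the field are kept.
    """
    if column not in genotypes.snp_map.columns:
        return genotypes
    quality = genotypes.snp_map[column].to_numpy(dtype=float)
    keep = np.isnan(quality) | (quality > r2_min)
    return genotypes.subset(snps=np.flatnonzero(keep))
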