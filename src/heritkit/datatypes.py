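"""Core in-memory containers shared across the toolkit.

Conventions
-----------
* Dosages are counts of the A1 allele in ``{0, 1, 2}`` (``numpy.nan`` for a
  missing call); imputed data may carry fractional values in ``[0, 2]``.
* All internal genomic positions are 1-based and closed; BED input/output is
  converted at the boundary (see :mod:`heritkit.annotation`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HeritkitError",
    "ConfigurationError",
    "FormatError",
    "GenotypeMatrix",
    "GRMResult",
    "AnnotationTrack",
    "LDMatrix",
    "QCReport",
    "TwinDataset",
]

SNP_MAP_COLUMNS = ["snp", "chrom", "pos", "a1", "a2"]


class HeritkitError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(HeritkitError, ValueError):
    """Invalid user-supplied configuration or parameters."""


class FormatError(HeritkitError, ValueError):
    """Malformed input file (bad magic bytes, truncation, dimension mismatch)."""


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs allele-dosage matrix plus SNP map metadata.

    Parameters
    ----------
    subject_ids
        Ordered subject identifiers (IID strings).
    snp_map
        DataFrame with columns ``snp, chrom, pos, a1, a2``; positions 1-based,
        nondecreasing within each chromosome.
    dosages
        ``(n_subjects, n_snps)`` float array of A1-allele counts, ``nan``
        for missing.
    family_ids
        Optional FID column; defaults to the subject ids.
    """

    subject_ids: list[str]
    snp_map: pd.DataFrame
    dosages: np.ndarray
    family_ids: list[str] | None = None
    # Haplotype-level detail retained by the simulator so that relatedness can
    # be planted after the fact; (2n, M) uint8 array and block boundaries.
    haplotypes: np.ndarray | None = field(default=None, repr=False)
    block_bounds: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ConfigurationError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        if len(self.subject_ids) != n:
            raise ConfigurationError(
                f"{len(self.subject_ids)} subject ids but {n} dosage rows"
            )
        if len(self.snp_map) != m:
            raise ConfigurationError(
                f"{len(self.snp_map)} SNP-map rows but {m} dosage columns"
            )
        missing_cols = [c for c in SNP_MAP_COLUMNS if c not in self.snp_map.columns]
        if missing_cols:
            raise ConfigurationError(f"snp_map lacks columns {missing_cols}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ConfigurationError("dosage values must lie in [0, 2] or be nan")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ConfigurationError("positions must be nondecreasing per chromosome")
        if self.family_ids is None:
            self.family_ids = list(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """In-sample A1 allele frequency per SNP (mean dosage / 2, missing skipped)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(self, subjects: np.ndarray | None = None, snps: np.ndarray | None = None
               ) -> "GenotypeMatrix":
        """Return a copy restricted to the given subject / SNP index arrays."""
        subj_idx = np.arange(self.n_subjects) if subjects is None else np.asarray(subjects)
        snp_idx = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            subject_ids=[self.subject_ids[i] for i in subj_idx],
            snp_map=self.snp_map.iloc[snp_idx].reset_index(drop=True),
            dosages=self.dosages[np.ix_(subj_idx, snp_idx)].copy(),
            family_ids=[self.family_ids[i] for i in subj_idx],
        )


@dataclass
class GRMResult:
    """Symmetric genetic-relationship matrix with per-pair SNP counts."""

    subject_ids: list[str]
    values: np.ndarray
    pair_snp_counts: np.ndarray
    n_snps_total: int
    family_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.subject_ids)
        if self.values.shape != (n, n):
            raise ConfigurationError("GRM shape does not match subject ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ConfigurationError("GRM must be symmetric within 1e-12")
        if self.family_ids is None:
            self.family_ids = list(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclass
class AnnotationTrack:
    """Per-SNP raw and LD-weighted annotation scores plus category labels.

    ``raw_score`` is a phastCons-style value in [0, 1] or a {0, 1} genic
    indicator; ``nan`` marks SNPs without a score.  ``category`` holds one
    label per SNP (empty string for unlabelled/excluded SNPs).
    """

    snp_ids: list[str]
    raw_score: np.ndarray
    ld_weighted_score: np.ndarray | None = None
    category: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        self.raw_score = np.asarray(self.raw_score, dtype=float)
        if self.raw_score.shape != (m,):
            raise ConfigurationError("raw_score length must equal SNP count")
        if self.ld_weighted_score is not None:
            self.ld_weighted_score = np.asarray(self.ld_weighted_score, dtype=float)
            if self.ld_weighted_score.shape != (m,):
                raise ConfigurationError("ld_weighted_score length must equal SNP count")
        if self.category is not None:
            self.category = np.asarray(self.category, dtype=object)
            if self.category.shape != (m,):
                raise ConfigurationError("category length must equal SNP count")

    def scores(self) -> np.ndarray:
        """LD-weighted scores when present, raw scores otherwise."""
        return self.ld_weighted_score if self.ld_weighted_score is not None else self.raw_score


@dataclass
class LDMatrix:
    """Sparse symmetric pairwise r^2 restricted to a base-pair window.

    ``values`` is a ``scipy.sparse`` matrix with unit diagonal; entries exist
    only for same-chromosome pairs within ``window_bp``.
    """

    snp_ids: list[str]
    values: "object"
    window_bp: int


@dataclass
class QCReport:
    """Record of sample/SNP removals from one QC pass (or fixpoint run)."""

    removed_samples: pd.DataFrame  # columns: id, reason
    removed_snps: pd.DataFrame     # columns: id, reason
    thresholds: dict
    n_samples_before: int
    n_samples_after: int
    n_snps_before: int
    n_snps_after: int
    passes: int = 1

    def __post_init__(self) -> None:
        if self.n_samples_before - len(self.removed_samples) != self.n_samples_after:
            raise ConfigurationError("sample counts inconsistent with removal list")
        if self.n_snps_before - len(self.removed_snps) != self.n_snps_after:
            raise ConfigurationError("SNP counts inconsistent with removal list")

    def to_frame(self) -> pd.DataFrame:
        """Removals as one tidy table (kind, id, reason)."""
        samples = self.removed_samples.assign(kind="sample")
        snps = self.removed_snps.assign(kind="snp")
        return pd.concat([samples, snps], ignore_index=True)[["kind", "id", "reason"]]


@dataclass
class TwinDataset:
    """MZ/DZ twin-pair phenotypes.

    ``mz`` and ``dz`` are ``(n_pairs, 2)`` arrays of the two co-twins'
    phenotype values (assumed covariate-adjusted upstream).
    """

    mz: np.ndarray
    dz: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.dz = np.asarray(self.dz, dtype=float)
        for name, arr in (("mz", self.mz), ("dz", self.dz)):
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ConfigurationError(f"{name} pairs must be an (n, 2) array")
            if not np.isfinite(arr).all():
                raise ConfigurationError(f"{name} phenotypes must be finite")

    @property
    def n_mz(self) -> int:
        return self.mz.shape[0]

    @property
    def n_dz(self) -> int:
        return self.dz.shape[0]
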