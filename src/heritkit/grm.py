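"""Genetic relationship matrix, relatedness pruning, and GRM-based PCA.

The GRM estimator is the standard allele-frequency-standardized form.  For
subjects ``j != k``::

    A_jk = (1 / M_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

over SNPs non-missing in both subjects (``M_jk`` of them), with the
inbreeding-adjusted diagonal::

    A_jj = 1 + (1 / M_j) * sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i (1 - p_i))

``p_i`` is the in-sample A1 allele frequency.  Binary I/O is bit-compatible
with the GCTA triple (``.grm.bin`` / ``.grm.N.bin`` / ``.grm.id``):
single-precision lower-triangle streams plus a two-column id file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import FormatError, GenotypeMatrix, GRMResult, HeritkitError

__all__ = ["compute_grm", "prune_related", "grm_pca", "read_grm_bin", "write_grm_bin"]


def compute_grm(genotypes: GenotypeMatrix) -> GRMResult:
    """Compute the GRM with per-pair SNP counts (missing-aware).

    Raises if any SNP is monomorphic in-sample — such SNPs carry no
    relationship information and should have been removed by the MAF filter.
    """
    d = genotypes.dosages
    p = np.nanmean(d, axis=0) / 2.0
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        names = genotypes.snp_map["snp"].to_numpy()[mono][:5]
        raise HeritkitError(
            f"monomorphic SNP(s) reached GRM stage (e.g. {', '.join(map(str, names))}); "
            "apply the MAF filter first"
        )
    denom = 2.0 * p * (1.0 - p)
    observed = ~np.isnan(d)
    x = np.where(observed, d, 0.0)
    w = (x - 2.0 * p) / np.sqrt(denom)
    w[~observed] = 0.0
    numer = w @ w.T
    counts = observed.astype(float) @ observed.astype(float).T
    if (counts < 1).any():
        raise HeritkitError("some subject pair shares no non-missing SNP")
    values = numer / counts
    # inbreeding-adjusted diagonal
    with np.errstate(invalid="ignore"):
        diag_terms = (d * d - (1.0 + 2.0 * p) * d + 2.0 * p * p) / denom
    diag_counts = observed.sum(axis=1)
    diag = 1.0 + np.nansum(diag_terms, axis=1) / diag_counts
    np.fill_diagonal(values, diag)
    np.fill_diagonal(counts, diag_counts)
    values = (values + values.T) / 2.0
    return GRMResult(
        subject_ids=list(genotypes.subject_ids),
        values=values,
        pair_snp_counts=counts,
        n_snps_total=genotypes.n_snps,
        family_ids=list(genotypes.family_ids),
    )


def prune_related(grm: GRMResult, threshold: float) -> list[str]:
    """Greedily drop subjects until no off-diagonal entry exceeds ``threshold``.

    While any pair sits strictly above the threshold, the subject involved in
    the most such pairs is removed (ties broken by removing the later subject
    in input order).  Returns the kept subject ids in input order.
    """
    if threshold <= 0:
        raise HeritkitError("prune threshold must be positive")
    n = grm.n_subjects
    adj = grm.values > threshold
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    while True:
        degrees = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        if degrees.max(initial=0) == 0:
            break
        worst = degrees.max()
        # later subject in input order among the maximum-degree candidates
        victim = np.flatnonzero((degrees == worst) & alive)[-1]
        alive[victim] = False
    return [grm.subject_ids[i] for i in np.flatnonzero(alive)]


def grm_pca(grm: GRMResult, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Top-``k`` eigenvectors of the GRM for use as ancestry covariates.

    Returns ``(vectors, eigenvalues)`` with unit-norm columns in
    eigenvalue-descending order; each column's largest-magnitude loading is
    made positive (deterministic sign convention).
    """
    n = grm.n_subjects
    if k >= n:
        raise HeritkitError(f"k={k} must be smaller than the sample size {n}")
    eigvals, eigvecs = np.linalg.eigh(grm.values)
    order = np.argsort(eigvals)[::-1][:k]
    vals = eigvals[order]
    vecs = eigvecs[:, order]
    for j in range(vecs.shape[1]):
        lead = np.argmax(np.abs(vecs[:, j]))
        if vecs[lead, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs, vals


def _tril_stream(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    idx = np.tril_indices(n)
    return values[idx].astype(np.float32)


def write_grm_bin(grm: GRMResult, prefix: str | Path) -> None:
    """Write the GCTA binary triple ``prefix.grm.bin/.grm.N.bin/.grm.id``."""
    prefix = Path(prefix)
    with open(f"{prefix}.grm.bin", "wb") as fh:
        fh.write(_tril_stream(grm.values).tobytes())
    with open(f"{prefix}.grm.N.bin", "wb") as fh:
        fh.write(_tril_stream(grm.pair_snp_counts).tobytes())
    pd.DataFrame({"fid": grm.family_ids, "iid": grm.subject_ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm_bin(prefix: str | Path) -> GRMResult:
    """Read a GCTA binary GRM triple."""
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None,
                      names=["fid", "iid"], dtype=str)
    n = len(ids)
    n_tri = n * (n + 1) // 2
    vals = np.fromfile(f"{prefix}.grm.bin", dtype=np.float32)
    if len(vals) != n_tri:
        raise FormatError(
            f"{prefix}.grm.bin holds {len(vals)} floats but id file implies {n_tri}"
        )
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype=np.float32)
    if len(counts) not in (n_tri, 1):
        raise FormatError(f"{prefix}.grm.N.bin has unexpected length {len(counts)}")
    if len(counts) == 1:  # GCTA may store a single overall count
        counts = np.full(n_tri, counts[0], dtype=np.float32)
    values = np.zeros((n, n))
    count_mat = np.zeros((n, n))
    idx = np.tril_indices(n)
    values[idx] = vals
    count_mat[idx] = counts
    values = values + np.tril(values, -1).T
    count_mat = count_mat + np.tril(count_mat, -1).T
    return GRMResult(
        subject_ids=list(ids["iid"]),
        values=values,
        pair_snp_counts=count_mat,
        n_snps_total=int(count_mat.max()),
        family_ids=list(ids["fid"]),
    )
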