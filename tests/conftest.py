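"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from heritkit import GenotypeMatrix, SimulationConfig, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_genotypes(n: int, m: int, rng: np.random.Generator,
                   freqs: np.ndarray | None = None,
                   missing_rate: float = 0.0) -> GenotypeMatrix:
    """Independent-SNP genotype fixture (binomial dosages, no LD)."""
    if freqs is None:
        freqs = rng.uniform(0.1, 0.5, size=m)
    d = rng.binomial(2, freqs, size=(n, m)).astype(float)
    for _ in range(100):  # redraw columns that came out monomorphic
        p = d.mean(axis=0) / 2
        mono = (p <= 0) | (p >= 1)
        if not mono.any():
            break
        d[:, mono] = rng.binomial(2, freqs[mono], size=(n, mono.sum()))
    if missing_rate > 0:
        d[rng.random((n, m)) < missing_rate] = np.nan
    snp_map = pd.DataFrame({
        "snp": [f"snp{i}" for i in range(m)],
        "chrom": "1",
        "pos": np.arange(1, m + 1) * 1000,
        "a1": "A",
        "a2": "C",
    })
    return GenotypeMatrix(
        subject_ids=[f"s{i}" for i in range(n)], snp_map=snp_map, dosages=d
    )


@pytest.fixture
def small_genotypes(rng):
    return make_genotypes(50, 200, rng)


@pytest.fixture
def ld_genotypes():
    """Simulator-produced genotypes with blockwise LD."""
    cfg = SimulationConfig(n_subjects=300, n_snps=600, block_size=10,
                           ld_rho=0.6, seed=42)
    return simulate_genotypes(cfg)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_grm(dosages: np.ndarray):
    """Two-loop GRM estimator: off-diagonal standardized cross-products over
    pairwise-complete SNPs, inbreeding-adjusted diagonal."""
    n, m = dosages.shape
    p = np.nanmean(dosages, axis=0) / 2.0
    denom = 2.0 * p * (1.0 - p)
    a = np.zeros((n, n))
    counts = np.zeros((n, n))
    for j in range(n):
        terms = []
        for i in range(m):
            x = dosages[j, i]
            if np.isnan(x):
                continue
            terms.append((x * x - (1 + 2 * p[i]) * x + 2 * p[i] ** 2) / denom[i])
        a[j, j] = 1.0 + np.mean(terms)
        counts[j, j] = len(terms)
        for k in range(j + 1, n):
            acc, cnt = 0.0, 0
            for i in range(m):
                xj, xk = dosages[j, i], dosages[k, i]
                if np.isnan(xj) or np.isnan(xk):
                    continue
                acc += (xj - 2 * p[i]) * (xk - 2 * p[i]) / denom[i]
                cnt += 1
            a[j, k] = a[k, j] = acc / cnt
            counts[j, k] = counts[k, j] = cnt
    return a, counts


def mvn_reml_loglik(y: np.ndarray, x: np.ndarray, v: np.ndarray) -> float:
    """Direct error-contrast REML evaluation: the Gaussian log-density of
    K'y with covariance K'VK, K an orthonormal basis of the orthogonal
    complement of col(X).  Reported in the same convention as
    ``heritkit.reml.reml_loglik``: since
    ``log|K'VK| = log|V| + log|X'V^-1X| - log|X'X|`` for orthonormal K, the
    fixed ``-1/2 log|X'X|`` restores equality."""
    from scipy.linalg import null_space

    k = null_space(x.T)
    kvk = k.T @ v @ k
    ky = k.T @ y
    sign, logdet = np.linalg.slogdet(kvk)
    assert sign > 0
    quad = ky @ np.linalg.solve(kvk, ky)
    _, logdet_xx = np.linalg.slogdet(x.T @ x)
    return -0.5 * (logdet + quad) - 0.5 * logdet_xx


def brute_force_genic(positions: np.ndarray, gene_table: pd.DataFrame,
                      flank_bp: int) -> np.ndarray:
    """Per-SNP genic flag by scanning every (flanked) gene interval."""
    flags = np.zeros(len(positions), dtype=bool)
    for _, gene in gene_table.iterrows():
        lo = gene["start"] + 1 - flank_bp  # BED -> 1-based closed
        hi = gene["end"] + flank_bp
        flags |= (positions >= lo) & (positions <= hi)
    return flags


def exhaustive_max_kept(values: np.ndarray, threshold: float) -> int:
    """Size of the largest subject subset with no pair above threshold
    (exhaustive search; use only for n <= 12)."""
    from itertools import combinations

    n = values.shape[0]
    adj = values > threshold
    np.fill_diagonal(adj, False)
    for size in range(n, 0, -1):
        for subset in combinations(range(n), size):
            idx = np.array(subset)
            if not adj[np.ix_(idx, idx)].any():
                return size
    return 0


def exact_correlation_tracks(rng: np.random.Generator, n: int, r: float):
    """Two vectors with *exact* sample correlation r (Gram-Schmidt)."""
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x
    z /= z.std()
    y = r * x + np.sqrt(1 - r * r) * z
    return x, y
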