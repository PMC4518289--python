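"""PLINK-format genotype I/O plus the transparent TSV dosage dialect.

The binary .bed layout is the standard SNP-major encoding: three magic bytes
``0x6c 0x1b 0x01`` followed by ``ceil(n/4)`` bytes per SNP, four genotypes
per byte packed low bits first, with two-bit codes

====  ==========================  ==============
bits  genotype                    A1 dosage
====  ==========================  ==============
00    homozygous A1/A1            2
01    missing                     nan
10    heterozygous                1
11    homozygous A2/A2            0
====  ==========================  ==============

Round trips are lossless for hard calls; fractional (imputed) dosages only
travel through the TSV dialect.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import FormatError, GenotypeMatrix

__all__ = [
    "read_plink",
    "write_plink",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_phenotype",
    "write_phenotype",
    "read_covariates",
    "write_covariates",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


def _ext(prefix: Path, ext: str) -> Path:
    # not Path.with_suffix: prefixes like "run0.1" must keep their dot
    return prefix.with_name(prefix.name + ext)


# code -> dosage lookup for the four 2-bit genotype codes
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam (SNP-major bed, hard calls only)."""
    prefix = Path(prefix)
    n, m = genotypes.n_subjects, genotypes.n_snps
    d = genotypes.dosages
    hard = np.where(np.isnan(d), -1, d)
    if not np.isin(hard, [-1, 0, 1, 2]).all():
        raise FormatError("PLINK bed holds hard calls only; dosages must be {0,1,2,nan}")
    # dosage -> 2-bit code; index by dosage+1 so missing (-1) maps to code 01
    dose_to_code = np.array([0b01, 0b11, 0b10, 0b00], dtype=np.uint8)
    codes = dose_to_code[(hard + 1).astype(int)]  # (n, m)
    n_bytes = math.ceil(n / 4)
    padded = np.zeros((4 * n_bytes, m), dtype=np.uint8)
    padded[:n] = codes
    shifted = (
        padded[0::4]
        | (padded[1::4] << 2)
        | (padded[2::4] << 4)
        | (padded[3::4] << 6)
    )  # (n_bytes, m)
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(shifted.T.tobytes())  # SNP-major: all bytes of SNP 0, then SNP 1, ...

    bim = pd.DataFrame({
        "chrom": genotypes.snp_map["chrom"],
        "snp": genotypes.snp_map["snp"],
        "cm": 0,
        "pos": genotypes.snp_map["pos"],
        "a1": genotypes.snp_map["a1"],
        "a2": genotypes.snp_map["a2"],
    })
    bim.to_csv(_ext(prefix, ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": genotypes.family_ids,
        "iid": genotypes.subject_ids,
        "pid": 0,
        "mid": 0,
        "sex": 0,
        "pheno": -9,
    })
    fam.to_csv(_ext(prefix, ".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read ``prefix``.bed/.bim/.fam into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    bed_path = _ext(prefix, ".bed")
    for ext in (".bed", ".bim", ".fam"):
        if not _ext(prefix, ext).exists():
            raise FormatError(f"missing PLINK file {_ext(prefix, ext)}")
    bim = pd.read_csv(
        _ext(prefix, ".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        _ext(prefix, ".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"{bed_path}: bad magic bytes {raw[:3].hex()} at offset 0 "
            f"(expected {_BED_MAGIC.hex()}: SNP-major PLINK bed)"
        )
    n_bytes = math.ceil(n / 4)
    expected = 3 + n_bytes * m
    if len(raw) != expected:
        raise FormatError(
            f"{bed_path}: {len(raw)} bytes but .bim/.fam imply {expected} "
            f"({m} SNPs x {n_bytes} bytes + 3 magic); truncated or mismatched"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, n_bytes)
    codes = np.empty((m, 4 * n_bytes), dtype=np.uint8)
    codes[:, 0::4] = data & 0b11
    codes[:, 1::4] = (data >> 2) & 0b11
    codes[:, 2::4] = (data >> 4) & 0b11
    codes[:, 3::4] = (data >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m)
    snp_map = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(
        subject_ids=list(fam["iid"]),
        snp_map=snp_map,
        dosages=dosages,
        family_ids=list(fam["fid"]),
    )


def _snpmap_path(path: Path) -> Path:
    return path.with_name(path.name + ".snpmap.tsv")


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write the transparent TSV dialect: header ``id`` + SNP ids, one row
    per subject, ``NA`` for missing; fractional dosages allowed.  The SNP map
    goes to a sibling ``<name>.snpmap.tsv``."""
    path = Path(path)
    frame = pd.DataFrame(genotypes.dosages, columns=genotypes.snp_map["snp"])
    frame.insert(0, "id", genotypes.subject_ids)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")
    genotypes.snp_map.to_csv(_snpmap_path(path), sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=["NA"])
    if frame.columns[0] != "id":
        raise FormatError(f"{path}: first column must be 'id'")
    map_path = _snpmap_path(path)
    if map_path.exists():
        snp_map = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    else:
        snps = list(frame.columns[1:])
        snp_map = pd.DataFrame({
            "snp": snps, "chrom": "1", "pos": np.arange(1, len(snps) + 1),
            "a1": "A", "a2": "C",
        })
    return GenotypeMatrix(
        subject_ids=list(frame["id"]),
        snp_map=snp_map,
        dosages=frame.iloc[:, 1:].to_numpy(dtype=float),
    )


def write_phenotype(path: str | Path, fids, iids, values) -> None:
    """PLINK-style phenotype file: ``FID IID value`` (no header)."""
    pd.DataFrame({"fid": fids, "iid": iids, "value": values}).to_csv(
        path, sep=" ", header=False, index=False
    )


def read_phenotype(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None,
                       names=["fid", "iid", "value"], dtype={"fid": str, "iid": str})


def write_covariates(path: str | Path, fids, iids, covariates: pd.DataFrame) -> None:
    """Whitespace-delimited covariate file: ``FID IID cov1 cov2 ...`` with header."""
    out = covariates.copy()
    out.insert(0, "IID", list(iids))
    out.insert(0, "FID", list(fids))
    out.to_csv(path, sep=" ", index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", dtype={"FID": str, "IID": str})
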