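"""Genic and conservation annotation, LD-weighted scores, and SNP partitions.

Coordinate conventions are centralized here: BED input/output is 0-based
half-open; every internal position is 1-based closed.  A SNP is genic iff
its position lies within ``[gene_start - flank_bp, gene_end + flank_bp]``
(closed interval, flanks applied to the gene span).

The LD-weighted score of SNP ``i`` is the self-inclusive r^2-weighted
average over scored SNPs within the window::

    s~_i = sum_j r2_ij s_j / sum_j r2_ij      (r2_ii = 1)

which keeps scores on the raw scale (a constant score vector is invariant);
the raw matrix-vector product is available with ``normalize=False``.  SNPs
with a missing raw score and no scored LD partner keep a missing weighted
score and drop out of later partitioning.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .datatypes import AnnotationTrack, GenotypeMatrix, HeritkitError, LDMatrix

__all__ = [
    "annotate_genic",
    "compute_ld_matrix",
    "ld_weight_scores",
    "median_split",
    "score_correlation",
    "build_partition",
    "read_bed",
    "write_bed",
    "read_scores_tsv",
    "write_scores_tsv",
    "write_partition_tsv",
]


# ---------------------------------------------------------------------------
# genic annotation
# ---------------------------------------------------------------------------

def annotate_genic(snp_map: pd.DataFrame, gene_table: pd.DataFrame,
                   flank_bp: int = 20_000) -> AnnotationTrack:
    """Label each SNP genic/intergenic from a BED-style gene table.

    ``gene_table`` is 0-based half-open (columns ``chrom, start, end`` and
    optionally ``name``); a gene ``[start, end)`` becomes the 1-based closed
    span ``[start + 1, end]``, extended by ``flank_bp`` on both sides.
    An empty table yields all-intergenic.  A non-empty table whose
    chromosomes are disjoint from the SNP map's raises, listing the
    unmatched names.
    """
    bad = gene_table[gene_table["start"] >= gene_table["end"]] if len(gene_table) else gene_table
    if len(bad):
        raise HeritkitError(f"invalid gene intervals (start >= end): {bad.head().to_dict('records')}")
    snp_chroms = set(map(str, snp_map["chrom"].unique()))
    m = len(snp_map)
    genic = np.zeros(m, dtype=bool)
    if len(gene_table):
        gene_chroms = set(map(str, gene_table["chrom"].unique()))
        if not (gene_chroms & snp_chroms):
            raise HeritkitError(
                "no gene-table chromosome matches the SNP map; unmatched: "
                f"gene table {sorted(gene_chroms)} vs SNP map {sorted(snp_chroms)}"
            )
        for chrom, genes in gene_table.groupby("chrom"):
            sel = snp_map["chrom"].astype(str) == str(chrom)
            if not sel.any():
                continue
            pos = snp_map.loc[sel, "pos"].to_numpy()
            # BED -> 1-based closed, then flank
            starts = genes["start"].to_numpy() + 1 - flank_bp
            ends = genes["end"].to_numpy() + flank_bp
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            merged_s, merged_e = [], []
            for s, e in zip(starts, ends):
                if merged_e and s <= merged_e[-1] + 1:
                    merged_e[-1] = max(merged_e[-1], e)
                else:
                    merged_s.append(s)
                    merged_e.append(e)
            ms = np.asarray(merged_s)
            me = np.asarray(merged_e)
            idx = np.searchsorted(ms, pos, side="right") - 1
            inside = (idx >= 0) & (pos <= me[np.clip(idx, 0, len(me) - 1)])
            genic[np.flatnonzero(sel)[inside]] = True
    return AnnotationTrack(
        snp_ids=list(snp_map["snp"]),
        raw_score=genic.astype(float),
        category=np.where(genic, "genic", "intergenic").astype(object),
        name="genic",
    )


# ---------------------------------------------------------------------------
# LD matrix
# ---------------------------------------------------------------------------

def compute_ld_matrix(genotypes: GenotypeMatrix, window_bp: int = 1_000_000) -> LDMatrix:
    """Pairwise r^2 of dosage columns for same-chromosome pairs within a window.

    Missing dosages are pairwise-deleted.  Zero-variance SNPs raise (they
    should have been removed by the MAF filter).
    """
    d = genotypes.dosages
    n, m = d.shape
    var = np.nanvar(d, axis=0)
    if (var <= 0).any():
        names = genotypes.snp_map["snp"].to_numpy()[var <= 0][:5]
        raise HeritkitError(f"zero-variance SNP(s): {', '.join(map(str, names))}")
    has_missing = np.isnan(d).any()
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    if not has_missing:
        z = (d - d.mean(axis=0)) / d.std(axis=0)
    for chrom, grp in genotypes.snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        for a in range(len(idx)):
            hi = np.searchsorted(pos, pos[a] + window_bp, side="right")
            if hi <= a + 1:
                continue
            j = idx[a + 1:hi]
            if not has_missing:
                r = z[:, j].T @ z[:, idx[a]] / n
            else:
                r = np.empty(len(j))
                xa = d[:, idx[a]]
                for t, jj in enumerate(j):
                    xb = d[:, jj]
                    ok = ~(np.isnan(xa) | np.isnan(xb))
                    if ok.sum() < 2:
                        r[t] = 0.0
                        continue
                    sa, sb = xa[ok].std(), xb[ok].std()
                    if sa == 0 or sb == 0:
                        r[t] = 0.0
                        continue
                    r[t] = np.corrcoef(xa[ok], xb[ok])[0, 1]
            rows.append(np.full(len(j), idx[a]))
            cols.append(j)
            vals.append(r**2)
    if rows:
        i = np.concatenate(rows)
        j = np.concatenate(cols)
        v = np.concatenate(vals)
        upper = sparse.coo_matrix((v, (i, j)), shape=(m, m))
        mat = (upper + upper.T + sparse.eye(m)).tocsr()
    else:
        mat = sparse.eye(m, format="csr")
    return LDMatrix(snp_ids=list(genotypes.snp_map["snp"]), values=mat, window_bp=window_bp)


def ld_weight_scores(ld: LDMatrix, raw: AnnotationTrack,
                     normalize: bool = True) -> AnnotationTrack:
    """Apply the pairwise LD matrix to a raw score vector.

    With ``normalize`` (default) the result is the self-inclusive weighted
    average described in the module docstring; otherwise the raw ``R s``
    matrix-vector product is returned.
    """
    if ld.snp_ids != raw.snp_ids:
        raise HeritkitError("LD matrix and annotation track must share snp_ids")
    s = raw.raw_score.astype(float)
    scored = ~np.isnan(s)
    if not scored.any():
        raise HeritkitError("no scored SNPs overlap the LD matrix")
    filled = np.where(scored, s, 0.0)
    numer = ld.values @ filled
    denom = ld.values @ scored.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        weighted = numer / denom if normalize else numer
    weighted = np.where(denom > 0, weighted, np.nan)
    return AnnotationTrack(
        snp_ids=list(raw.snp_ids),
        raw_score=raw.raw_score,
        ld_weighted_score=weighted,
        category=raw.category,
        name=raw.name,
    )


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def median_split(track: AnnotationTrack) -> AnnotationTrack:
    """Split scored SNPs at the median into ``low`` (<= median) and ``high``.

    Uses the LD-weighted scores when present.  Missing-score SNPs get an
    empty category and are excluded downstream.  All-identical scores raise
    (degenerate split).
    """
    s = track.scores()
    scored = ~np.isnan(s)
    if scored.sum() < 2:
        raise HeritkitError("median split needs at least 2 scored SNPs")
    vals = s[scored]
    if np.all(vals == vals[0]):
        raise HeritkitError("degenerate split: all scores identical")
    med = np.median(vals)
    category = np.array([""] * len(s), dtype=object)
    category[scored & (s > med)] = "high"
    category[scored & (s <= med)] = "low"
    return AnnotationTrack(
        snp_ids=list(track.snp_ids),
        raw_score=track.raw_score,
        ld_weighted_score=track.ld_weighted_score,
        category=category,
        name=track.name or "conservation",
    )


def score_correlation(track_a: AnnotationTrack, track_b: AnnotationTrack
                      ) -> tuple[float, float]:
    """Pearson correlation (and its square) over SNPs scored in both tracks."""
    ids_a = {s: i for i, s in enumerate(track_a.snp_ids)}
    common = [(ids_a[s], j) for j, s in enumerate(track_b.snp_ids) if s in ids_a]
    if not common:
        raise HeritkitError("tracks share no SNPs")
    ia, ib = map(np.asarray, zip(*common))
    a = track_a.scores()[ia]
    b = track_b.scores()[ib]
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        raise HeritkitError("need at least 3 SNPs scored in both tracks")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise HeritkitError("zero variance in a score track")
    r = float(np.corrcoef(a, b)[0, 1])
    return r, r * r


def build_partition(*tracks: AnnotationTrack,
                    categories: list[str] | None = None) -> dict[str, set[str]]:
    """Collect disjoint SNP-id sets per category, ready for per-category GRMs.

    Each track contributes its labelled SNPs; a SNP labelled by two tracks
    (or listed twice) raises.  If ``categories`` is given, each must be
    non-empty in the result.
    """
    out: dict[str, set[str]] = {}
    seen: dict[str, str] = {}
    for track in tracks:
        if track.category is None:
            raise HeritkitError(f"track {track.name!r} has no category labels")
        for snp, cat in zip(track.snp_ids, track.category):
            if not cat:
                continue
            if snp in seen:
                raise HeritkitError(
                    f"overlapping categories: SNP {snp} in {seen[snp]!r} and {cat!r}"
                )
            seen[snp] = cat
            out.setdefault(str(cat), set()).add(snp)
    wanted = categories if categories is not None else list(out)
    for cat in wanted:
        if not out.get(cat):
            raise HeritkitError(f"empty category {cat!r} in partition")
    return {c: out[c] for c in wanted}


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_bed(gene_table: pd.DataFrame, path: str | Path) -> None:
    """Write a BED gene table (0-based half-open, no header)."""
    cols = [c for c in ("chrom", "start", "end", "name") if c in gene_table.columns]
    gene_table[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=["chrom", "start", "end", "name"], dtype={"chrom": str})
    if frame["name"].isna().all():
        frame = frame.drop(columns=["name"])
    return frame


def write_scores_tsv(snp_map: pd.DataFrame, scores: np.ndarray, path: str | Path) -> None:
    """Conservation-score TSV: chrom, 1-based pos, score (missing rows omitted)."""
    frame = pd.DataFrame({
        "chrom": snp_map["chrom"], "pos": snp_map["pos"], "score": scores,
    }).dropna(subset=["score"])
    frame.to_csv(path, sep="\t", index=False)


def read_scores_tsv(path: str | Path, snp_map: pd.DataFrame) -> AnnotationTrack:
    """Join a (chrom, pos, score) TSV onto a SNP map; unmatched SNPs stay unscored."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    merged = snp_map.assign(chrom=snp_map["chrom"].astype(str)).merge(
        table, on=["chrom", "pos"], how="left"
    )
    return AnnotationTrack(
        snp_ids=list(snp_map["snp"]),
        raw_score=merged["score"].to_numpy(dtype=float),
        name="conservation",
    )


def write_partition_tsv(partition: dict[str, set[str]], path: str | Path) -> None:
    rows = [(snp, cat) for cat, snps in partition.items() for snp in sorted(snps)]
    pd.DataFrame(rows, columns=["snp_id", "category"]).to_csv(path, sep="\t", index=False)
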