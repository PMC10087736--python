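"""Genomic differentiation: per-SNP pairwise FST and its summaries.

FST is Wright's fixation index computed per biallelic SNP for one pair of
stations from pooled allele frequencies.  With p1, p2 the alternate-allele
frequencies at the two stations and pbar = (p1 + p2)/2,

    H_T = 2 * pbar * (1 - pbar)            (expected total heterozygosity)
    H_S = p1*(1 - p1) + p2*(1 - p2)        (mean within-station heterozygosity)
    FST = (H_T - H_S) / H_T

The mean frequency is always taken over the two stations of the pair only —
never over all stations — because the set of SNPs with defined frequencies
differs strongly from pair to pair in sparse metagenomic data.  A SNP fixed
for the same allele at both stations (H_T = 0) carries no information and is
excluded.  A pair's genomic distance is the *median* per-SNP FST over the
SNPs observed at both stations; the global FST is the mean of the non-missing
pairwise entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .core_tables import AlleleCountTable, DistanceMatrix, SnpRecord, ValidationError

log = logging.getLogger(__name__)

#: differentiation classes and their upper bounds (lower-open, upper-closed)
FST_CLASS_BOUNDS = (("little", 0.05), ("moderate", 0.15), ("high", 0.25))


def allele_frequency(record: SnpRecord, station: str) -> float:
    """Alternate-allele frequency of one SNP at one station.

    Undefined (raises) at zero coverage: absence of reads is absence of an
    observation, not frequency zero.
    """
    ref, alt = record.counts.get(station, (0, 0))
    cov = ref + alt
    if cov == 0:
        raise ValidationError(f"{record.snp_id} not observed at station {station}")
    return alt / cov


def snp_pair_fst(p1: float, p2: float) -> float:
    """Wright FST for one SNP between two stations; NaN when both are fixed
    for the same allele (H_T = 0, no information)."""
    if not (0.0 <= p1 <= 1.0) or not (0.0 <= p2 <= 1.0):
        raise ValueError(f"allele frequencies outside [0, 1]: {p1}, {p2}")
    pbar = 0.5 * (p1 + p2)
    ht = 2.0 * pbar * (1.0 - pbar)
    if ht == 0.0:
        return float("nan")
    hs = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    return (ht - hs) / ht


def _pair_fst_vector(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Vectorized snp_pair_fst; NaN where undefined."""
    pbar = 0.5 * (p1 + p2)
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), np.nan)
    return fst


@dataclass
class PairwiseFstResult:
    """Median-FST genomic distance matrix plus bookkeeping.

    ``n_shared_snps[(a, b)]`` counts SNPs observed at both stations of the
    pair; the matrix entry is missing (NaN) exactly when no shared SNP gives
    a defined FST.  ``global_fst`` is the mean of non-missing entries, each
    unordered pair counted once.
    """

    matrix: DistanceMatrix
    n_shared_snps: dict[tuple[str, str], int]
    global_fst: float
    per_snp_fst: Optional[pd.DataFrame] = None


def pairwise_fst_from_frequencies(
    freqs: pd.DataFrame, *, per_snp: bool = False
) -> PairwiseFstResult:
    """Median pairwise FST from a SNP x station frequency matrix.

    ``freqs`` holds alternate-allele frequencies with NaN where a SNP is not
    observed at a station.  This is the infinite-coverage entry point: feed
    it true simulated frequencies to bypass read sampling entirely.
    """
    stations = [str(c) for c in freqs.columns]
    if len(stations) < 2:
        raise ValidationError("pairwise FST needs at least 2 stations")
    P = freqs.to_numpy(dtype=float)
    n = len(stations)
    mat = np.zeros((n, n), dtype=float)
    shared: dict[tuple[str, str], int] = {}
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(P[:, i]) & ~np.isnan(P[:, j])
            shared[(stations[i], stations[j])] = int(both.sum())
            fst = _pair_fst_vector(P[both, i], P[both, j])
            defined = ~np.isnan(fst)
            if defined.any():
                med = float(np.median(fst[defined]))
            else:
                med = np.nan
            mat[i, j] = mat[j, i] = med
            if per_snp and defined.any():
                ids = freqs.index.to_numpy()[both][defined]
                rows.append(
                    pd.DataFrame(
                        {
                            "snp_id": ids,
                            "station_a": stations[i],
                            "station_b": stations[j],
                            "fst": fst[defined],
                        }
                    )
                )
    dm = DistanceMatrix(stations, mat, "genomic")
    off = dm.offdiagonal()
    n_missing = int(np.isnan(off).sum())
    if n_missing:
        log.info("%d of %d station pairs have no shared SNP", n_missing, off.size)
    if np.isnan(off).all():
        global_fst = float("nan")
    else:
        global_fst = float(np.nanmean(off))
    per = pd.concat(rows, ignore_index=True) if rows else None
    return PairwiseFstResult(dm, shared, global_fst, per)


def pairwise_fst_matrix(table: AlleleCountTable, *, per_snp: bool = False) -> PairwiseFstResult:
    """Median pairwise FST between all station pairs of a (filtered) table."""
    if table.n_stations < 2:
        raise ValidationError("pairwise FST needs at least 2 stations")
    return pairwise_fst_from_frequencies(table.frequencies(), per_snp=per_snp)


def classify_fst(fst: float) -> str:
    """Differentiation class of an FST value.

    Bins: < 0.05 little, [0.05, 0.15] moderate, (0.15, 0.25] high,
    > 0.25 very high.
    """
    if not (0.0 <= fst <= 1.0) or np.isnan(fst):
        raise ValueError(f"FST outside [0, 1]: {fst}")
    if fst < 0.05:
        return "little"
    for name, hi in FST_CLASS_BOUNDS[1:]:
        if fst <= hi:
            return name
    return "very_high"


def fst_class_counts(matrix: DistanceMatrix) -> dict[str, int]:
    """Histogram of differentiation classes over non-missing pairs."""
    counts = {name: 0 for name, _ in FST_CLASS_BOUNDS}
    counts["very_high"] = 0
    for v in matrix.offdiagonal():
        if not np.isnan(v):
            counts[classify_fst(float(v))] += 1
    return counts


def impute_missing(matrix: DistanceMatrix) -> DistanceMatrix:
    """Replace missing pairwise entries by the mean of the non-missing ones."""
    off = matrix.offdiagonal()
    finite = off[~np.isnan(off)]
    if finite.size == 0:
        raise ValidationError("all pairwise entries are missing; nothing to impute from")
    fill = float(finite.mean())
    values = matrix.values.copy()
    values[np.isnan(values)] = fill
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(list(matrix.labels), values, matrix.kind)


def cluster_stations(matrix: DistanceMatrix) -> tuple[np.ndarray, DistanceMatrix]:
    """Complete-linkage hierarchical clustering of stations.

    Missing genomic distances are first replaced by the mean non-missing
    value (imputation is used here only; regression drops missing pairs).
    Returns the scipy linkage matrix and the imputed distance matrix.
    """
    if matrix.n < 2:
        raise ValidationError("clustering needs at least 2 stations")
    imputed = impute_missing(matrix) if np.isnan(matrix.values).any() else matrix
    condensed = squareform(imputed.values, checks=False)
    Z = linkage(condensed, method="complete")
    return Z, imputed


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = walk(node.left)
        right = walk(node.right)
        bl_l = node.dist - node.left.dist
        bl_r = node.dist - node.right.dist
        return f"({left}:{bl_l:g},{right}:{bl_r:g})"

    return walk(tree) + ";"


def plot_fst_heatmap(matrix: DistanceMatrix, path: str, *, Z: np.ndarray | None = None) -> None:
    """Heatmap of (imputed) genomic distances with stations in dendrogram order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list

    if Z is None:
        Z, matrix = cluster_stations(matrix)
    elif np.isnan(matrix.values).any():
        matrix = impute_missing(matrix)
    order = leaves_list(Z)
    values = matrix.values[np.ix_(order, order)]
    labels = [matrix.labels[i] for i in order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(values, cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="pairwise FST")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
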