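"""End-to-end orchestration: filter -> FST -> distance layers -> regression.

`run_analysis` is the in-memory composition of the stage functions (the CLI
`pipeline` subcommand is a thin file-reading wrapper around it); it adds no
computation of its own, so composing the stage CLIs manually gives identical
results.  Per-stage record counts are collected for the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_tables import AlleleCountTable, DistanceMatrix, StationTable, filter_snps_by_coverage
from .distances import (
    ConnectivitySet,
    EnvPcaResult,
    SeaGrid,
    env_distance_matrix,
    env_pca,
    oceanographic_distances,
    sea_distance_matrix,
)
from .fst import PairwiseFstResult, cluster_stations, fst_class_counts, pairwise_fst_matrix
from .regression import RegressionResult, assemble_pairs, exhaustive_bic_select

log = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    filtered: AlleleCountTable
    fst: PairwiseFstResult
    geographic: DistanceMatrix
    env: DistanceMatrix
    env_pca: EnvPcaResult
    pc: DistanceMatrix
    mct: DistanceMatrix
    pairs: pd.DataFrame
    regression: RegressionResult
    counts: dict = field(default_factory=dict)


def run_analysis(
    table: AlleleCountTable,
    stations: StationTable,
    grid: SeaGrid,
    connectivity: ConnectivitySet,
    *,
    min_cov: int = 4,
    sigma_mult: float = 2.0,
    min_alt: int = 1,
    support: str = "total",
    log1p_vars: list[str] | None = None,
    n_axes: int | None = None,
    env_weight: str = "none",
    terms: tuple[str, ...] = ("geo", "env", "pc", "mct"),
    snap_max_km: float = 300.0,
) -> AnalysisResult:
    """Run the full analysis on in-memory inputs.

    Station ids present in the allele-count table must be a subset of the
    station table; distance layers are computed on the stations that carry
    genomic data.
    """
    missing = set(table.stations) - set(stations.station_ids)
    if missing:
        raise ValueError(f"allele-count stations missing from station table: {sorted(missing)}")
    genostations = StationTable(stations.data.loc[table.stations])

    cells_in = int(table.observed().to_numpy().sum())
    filtered = filter_snps_by_coverage(
        table, min_cov=min_cov, sigma_mult=sigma_mult, min_alt=min_alt, support=support
    )
    cells_kept = int(filtered.observed().to_numpy().sum())
    log.info("stage filter: %d -> %d SNPs, %d -> %d cells", table.n_snps, filtered.n_snps, cells_in, cells_kept)

    fst = pairwise_fst_matrix(filtered)
    off = fst.matrix.offdiagonal()
    n_pairs_total = off.size
    n_pairs_fst = int((~np.isnan(off)).sum())
    log.info("stage fst: %d of %d pairs have a genomic distance; global FST = %.4g", n_pairs_fst, n_pairs_total, fst.global_fst)

    geo = sea_distance_matrix(genostations, grid, snap_max_km=snap_max_km)
    pca = env_pca(genostations, log1p_vars=log1p_vars, n_axes=n_axes)
    env = env_distance_matrix(pca, weight=env_weight)
    pc, mct = oceanographic_distances(connectivity)
    pc = pc.reorder(filtered.stations) if set(pc.labels) == set(filtered.stations) else pc
    mct = mct.reorder(filtered.stations) if set(mct.labels) == set(filtered.stations) else mct
    log.info("stage distances: %d retained PCA axes", len(pca.kept_axes))

    pairs = assemble_pairs(fst.matrix, geo, env, pc, mct)
    regression = exhaustive_bic_select(pairs, terms=terms)
    log.info(
        "stage regression: selected {%s} on %d pairs",
        "+".join(regression.selected_terms) or "intercept-only",
        regression.n_obs,
    )

    counts = {
        "snps_in": table.n_snps,
        "cells_in": cells_in,
        "snps_after_filter": filtered.n_snps,
        "cells_after_filter": cells_kept,
        "cells_removed": cells_in - cells_kept,
        "pairs_total": int(n_pairs_total),
        "pairs_with_fst": n_pairs_fst,
        "pairs_missing": int(n_pairs_total - n_pairs_fst),
        "pairs_regressed": regression.n_obs,
        "pca_axes_kept": len(pca.kept_axes),
        "global_fst": fst.global_fst,
        "fst_classes": fst_class_counts(fst.matrix),
        "selected_terms": list(regression.selected_terms),
    }
    return AnalysisResult(filtered, fst, geo, env, pca, pc, mct, pairs, regression, counts)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_analysis_outputs(
    result: AnalysisResult, outdir: str | Path, *, config: dict | None = None, seed: int | None = None
) -> dict:
    """Write matrices, summary tables, figures and the run manifest."""
    from .fst import linkage_to_newick, plot_fst_heatmap
    from .regression import report

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.fst.matrix.to_tsv(out / "fst_matrix.tsv")
    result.geographic.to_tsv(out / "geographic_distance.tsv")
    result.env.to_tsv(out / "environmental_distance.tsv")
    result.pc.to_tsv(out / "pc_connectivity.tsv")
    result.mct.to_tsv(out / "mct_distance.tsv")
    result.pairs.to_csv(out / "pair_observations.tsv", sep="\t", index=False)

    text, table = report(result.regression)
    table.to_csv(out / "drivers_table.tsv", sep="\t", index=False)
    result.regression.bic_table.to_csv(out / "bic_table.tsv", sep="\t", index=False)
    (out / "drivers_summary.txt").write_text(text + "\n", encoding="utf-8")

    pd.Series(result.counts["fst_classes"]).rename_axis("class").rename("n_pairs").to_csv(
        out / "fst_class_counts.tsv", sep="\t"
    )
    Z, imputed = cluster_stations(result.fst.matrix)
    (out / "dendrogram.nwk").write_text(linkage_to_newick(Z, imputed.labels) + "\n", encoding="utf-8")
    plot_fst_heatmap(imputed, str(out / "fst_heatmap.png"), Z=Z)

    manifest = {
        "picopop_version": __version__,
        "seed": seed,
        "config": config or {},
        "counts": result.counts,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8")
    return manifest
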