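"""Core data model and I/O.

Holds the tabular containers the whole pipeline operates on — per-SNP,
per-station read counts for one species, station metadata, and square
station-by-station distance matrices — together with their file formats and
the vertical-coverage SNP filter applied to metagenomic variant tables.

A "cell" is one (SNP, station) pair.  A SNP is *observed* at a station when
at least one read covers it there and the cell has survived filtering; cells
with zero coverage carry no information and are treated as absent, not as
frequency zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: canonical column order of the long allele-count TSV dialect
TSV_COLUMNS = (
    "snp_id",
    "contig",
    "pos",
    "ref",
    "alt",
    "station",
    "ref_count",
    "alt_count",
)

DISTANCE_KINDS = ("genomic", "geographic", "environmental", "pc_connectivity", "mct")


class ParseError(ValueError):
    """A malformed input row; the message carries the 1-based line number."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a table invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SnpRecord:
    """One biallelic variant site with per-station read support.

    ``counts`` maps station id to ``(ref_count, alt_count)``; stations with
    zero total coverage may simply be absent from the map.
    """

    snp_id: str
    contig: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be single nucleotides in ACGT, "
                f"got ref={self.ref_allele!r} alt={self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"{self.snp_id}: ref and alt alleles are identical")
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: position must be 1-based positive")
        for station, (r, a) in self.counts.items():
            if r < 0 or a < 0:
                raise ValidationError(f"{self.snp_id}@{station}: negative read count")

    def coverage(self, station: str) -> int:
        """Vertical coverage (total reads) at ``station``; 0 when absent."""
        r, a = self.counts.get(station, (0, 0))
        return r + a


@dataclass
class AlleleCountTable:
    """Per-SNP, per-station reference/alternate read counts for one species.

    Internally matrix-shaped: ``ref_counts`` and ``alt_counts`` are integer
    DataFrames indexed by snp_id with one column per station, aligned with
    ``snp_meta`` (columns contig, pos, ref, alt).
    """

    species_label: str
    snp_meta: pd.DataFrame
    ref_counts: pd.DataFrame
    alt_counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.snp_meta.index.equals(self.ref_counts.index) or not self.snp_meta.index.equals(
            self.alt_counts.index
        ):
            raise ValidationError("snp_meta / count matrices are not aligned on snp_id")
        if list(self.ref_counts.columns) != list(self.alt_counts.columns):
            raise ValidationError("ref and alt count matrices have different stations")
        if self.snp_meta.index.has_duplicates:
            dup = self.snp_meta.index[self.snp_meta.index.duplicated()][0]
            raise ValidationError(f"duplicate snp_id {dup!r}")
        if self.ref_counts.columns.has_duplicates:
            raise ValidationError("duplicate station ids")
        if (self.ref_counts.to_numpy() < 0).any() or (self.alt_counts.to_numpy() < 0).any():
            raise ValidationError("negative read counts")

    # -- basic accessors ----------------------------------------------------

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_meta.index)

    @property
    def stations(self) -> list[str]:
        return list(self.ref_counts.columns)

    @property
    def n_snps(self) -> int:
        return len(self.snp_meta)

    @property
    def n_stations(self) -> int:
        return self.ref_counts.shape[1]

    def coverage(self) -> pd.DataFrame:
        """Vertical coverage per cell: ref_count + alt_count."""
        return self.ref_counts + self.alt_counts

    def frequencies(self) -> pd.DataFrame:
        """Alternate-allele frequency per cell; NaN where coverage is zero."""
        cov = self.coverage().to_numpy(dtype=float)
        alt = self.alt_counts.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(cov > 0, alt / np.where(cov > 0, cov, 1.0), np.nan)
        return pd.DataFrame(freq, index=self.snp_meta.index, columns=self.ref_counts.columns)

    def observed(self) -> pd.DataFrame:
        """Boolean mask of cells with coverage >= 1."""
        return self.coverage() > 0

    def records(self) -> Iterator[SnpRecord]:
        ref = self.ref_counts.to_numpy()
        alt = self.alt_counts.to_numpy()
        stations = self.stations
        for i, (snp_id, meta) in enumerate(self.snp_meta.iterrows()):
            counts = {
                s: (int(ref[i, j]), int(alt[i, j]))
                for j, s in enumerate(stations)
                if ref[i, j] + alt[i, j] > 0
            }
            yield SnpRecord(
                snp_id=str(snp_id),
                contig=str(meta["contig"]),
                pos=int(meta["pos"]),
                ref_allele=str(meta["ref"]),
                alt_allele=str(meta["alt"]),
                counts=counts,
            )

    def record(self, snp_id: str) -> SnpRecord:
        for rec in self.records():
            if rec.snp_id == snp_id:
                return rec
        raise KeyError(snp_id)


@dataclass
class StationTable:
    """Sampling stations: id, surface coordinates, environmental variables.

    ``data`` is indexed by station_id with columns ``lat``, ``lon`` followed
    by one column per environmental variable (temperature in degC, salinity
    in PSU, nutrient concentrations in mmol m^-3, oxygen in ml l^-1,
    chlorophyll-a in mg m^-3 in the canonical set, but any numeric set is
    accepted as long as it is complete).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "lat" not in self.data.columns or "lon" not in self.data.columns:
            raise ValidationError("station table needs 'lat' and 'lon' columns")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate station ids")
        lat = self.data["lat"]
        lon = self.data["lon"]
        if ((lat < -90) | (lat > 90)).any():
            raise ValidationError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise ValidationError("longitude outside [-180, 180]")
        if self.env.isna().any().any():
            raise ValidationError("missing environmental values are not allowed")

    @property
    def station_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def env(self) -> pd.DataFrame:
        """Environmental variables only (everything after lat/lon)."""
        return self.data.drop(columns=["lat", "lon"])

    @property
    def latitudes(self) -> np.ndarray:
        return self.data["lat"].to_numpy(dtype=float)

    @property
    def longitudes(self) -> np.ndarray:
        return self.data["lon"].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StationTable":
        df = pd.read_csv(path, dtype={"station_id": str})
        if "station_id" not in df.columns:
            raise ParseError(f"{path}: missing 'station_id' column")
        df = df.set_index("station_id")
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="station_id")


@dataclass
class DistanceMatrix:
    """Square symmetric station-by-station matrix; NaN marks a missing pair.

    Missing entries are only meaningful for ``kind='genomic'`` (station pairs
    that share no SNP).  The diagonal is zero by convention; for
    ``pc_connectivity`` (a similarity, not a metric) the diagonal is stored
    as zero and ignored by consumers.
    """

    labels: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.kind not in DISTANCE_KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate station labels")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(self.values - self.values.T), initial=0.0)
        if asym > 1e-8:
            raise ValidationError(f"matrix is not symmetric (max |A - A.T| = {asym:g})")
        if not np.array_equal(np.isnan(self.values), np.isnan(self.values).T):
            raise ValidationError("missing entries are not symmetric")
        if np.isnan(self.values).any() and self.kind != "genomic":
            raise ValidationError(f"missing entries not allowed for kind={self.kind!r}")
        off = ~np.eye(n, dtype=bool)
        finite_off = self.values[off][~np.isnan(self.values[off])]
        if (finite_off < 0).any():
            raise ValidationError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def offdiagonal(self) -> np.ndarray:
        """Upper-triangle entries (each unordered pair once), NaN included."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        if set(labels) != set(self.labels):
            raise ValidationError("label set mismatch in reorder")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA", index_label="station")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ParseError(f"{path}: row and column labels differ")
        return cls(list(df.index), df.to_numpy(dtype=float), kind)


# ---------------------------------------------------------------------------
# allele-count I/O
# ---------------------------------------------------------------------------


def _table_from_long(long: pd.DataFrame, species_label: str) -> AlleleCountTable:
    snp_order = long["snp_id"].drop_duplicates().tolist()
    station_order = long["station"].drop_duplicates().tolist()
    meta = (
        long.drop_duplicates("snp_id")
        .set_index("snp_id")[["contig", "pos", "ref", "alt"]]
        .loc[snp_order]
    )
    # reject a snp_id reused with conflicting site metadata
    chk = long.groupby("snp_id")[["contig", "pos", "ref", "alt"]].nunique()
    bad = chk[(chk > 1).any(axis=1)]
    if len(bad):
        raise ValidationError(f"snp_id {bad.index[0]!r} has inconsistent site metadata")
    ref = long.pivot(index="snp_id", columns="station", values="ref_count")
    alt = long.pivot(index="snp_id", columns="station", values="alt_count")
    ref = ref.reindex(index=snp_order, columns=station_order).fillna(0).astype(int)
    alt = alt.reindex(index=snp_order, columns=station_order).fillna(0).astype(int)
    ref.columns.name = alt.columns.name = None
    table = AlleleCountTable(species_label, meta, ref, alt)
    for rec in table.records():  # validates alleles site by site
        pass
    return table


def read_allele_counts(
    path: str | Path,
    format: str = "tsv",
    *,
    sample_map: Mapping[str, str] | None = None,
    species_label: str | None = None,
) -> AlleleCountTable:
    """Read an allele-count table from long TSV or from VCF.

    The TSV dialect is tab-separated UTF-8 with a header row and columns
    ``snp_id contig pos ref alt station ref_count alt_count``; each row is
    one observed cell.  For VCF, per-sample allele depths (the AD format
    field, or paired RO/AO) are used and ``sample_map`` must map VCF sample
    names to station ids.
    """
    path = Path(path)
    label = species_label if species_label is not None else path.stem
    if format == "tsv":
        return _read_allele_counts_tsv(path, label)
    if format == "vcf":
        if sample_map is None:
            raise ValidationError("VCF input requires a sample -> station name mapping")
        return _read_allele_counts_vcf(path, label, sample_map)
    raise ValueError(f"unknown format {format!r}")


def _read_allele_counts_tsv(path: Path, label: str) -> AlleleCountTable:
    try:
        long = pd.read_csv(
            path,
            sep="\t",
            dtype={
                "snp_id": str,
                "contig": str,
                "ref": str,
                "alt": str,
                "station": str,
            },
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in TSV_COLUMNS if c not in long.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("pos", "ref_count", "alt_count"):
        coerced = pd.to_numeric(long[col], errors="coerce")
        bad = coerced.isna() | (coerced != coerced.round())
        if bad.any():
            line = int(long.index[bad][0]) + 2  # header is line 1
            raise ParseError(f"{path}, line {line}: non-integer value in column {col!r}")
        long[col] = coerced.astype(int)
    dup = long.duplicated(subset=["snp_id", "station"])
    if dup.any():
        row = long[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate cell (snp_id={row['snp_id']!r}, station={row['station']!r})"
        )
    bad_allele = ~(long["ref"].isin(list(NUCLEOTIDES)) & long["alt"].isin(list(NUCLEOTIDES)))
    if bad_allele.any():
        line = int(long.index[bad_allele][0]) + 2
        raise ParseError(f"{path}, line {line}: alleles must be single nucleotides in ACGT")
    return _table_from_long(long[list(TSV_COLUMNS)], label)


def _read_allele_counts_vcf(
    path: Path, label: str, sample_map: Mapping[str, str]
) -> AlleleCountTable:
    from cyvcf2 import VCF  # deferred: only VCF input needs it

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in sample_map]
    if unknown:
        raise ValidationError(f"VCF samples without station mapping: {unknown}")
    stations = [sample_map[s] for s in samples]

    rows: list[dict] = []
    n_indel = n_multi = 0
    for var in vcf:
        ref = var.REF
        alts = list(var.ALT)
        if len(ref) != 1 or ref not in NUCLEOTIDES:
            n_indel += 1
            continue
        snp_alts = [(k, a) for k, a in enumerate(alts) if len(a) == 1 and a in NUCLEOTIDES]
        if not snp_alts:
            n_indel += 1
            continue
        ad = var.format("AD")
        if ad is None:
            ro, ao = var.format("RO"), var.format("AO")
            if ro is None or ao is None:
                raise ParseError(f"{path}: no AD (or RO/AO) depth fields at {var.CHROM}:{var.POS}")
            ad = np.concatenate([ro.reshape(len(samples), 1), ao.reshape(len(samples), -1)], axis=1)
        ad = np.asarray(ad)
        ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing as negative
        if len(snp_alts) > 1:
            n_multi += 1
        # majority alternate across stations; ties fall to the first listed
        support = [ad[:, k + 1].sum() for k, _ in snp_alts]
        k_best, alt = snp_alts[int(np.argmax(support))]
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        for j, station in enumerate(stations):
            r, a = int(ad[j, 0]), int(ad[j, k_best + 1])
            if r + a > 0:
                rows.append(
                    dict(
                        snp_id=snp_id,
                        contig=var.CHROM,
                        pos=var.POS,
                        ref=ref,
                        alt=alt,
                        station=station,
                        ref_count=r,
                        alt_count=a,
                    )
                )
    if n_indel:
        log.info("dropped %d non-SNP (indel/symbolic) records", n_indel)
    if n_multi:
        log.info("reduced %d multi-allelic sites to their majority alternate", n_multi)
    if not rows:
        raise ValidationError(f"{path}: no biallelic SNP records with read support")
    return _table_from_long(pd.DataFrame(rows), label)


def write_allele_counts(table: AlleleCountTable, path: str | Path) -> None:
    """Write the long TSV dialect; only observed cells (coverage >= 1) are emitted."""
    ref = table.ref_counts.to_numpy()
    alt = table.alt_counts.to_numpy()
    stations = table.stations
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for i, (snp_id, meta) in enumerate(table.snp_meta.iterrows()):
            for j, station in enumerate(stations):
                if ref[i, j] + alt[i, j] > 0:
                    fh.write(
                        f"{snp_id}\t{meta['contig']}\t{meta['pos']}\t{meta['ref']}\t"
                        f"{meta['alt']}\t{station}\t{ref[i, j]}\t{alt[i, j]}\n"
                    )


def write_vcf(table: AlleleCountTable, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with per-sample AD fields (stations as samples)."""
    stations = table.stations
    ref = table.ref_counts.to_numpy()
    alt = table.alt_counts.to_numpy()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=picopop ({table.species_label})\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(stations) + "\n")
        for i, (snp_id, meta) in enumerate(table.snp_meta.iterrows()):
            cells = "\t".join(f"{ref[i, j]},{alt[i, j]}" for j in range(len(stations)))
            fh.write(
                f"{meta['contig']}\t{meta['pos']}\t{snp_id}\t{meta['ref']}\t{meta['alt']}"
                f"\t.\tPASS\t.\tAD\t{cells}\n"
            )


# ---------------------------------------------------------------------------
# coverage filter
# ---------------------------------------------------------------------------


def filter_snps_by_coverage(
    table: AlleleCountTable,
    min_cov: int = 4,
    sigma_mult: float = 2.0,
    *,
    min_alt: int = 1,
    support: str = "total",
) -> AlleleCountTable:
    """Apply the per-station vertical-coverage window to every cell.

    For each station independently, the mean mu and sample standard deviation
    sigma of vertical coverage are computed over that station's covered SNPs
    (coverage >= 1); a cell is retained iff its coverage c satisfies
    ``min_cov <= c < mu + sigma_mult * sigma`` (strict upper bound) and it
    carries at least ``min_alt`` alternate reads.  The lower bound guards
    against spurious low-support calls; the upper bound removes sites whose
    excess coverage betrays read recruitment from closely related taxa.

    ``support='total'`` applies ``min_cov`` to total coverage (default);
    ``support='alt'`` applies it to alternate reads only.  A station with
    fewer than two covered SNPs has no defined sigma: only the lower bound is
    applied there and a warning is logged.  SNPs retained at no station are
    dropped from the table.
    """
    if table.n_snps == 0:
        raise ValidationError("cannot filter an empty table")
    if support not in ("total", "alt"):
        raise ValueError(f"support must be 'total' or 'alt', got {support!r}")
    cov = table.coverage().to_numpy()
    alt = table.alt_counts.to_numpy()

    keep = np.zeros(cov.shape, dtype=bool)
    n_floor = n_ceil = n_alt = 0
    for j, station in enumerate(table.stations):
        c = cov[:, j]
        covered = c >= 1
        n_covered = int(covered.sum())
        if n_covered == 0:
            continue
        if n_covered < 2:
            log.warning(
                "station %s has %d covered SNP(s); sigma undefined, "
                "applying only the minimum-coverage bound",
                station,
                n_covered,
            )
            upper = np.inf
        else:
            mu = float(c[covered].mean())
            sigma = float(c[covered].std(ddof=1))
            upper = mu + sigma_mult * sigma
        supp = c if support == "total" else alt[:, j]
        ok_floor = supp >= min_cov
        ok_ceil = c < upper
        ok_alt = alt[:, j] >= min_alt
        keep[:, j] = covered & ok_floor & ok_ceil & ok_alt
        n_floor += int((covered & ~ok_floor).sum())
        n_ceil += int((covered & ok_floor & ~ok_ceil).sum())
        n_alt += int((covered & ok_floor & ok_ceil & ~ok_alt).sum())

    log.info(
        "coverage filter: %d cells below the %d-read floor, %d above mu+%gsigma, "
        "%d with fewer than %d alternate reads",
        n_floor,
        min_cov,
        n_ceil,
        sigma_mult,
        n_alt,
        min_alt,
    )
    ref_new = pd.DataFrame(
        np.where(keep, table.ref_counts.to_numpy(), 0),
        index=table.snp_meta.index,
        columns=table.ref_counts.columns,
    )
    alt_new = pd.DataFrame(
        np.where(keep, alt, 0), index=table.snp_meta.index, columns=table.alt_counts.columns
    )
    alive = keep.any(axis=1)
    log.info("coverage filter: %d of %d SNPs retained in >= 1 station", int(alive.sum()), len(alive))
    return AlleleCountTable(
        table.species_label,
        table.snp_meta.loc[alive],
        ref_new.loc[alive].astype(int),
        alt_new.loc[alive].astype(int),
    )
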