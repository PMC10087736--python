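"""Explanatory distance layers between sampling stations.

Three constructions:

* **Geographic** — least-cost over-sea distance: stations are snapped to the
  nearest sea cell of a land/sea raster and shortest paths are computed on
  the 8-connected sea-cell graph with haversine edge weights, so routes never
  cross land.
* **Environmental** — stations are embedded by PCA of their standardized
  environmental variables; axes are retained by the Kaiser–Guttman criterion
  (eigenvalue strictly above the mean eigenvalue, i.e. above 1 for
  correlation-based PCA) and the distance is Euclidean in the retained-axis
  score space.
* **Oceanographic** — from directed Lagrangian products: the probability of
  connection (PC) is averaged over the 3-, 6- and 12-month dispersal horizons
  per direction and symmetrized by the maximum of the two directions; the
  mean connection time (MCT, days) is symmetrized by the minimum.  Max-PC /
  min-MCT takes the *easier* of the two directed routes as the effective
  separation of an asymmetric pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .core_tables import DistanceMatrix, StationTable, ValidationError

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
PC_HORIZONS_MONTHS = (3, 6, 12)


def haversine_km(
    lat1: np.ndarray | float,
    lon1: np.ndarray | float,
    lat2: np.ndarray | float,
    lon2: np.ndarray | float,
) -> np.ndarray | float:
    """Great-circle distance in km (spherical Earth, radius 6371 km)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


# ---------------------------------------------------------------------------
# sea grid and least-cost geographic distance
# ---------------------------------------------------------------------------


@dataclass
class SeaGrid:
    """Regular lat/lon raster with a boolean sea mask (True = sea).

    ``mask`` has shape ``(len(lat_axis), len(lon_axis))``; axes hold cell
    *centers* and must be strictly monotone.
    """

    lat_axis: np.ndarray
    lon_axis: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        for name, ax in (("lat", self.lat_axis), ("lon", self.lon_axis)):
            d = np.diff(ax)
            if len(ax) > 1 and not ((d > 0).all() or (d < 0).all()):
                raise ValidationError(f"{name} axis is not strictly monotone")
        if self.mask.shape != (len(self.lat_axis), len(self.lon_axis)):
            raise ValidationError(
                f"mask shape {self.mask.shape} != ({len(self.lat_axis)}, {len(self.lon_axis)})"
            )
        if not self.mask.any():
            raise ValidationError("grid has no sea cell")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def snap_station(self, lat: float, lon: float, max_km: float = 300.0) -> tuple[int, int]:
        """Index of the nearest sea cell center within ``max_km``."""
        ii, jj = np.nonzero(self.mask)
        d = haversine_km(lat, lon, self.lat_axis[ii], self.lon_axis[jj])
        k = int(np.argmin(d))
        if d[k] > max_km:
            raise ValidationError(
                f"no sea cell within {max_km} km of ({lat:.3f}, {lon:.3f}); nearest is {d[k]:.1f} km"
            )
        return int(ii[k]), int(jj[k])

    # -- text format: axis header lines then a 0/1 matrix -------------------

    def to_text(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("# picopop seagrid (1 = sea, 0 = land)\n")
            fh.write("lats: " + " ".join(f"{v:g}" for v in self.lat_axis) + "\n")
            fh.write("lons: " + " ".join(f"{v:g}" for v in self.lon_axis) + "\n")
            for row in self.mask.astype(int):
                fh.write("".join(str(v) for v in row) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "SeaGrid":
        lats = lons = None
        rows: list[list[int]] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if line.startswith("lats:"):
                    lats = [float(v) for v in line.split(":", 1)[1].split()]
                elif line.startswith("lons:"):
                    lons = [float(v) for v in line.split(":", 1)[1].split()]
                else:
                    rows.append([int(c) for c in line])
        if lats is None or lons is None:
            raise ValidationError(f"{path}: missing 'lats:' / 'lons:' header lines")
        return cls(np.array(lats), np.array(lons), np.array(rows, dtype=bool))

    @classmethod
    def from_cell_list(cls, path: str | Path) -> "SeaGrid":
        """Load from a CSV of (lat, lon, sea) cell rows on a regular grid."""
        df = pd.read_csv(path)
        lats = np.sort(df["lat"].unique())
        lons = np.sort(df["lon"].unique())
        mask = np.zeros((len(lats), len(lons)), dtype=bool)
        li = {v: i for i, v in enumerate(lats)}
        lj = {v: j for j, v in enumerate(lons)}
        for _, row in df.iterrows():
            mask[li[row["lat"]], lj[row["lon"]]] = bool(int(row["sea"]))
        return cls(lats, lons, mask)


def _sea_graph(grid: SeaGrid):
    """Sparse 8-connected graph over sea cells with haversine edge weights."""
    nlat, nlon = grid.shape
    node = -np.ones(grid.shape, dtype=int)
    ii, jj = np.nonzero(grid.mask)
    node[ii, jj] = np.arange(len(ii))
    src, dst, w = [], [], []
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for di, dj in offsets:
        i2, j2 = ii + di, jj + dj
        inside = (i2 >= 0) & (i2 < nlat) & (j2 >= 0) & (j2 < nlon)
        sel = np.flatnonzero(inside)
        sel = sel[grid.mask[i2[sel], j2[sel]]]
        src.append(node[ii[sel], jj[sel]])
        dst.append(node[i2[sel], j2[sel]])
        w.append(
            haversine_km(
                grid.lat_axis[ii[sel]],
                grid.lon_axis[jj[sel]],
                grid.lat_axis[i2[sel]],
                grid.lon_axis[j2[sel]],
            )
        )
    n = len(ii)
    g = coo_matrix(
        (np.concatenate(w), (np.concatenate(src), np.concatenate(dst))), shape=(n, n)
    ).tocsr()
    return node, g


def sea_distance_matrix(
    stations: StationTable, grid: SeaGrid, *, snap_max_km: float = 300.0
) -> DistanceMatrix:
    """Least-cost over-sea distance (km) between every pair of stations.

    Each station is snapped to its nearest sea cell; the entry is the length
    of the shortest 8-connected path between the two cells, so two stations
    snapped to the same cell are at distance 0.
    """
    cells = [
        grid.snap_station(lat, lon, max_km=snap_max_km)
        for lat, lon in zip(stations.latitudes, stations.longitudes)
    ]
    node, g = _sea_graph(grid)
    idx = np.array([node[c] for c in cells])
    dist = dijkstra(g, directed=False, indices=np.unique(idx))
    row_of = {src: k for k, src in enumerate(np.unique(idx))}
    n = len(cells)
    values = np.zeros((n, n), dtype=float)
    for a in range(n):
        for b in range(a + 1, n):
            d = dist[row_of[idx[a]], idx[b]]
            if not np.isfinite(d):
                raise ValidationError(
                    f"stations {stations.station_ids[a]!r} and {stations.station_ids[b]!r} "
                    "lie in disconnected sea components"
                )
            values[a, b] = values[b, a] = d
    return DistanceMatrix(stations.station_ids, values, "geographic")


# ---------------------------------------------------------------------------
# environmental PCA distance
# ---------------------------------------------------------------------------


@dataclass
class EnvPcaResult:
    """PCA of standardized environmental variables.

    ``scores`` is stations x axes (all axes, descending eigenvalue);
    ``kept_axes`` lists the 0-based axes retained by Kaiser–Guttman;
    ``variance_fractions`` are eigenvalue shares of total variance.
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    kept_axes: list[int]
    loadings: pd.DataFrame = field(repr=False, default=None)


def env_pca(
    stations: StationTable,
    *,
    log1p_vars: list[str] | None = None,
    n_axes: int | None = None,
) -> EnvPcaResult:
    """Correlation-based PCA of the station environmental variables.

    Variables are optionally log1p-transformed (``log1p_vars``, useful for
    right-skewed nutrient concentrations) and then standardized to zero mean
    and unit variance.  Axes with eigenvalue strictly greater than the mean
    eigenvalue (1 for a correlation matrix) are retained (Kaiser–Guttman);
    ``n_axes`` overrides the criterion with an explicit count.
    """
    X = stations.env.astype(float).copy()
    if X.shape[0] < 3:
        raise ValidationError("environmental PCA needs at least 3 stations")
    if X.shape[1] < 2:
        raise ValidationError("environmental PCA needs at least 2 variables")
    for v in log1p_vars or []:
        if (X[v] < 0).any():
            raise ValidationError(f"log1p normalization of {v!r}: negative values")
        X[v] = np.log1p(X[v])
    sd = X.std(ddof=1)
    if (sd == 0).any():
        const = list(sd.index[sd == 0])
        raise ValidationError(f"constant environmental variable(s): {const}")
    Z = (X - X.mean()) / sd
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude loading of each axis is positive
    flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(eigvec.shape[1])])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip
    scores = Z.to_numpy() @ eigvec
    axes = [f"PC{k + 1}" for k in range(len(eigval))]
    if n_axes is not None:
        if not 1 <= n_axes <= len(eigval):
            raise ValidationError(f"n_axes must be in [1, {len(eigval)}]")
        kept = list(range(n_axes))
    else:
        # strictly above the mean, with a numerical guard for exactly
        # degenerate spectra (all eigenvalues equal)
        kept = [k for k, ev in enumerate(eigval) if ev > eigval.mean() + 1e-9]
        if not kept:
            raise ValidationError(
                "Kaiser-Guttman retained no axis (all eigenvalues at the mean); "
                "pass an explicit axis count via n_axes"
            )
    return EnvPcaResult(
        scores=pd.DataFrame(scores, index=stations.station_ids, columns=axes),
        eigenvalues=eigval,
        variance_fractions=eigval / eigval.sum(),
        kept_axes=kept,
        loadings=pd.DataFrame(eigvec, index=stations.env.columns, columns=axes),
    )


def env_distance_matrix(pca: EnvPcaResult, *, weight: str = "none") -> DistanceMatrix:
    """Euclidean distance over the retained PCA axes.

    Scores already scale with the square root of each axis' eigenvalue, so
    the default uses them as-is; ``weight='varfrac'`` additionally multiplies
    each axis by its variance fraction (an alternative, more aggressive
    down-weighting of minor axes).
    """
    if not pca.kept_axes:
        raise ValidationError("no retained PCA axes")
    S = pca.scores.to_numpy()[:, pca.kept_axes]
    if weight == "varfrac":
        S = S * pca.variance_fractions[pca.kept_axes]
    elif weight != "none":
        raise ValueError(f"unknown weight {weight!r}")
    diff = S[:, None, :] - S[None, :, :]
    values = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(list(pca.scores.index), values, "environmental")


# ---------------------------------------------------------------------------
# oceanographic distances from Lagrangian products
# ---------------------------------------------------------------------------


@dataclass
class ConnectivitySet:
    """Directed Lagrangian connectivity inputs.

    ``pc_by_horizon`` maps a dispersal horizon in months (3, 6, 12) to a
    directed station x station matrix of connection probabilities; ``mct`` is
    the directed matrix of mean connection times in days.  Rows are source
    stations, columns destinations; asymmetry is expected.
    """

    pc_by_horizon: dict[int, pd.DataFrame]
    mct: pd.DataFrame

    def __post_init__(self) -> None:
        labels = list(self.mct.index)
        if list(self.mct.columns) != labels:
            raise ValidationError("MCT rows and columns are labelled differently")
        for h, m in self.pc_by_horizon.items():
            if list(m.index) != labels or list(m.columns) != labels:
                raise ValidationError(f"PC horizon {h} labels differ from MCT labels")
            vals = m.to_numpy(dtype=float)
            if (vals < 0).any() or (vals > 1).any():
                raise ValidationError(f"PC horizon {h}: probabilities outside [0, 1]")
        off = ~np.eye(len(labels), dtype=bool)
        if (self.mct.to_numpy(dtype=float)[off] <= 0).any():
            raise ValidationError("off-diagonal MCT entries must be positive days")

    @property
    def labels(self) -> list[str]:
        return list(self.mct.index)

    @classmethod
    def from_tsv(
        cls, pc_paths: Mapping[int, str | Path], mct_path: str | Path
    ) -> "ConnectivitySet":
        def load(p):
            df = pd.read_csv(p, sep="\t", index_col=0)
            df.index = df.index.astype(str)
            df.columns = df.columns.astype(str)
            return df

        return cls({int(h): load(p) for h, p in pc_paths.items()}, load(mct_path))


def oceanographic_distances(conn: ConnectivitySet) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Symmetrized oceanographic layers from directed Lagrangian matrices.

    PC: per directed pair, the mean over the dispersal horizons, then the
    maximum of the two directions.  MCT: the minimum of the two directions.
    Diagonals are neutral (PC self-connection ignored, MCT self = 0).
    """
    missing = [h for h in PC_HORIZONS_MONTHS if h not in conn.pc_by_horizon]
    if missing:
        raise ValidationError(f"missing PC horizons: {missing} (need {PC_HORIZONS_MONTHS})")
    labels = conn.labels
    pc_mean = np.mean(
        [conn.pc_by_horizon[h].to_numpy(dtype=float) for h in PC_HORIZONS_MONTHS], axis=0
    )
    pc_sym = np.maximum(pc_mean, pc_mean.T)
    np.fill_diagonal(pc_sym, 0.0)
    mct = conn.mct.to_numpy(dtype=float)
    mct_sym = np.minimum(mct, mct.T)
    np.fill_diagonal(mct_sym, 0.0)
    return (
        DistanceMatrix(labels, pc_sym, "pc_connectivity"),
        DistanceMatrix(labels, mct_sym, "mct"),
    )
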