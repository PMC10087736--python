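"""Least-cost sea distances, environmental PCA distance, Lagrangian layers."""

import numpy as np
import pandas as pd
import pytest

from picopop.core_tables import StationTable, ValidationError
from picopop.distances import (
    ConnectivitySet,
    SeaGrid,
    env_distance_matrix,
    env_pca,
    haversine_km,
    oceanographic_distances,
    sea_distance_matrix,
)


def stations_from(coords, env=None):
    ids = [f"s{i}" for i in range(len(coords))]
    df = pd.DataFrame(coords, columns=["lat", "lon"], index=pd.Index(ids, name="station_id"))
    if env is not None:
        for k, v in env.items():
            df[k] = v
    else:
        df["temperature"] = np.linspace(15, 20, len(coords))
        df["salinity"] = np.linspace(37, 39, len(coords))
    return StationTable(df)


# ---------------------------------------------------------------------------
# sea grid + geographic distance
# ---------------------------------------------------------------------------


def test_haversine_one_degree_at_equator():
    assert haversine_km(0.0, 0.0, 0.0, 1.0) == pytest.approx(111.19, abs=0.01)


def test_same_cell_stations_are_at_zero_distance():
    grid = SeaGrid(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]), np.ones((3, 3), bool))
    st = stations_from([(1.01, 1.02), (0.98, 0.97)])
    m = sea_distance_matrix(st, grid)
    assert m.get("s0", "s1") == 0.0


def test_adjacent_equatorial_cells_one_degree():
    grid = SeaGrid(np.array([-1.0, 0.0, 1.0]), np.array([0.0, 1.0, 2.0]), np.ones((3, 3), bool))
    st = stations_from([(0.0, 0.0), (0.0, 1.0)])
    m = sea_distance_matrix(st, grid)
    assert m.get("s0", "s1") == pytest.approx(111.19, abs=0.01)


def wall_grid():
    # 5x5 grid, land wall in column 2 except a gap at the top row
    mask = np.ones((5, 5), bool)
    mask[1:, 2] = False
    return SeaGrid(np.arange(40.0, 45.0), np.arange(0.0, 5.0), mask)


def test_wall_path_matches_networkx_dijkstra_oracle():
    import networkx as nx

    grid = wall_grid()
    st = stations_from([(42.0, 0.0), (42.0, 4.0)])
    m = sea_distance_matrix(st, grid)

    G = nx.Graph()
    cells = list(zip(*np.nonzero(grid.mask)))
    for i, j in cells:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if (di, dj) == (0, 0):
                    continue
                i2, j2 = i + di, j + dj
                if (i2, j2) in set(cells):
                    w = haversine_km(
                        grid.lat_axis[i], grid.lon_axis[j], grid.lat_axis[i2], grid.lon_axis[j2]
                    )
                    G.add_edge((i, j), (i2, j2), weight=w)
    src = grid.snap_station(42.0, 0.0)
    dst = grid.snap_station(42.0, 4.0)
    expected = nx.dijkstra_path_length(G, src, dst)
    assert m.get("s0", "s1") == pytest.approx(expected, rel=1e-9)
    # the wall forces a detour: strictly longer than the open-sea straight line
    assert m.get("s0", "s1") > haversine_km(42.0, 0.0, 42.0, 4.0)


def test_disconnected_components_raise_with_pair_names():
    mask = np.ones((3, 3), bool)
    mask[:, 1] = False  # full wall
    grid = SeaGrid(np.arange(3.0), np.arange(3.0), mask)
    st = stations_from([(1.0, 0.0), (1.0, 2.0)])
    with pytest.raises(ValidationError, match="s0.*s1|disconnected"):
        sea_distance_matrix(st, grid)


def test_opening_land_never_increases_distances():
    grid = wall_grid()
    st = stations_from([(42.0, 0.0), (42.0, 4.0), (44.0, 2.0)])
    before = sea_distance_matrix(st, grid).values
    open_mask = grid.mask.copy()
    open_mask[3, 2] = True  # breach the wall
    after = sea_distance_matrix(st, SeaGrid(grid.lat_axis, grid.lon_axis, open_mask)).values
    assert (after <= before + 1e-9).all()


def test_sea_distance_dominates_geodesic_of_snapped_cells():
    grid = wall_grid()
    st = stations_from([(40.0, 0.0), (44.0, 4.0), (42.0, 1.0)])
    m = sea_distance_matrix(st, grid)
    cells = [grid.snap_station(lat, lon) for lat, lon in zip(st.latitudes, st.longitudes)]
    diag = haversine_km(40.0, 0.0, 41.0, 1.0)  # one cell diagonal tolerance
    for a in range(3):
        for b in range(a + 1, 3):
            gc = haversine_km(
                grid.lat_axis[cells[a][0]],
                grid.lon_axis[cells[a][1]],
                grid.lat_axis[cells[b][0]],
                grid.lon_axis[cells[b][1]],
            )
            assert m.values[a, b] >= gc - diag


def test_snap_outside_radius_raises():
    grid = SeaGrid(np.array([0.0]), np.array([0.0]), np.ones((1, 1), bool))
    with pytest.raises(ValidationError, match="no sea cell"):
        grid.snap_station(50.0, 50.0, max_km=100.0)


def test_seagrid_text_round_trip(tmp_path):
    grid = wall_grid()
    grid.to_text(tmp_path / "g.txt")
    back = SeaGrid.from_text(tmp_path / "g.txt")
    np.testing.assert_array_equal(back.mask, grid.mask)
    np.testing.assert_allclose(back.lat_axis, grid.lat_axis)


# ---------------------------------------------------------------------------
# environmental PCA
# ---------------------------------------------------------------------------


def test_two_perfectly_correlated_variables_keep_one_axis():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    st = stations_from(
        [(0, 0), (0, 1), (0, 2), (0, 3)], env={"a": x, "b": 2 * x + 1}
    )
    pca = env_pca(st)
    assert pca.kept_axes == [0]
    assert pca.variance_fractions[0] == pytest.approx(1.0)


def test_exactly_uncorrelated_variables_error_advises_explicit_count():
    # centered orthogonal columns: sample correlation is the identity
    a = np.array([1.0, 1.0, -1.0, -1.0])
    b = np.array([1.0, -1.0, 1.0, -1.0])
    st = stations_from([(0, 0), (0, 1), (0, 2), (0, 3)], env={"a": a, "b": b})
    with pytest.raises(ValidationError, match="n_axes"):
        env_pca(st)
    pca = env_pca(st, n_axes=2)
    assert pca.kept_axes == [0, 1]


def test_constant_variable_rejected():
    st = stations_from(
        [(0, 0), (0, 1), (0, 2)], env={"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]}
    )
    with pytest.raises(ValidationError, match="constant"):
        env_pca(st)


def test_eigenvalues_sum_to_variable_count(rng):
    env = {f"v{k}": rng.normal(size=8) for k in range(5)}
    st = stations_from([(0, float(i)) for i in range(8)], env=env)
    pca = env_pca(st)
    assert pca.eigenvalues.sum() == pytest.approx(5.0)
    assert all(pca.eigenvalues[k] > 1.0 for k in pca.kept_axes)
    # scores variance equals eigenvalue (correlation PCA convention)
    v = pca.scores.var(ddof=1).to_numpy()
    np.testing.assert_allclose(v, pca.eigenvalues, atol=1e-8)


def test_env_distance_pythagoras_and_brute_force(rng):
    from picopop.distances import EnvPcaResult

    scores = pd.DataFrame(
        [[0.0, 0.0], [3.0, 4.0]], index=["a", "b"], columns=["PC1", "PC2"]
    )
    pca = EnvPcaResult(scores, np.array([1.5, 0.5]), np.array([0.75, 0.25]), [0, 1])
    m = env_distance_matrix(pca)
    assert m.get("a", "b") == pytest.approx(5.0)

    S = rng.normal(size=(5, 3))
    pca = EnvPcaResult(
        pd.DataFrame(S, index=[f"s{i}" for i in range(5)], columns=["PC1", "PC2", "PC3"]),
        np.ones(3),
        np.ones(3) / 3,
        [0, 1, 2],
    )
    m = env_distance_matrix(pca)
    for i in range(5):
        for j in range(5):
            assert m.values[i, j] == pytest.approx(np.sqrt(((S[i] - S[j]) ** 2).sum()))


def test_env_distance_triangle_inequality(rng):
    from picopop.distances import EnvPcaResult

    S = rng.normal(size=(6, 2))
    pca = EnvPcaResult(
        pd.DataFrame(S, index=[f"s{i}" for i in range(6)], columns=["PC1", "PC2"]),
        np.ones(2),
        np.ones(2) / 2,
        [0, 1],
    )
    d = env_distance_matrix(pca).values
    for a in range(6):
        for b in range(6):
            for c in range(6):
                assert d[a, b] <= d[a, c] + d[c, b] + 1e-9


# ---------------------------------------------------------------------------
# oceanographic distances
# ---------------------------------------------------------------------------


def make_conn(pc_ab=(0.1, 0.2, 0.6), pc_ba=(0.5, 0.5, 0.5), mct_ab=80.0, mct_ba=30.0):
    labels = ["a", "b"]

    def mat(v_ab, v_ba, diag):
        return pd.DataFrame(
            [[diag, v_ab], [v_ba, diag]], index=labels, columns=labels
        )

    pcs = {h: mat(pc_ab[k], pc_ba[k], 1.0) for k, h in enumerate((3, 6, 12))}
    return ConnectivitySet(pcs, mat(mct_ab, mct_ba, 0.0))


def test_pc_mean_over_horizons_then_max_rule():
    conn = make_conn()
    pc, mct = oceanographic_distances(conn)
    # a->b mean = 0.3, b->a mean = 0.5 -> symmetrized to 0.5
    assert pc.get("a", "b") == pytest.approx(0.5)
    assert pc.values[0, 0] == 0.0  # self-connection neutralized


def test_mct_min_rule():
    conn = make_conn()
    _, mct = oceanographic_distances(conn)
    assert mct.get("a", "b") == pytest.approx(30.0)


def test_missing_horizon_rejected():
    conn = make_conn()
    del conn.pc_by_horizon[6]
    with pytest.raises(ValidationError, match="horizons"):
        oceanographic_distances(conn)


def test_label_mismatch_rejected():
    labels = ["a", "b"]
    pc = pd.DataFrame(np.eye(2), index=labels, columns=labels)
    mct = pd.DataFrame([[0.0, 5.0], [5.0, 0.0]], index=["a", "x"], columns=["a", "x"])
    with pytest.raises(ValidationError):
        ConnectivitySet({3: pc, 6: pc, 12: pc}, mct)


def test_connectivity_tsv_round_trip(tmp_path):
    conn = make_conn()
    paths = {}
    for h, df in conn.pc_by_horizon.items():
        p = tmp_path / f"pc_{h}.tsv"
        df.to_csv(p, sep="\t", index_label="station")
        paths[h] = p
    mp = tmp_path / "mct.tsv"
    conn.mct.to_csv(mp, sep="\t", index_label="station")
    back = ConnectivitySet.from_tsv(paths, mp)
    pd.testing.assert_frame_equal(back.mct, conn.mct, check_names=False)
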