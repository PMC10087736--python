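"""Allele-count I/O and the per-station vertical-coverage filter."""

import logging

import numpy as np
import pandas as pd
import pytest

from picopop.core_tables import (
    AlleleCountTable,
    DistanceMatrix,
    ParseError,
    SnpRecord,
    StationTable,
    ValidationError,
    filter_snps_by_coverage,
    read_allele_counts,
    write_allele_counts,
    write_vcf,
)

from conftest import make_table, random_table


# ---------------------------------------------------------------------------
# TSV round trip and validation
# ---------------------------------------------------------------------------


def test_tsv_round_trip_is_bit_identical(toy_table, tmp_path):
    p1 = tmp_path / "a.tsv"
    p2 = tmp_path / "b.tsv"
    write_allele_counts(toy_table, p1)
    table = read_allele_counts(p1, "tsv")
    assert table.n_snps == 3
    assert table.stations == ["s1", "s2"]
    assert len(list(table.records())) == 3
    write_allele_counts(table, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_tsv_duplicate_cell_rejected(tmp_path):
    path = tmp_path / "dup.tsv"
    header = "snp_id\tcontig\tpos\tref\talt\tstation\tref_count\talt_count\n"
    row = "x1\tc1\t10\tA\tG\tstA\t3\t2\n"
    path.write_text(header + row + row)
    with pytest.raises(ValidationError, match="duplicate cell"):
        read_allele_counts(path, "tsv")


def test_tsv_malformed_row_reports_line_number(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "snp_id\tcontig\tpos\tref\talt\tstation\tref_count\talt_count\n"
        "x1\tc1\t10\tA\tG\tstA\t3\t2\n"
        "x2\tc1\toops\tA\tG\tstA\t3\t2\n"
    )
    with pytest.raises(ParseError, match="line 3"):
        read_allele_counts(path, "tsv")


def test_snp_record_rejects_bad_alleles():
    with pytest.raises(ValidationError):
        SnpRecord("x", "c1", 5, "A", "A", {})
    with pytest.raises(ValidationError):
        SnpRecord("x", "c1", 5, "A", "AT", {})


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampA\tsampB\n"
)


def test_vcf_multiallelic_keeps_majority_alt(tmp_path):
    # alt C has 3+1=4 supporting reads, alt T has 2+4=6 -> keep T
    path = tmp_path / "m.vcf"
    path.write_text(
        VCF_HEADER + "c1\t100\t.\tA\tC,T\t.\tPASS\t.\tAD\t5,3,2\t4,1,4\n"
    )
    table = read_allele_counts(
        path, "vcf", sample_map={"sampA": "st1", "sampB": "st2"}
    )
    rec = table.record("c1:100")
    assert rec.alt_allele == "T"
    assert rec.counts == {"st1": (5, 2), "st2": (4, 4)}


def test_vcf_indels_are_dropped(tmp_path):
    path = tmp_path / "i.vcf"
    path.write_text(
        VCF_HEADER
        + "c1\t100\t.\tA\tAT\t.\tPASS\t.\tAD\t5,3\t4,1\n"
        + "c1\t200\t.\tA\tG\t.\tPASS\t.\tAD\t6,2\t1,7\n"
    )
    table = read_allele_counts(path, "vcf", sample_map={"sampA": "st1", "sampB": "st2"})
    assert table.snp_ids == ["c1:200"]


def test_vcf_requires_sample_map(tmp_path):
    path = tmp_path / "s.vcf"
    path.write_text(VCF_HEADER + "c1\t1\t.\tA\tG\t.\tPASS\t.\tAD\t1,1\t2,2\n")
    with pytest.raises(ValidationError):
        read_allele_counts(path, "vcf")


def test_write_vcf_round_trip(toy_table, tmp_path):
    path = tmp_path / "out.vcf"
    write_vcf(toy_table, path)
    back = read_allele_counts(path, "vcf", sample_map={"s1": "s1", "s2": "s2"})
    pd.testing.assert_frame_equal(back.alt_counts, toy_table.alt_counts, check_names=False)


# ---------------------------------------------------------------------------
# coverage filter
# ---------------------------------------------------------------------------


def test_filter_window_on_known_coverage_vector():
    # one station, coverages ten 5s, one 3, one 60:
    # mu = 113/12 ~ 9.417, sample sigma ~ 15.94, upper bound ~ 41.3
    cov = np.array([5] * 10 + [3, 60])
    alt = np.ones_like(cov)
    table = make_table((cov - alt)[:, None], alt[:, None])
    out = filter_snps_by_coverage(table)
    assert out.n_snps == 10
    assert set(out.coverage().to_numpy().ravel()) == {5}
    mu, sigma = cov.mean(), cov.std(ddof=1)
    assert mu == pytest.approx(113 / 12)
    assert mu + 2 * sigma == pytest.approx(41.3, abs=0.05)


def test_filter_equal_coverage_gives_empty_window():
    # all coverages 4: sigma = 0, window [4, 4) is empty
    table = make_table(np.full((6, 1), 3), np.full((6, 1), 1))
    out = filter_snps_by_coverage(table)
    assert out.n_snps == 0


def test_snp_with_zero_coverage_cell_survives_elsewhere():
    ref = [[4, 0], [7, 4]]
    alt = [[2, 0], [3, 2]]
    table = make_table(ref, alt)
    out = filter_snps_by_coverage(table, sigma_mult=100)
    assert out.n_snps == 2
    assert out.coverage().loc["snp0001", "s2"] == 0


def test_filter_single_covered_snp_applies_only_floor(caplog):
    # station s2 covers a single SNP: sigma undefined, only the floor applies
    ref = [[4, 40], [4, 0], [4, 0]]
    alt = [[2, 10], [2, 0], [2, 0]]
    table = make_table(ref, alt)
    with caplog.at_level(logging.WARNING):
        out = filter_snps_by_coverage(table)
    assert "sigma undefined" in caplog.text
    assert out.coverage().loc["snp0001", "s2"] == 50


def test_filter_retained_cells_match_brute_force(rng):
    def oracle(table, min_cov=4, sigma_mult=2.0, min_alt=1):
        cov = table.coverage().to_numpy()
        alt = table.alt_counts.to_numpy()
        keep = np.zeros(cov.shape, bool)
        for j in range(cov.shape[1]):
            covered = [c for c in cov[:, j] if c >= 1]
            if not covered:
                continue
            if len(covered) < 2:
                upper = np.inf
            else:
                upper = np.mean(covered) + sigma_mult * np.std(covered, ddof=1)
            for i in range(cov.shape[0]):
                c = cov[i, j]
                keep[i, j] = c >= min_cov and c < upper and alt[i, j] >= min_alt
        return keep

    for _ in range(25):
        table = random_table(rng, n_snps=int(rng.integers(5, 50)), n_stations=5)
        expected = oracle(table)
        got = filter_snps_by_coverage(table).observed()
        full = pd.DataFrame(False, index=table.snp_meta.index, columns=table.ref_counts.columns)
        full.loc[got.index] = got
        assert np.array_equal(full.to_numpy(), expected)


def test_filter_is_non_increasing_under_reapplication(rng):
    for _ in range(10):
        table = random_table(rng, n_snps=40, n_stations=4)
        once = filter_snps_by_coverage(table)
        if once.n_snps == 0:
            continue
        twice = filter_snps_by_coverage(once)
        cells_once = set(zip(*np.nonzero(once.observed().to_numpy())))
        obs2 = twice.observed()
        full = pd.DataFrame(False, index=once.snp_meta.index, columns=once.ref_counts.columns)
        full.loc[obs2.index] = obs2
        cells_twice = set(zip(*np.nonzero(full.to_numpy())))
        assert cells_twice <= cells_once


def test_alt_support_mode_uses_alternate_reads():
    ref = [[10], [2]]
    alt = [[1], [8]]
    table = make_table(ref, alt)
    out = filter_snps_by_coverage(table, min_cov=4, sigma_mult=100, support="alt")
    assert out.snp_ids == ["snp0002"]


# ---------------------------------------------------------------------------
# station table and distance matrix containers
# ---------------------------------------------------------------------------


def test_station_table_rejects_missing_env(tmp_path):
    df = pd.DataFrame(
        {"lat": [1.0, 2.0], "lon": [3.0, 4.0], "temperature": [20.0, np.nan]},
        index=["a", "b"],
    )
    with pytest.raises(ValidationError, match="missing environmental"):
        StationTable(df)


def test_station_table_csv_round_trip(tmp_path):
    df = pd.DataFrame(
        {"lat": [1.0, 2.0], "lon": [3.0, 4.0], "temperature": [20.0, 21.0]},
        index=pd.Index(["a", "b"], name="station_id"),
    )
    st = StationTable(df)
    st.to_csv(tmp_path / "st.csv")
    back = StationTable.from_csv(tmp_path / "st.csv")
    pd.testing.assert_frame_equal(back.data, st.data)


def test_distance_matrix_validation():
    with pytest.raises(ValidationError, match="symmetric"):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]), "geographic")
    with pytest.raises(ValidationError, match="missing"):
        DistanceMatrix(["a", "b"], np.array([[0.0, np.nan], [np.nan, 0.0]]), "geographic")
    # NaN is fine for genomic
    DistanceMatrix(["a", "b"], np.array([[0.0, np.nan], [np.nan, 0.0]]), "genomic")


def test_distance_matrix_tsv_na_round_trip(tmp_path):
    m = DistanceMatrix(
        ["a", "b", "c"],
        np.array([[0.0, 0.2, np.nan], [0.2, 0.0, 0.4], [np.nan, 0.4, 0.0]]),
        "genomic",
    )
    m.to_tsv(tmp_path / "m.tsv")
    assert "NA" in (tmp_path / "m.tsv").read_text()
    back = DistanceMatrix.from_tsv(tmp_path / "m.tsv", "genomic")
    np.testing.assert_array_equal(np.isnan(back.values), np.isnan(m.values))
    np.testing.assert_allclose(back.values[~np.isnan(m.values)], m.values[~np.isnan(m.values)])
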