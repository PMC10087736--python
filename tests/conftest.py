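import numpy as np
import pandas as pd
import pytest

from picopop.core_tables import AlleleCountTable


def make_table(ref: np.ndarray, alt: np.ndarray, stations=None, label="toy") -> AlleleCountTable:
    """Build an AlleleCountTable from (n_snps, n_stations) count arrays."""
    ref = np.asarray(ref, dtype=int)
    alt = np.asarray(alt, dtype=int)
    m, n = ref.shape
    stations = stations or [f"s{j + 1}" for j in range(n)]
    ids = pd.Index([f"snp{i + 1:04d}" for i in range(m)], name="snp_id")
    meta = pd.DataFrame(
        {"contig": "c1", "pos": np.arange(1, m + 1) * 5, "ref": "A", "alt": "G"}, index=ids
    )
    return AlleleCountTable(
        label,
        meta,
        pd.DataFrame(ref, index=ids, columns=stations),
        pd.DataFrame(alt, index=ids, columns=stations),
    )


def random_table(rng: np.random.Generator, n_snps=30, n_stations=4) -> AlleleCountTable:
    """Random sparse counts: roughly half the cells covered."""
    cov = rng.poisson(6, size=(n_snps, n_stations)) * rng.integers(0, 2, size=(n_snps, n_stations))
    alt = rng.binomial(cov, rng.uniform(0.1, 0.9, size=(n_snps, 1)))
    return make_table(cov - alt, alt)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_table():
    # 3 SNPs x 2 stations, every cell observed
    ref = [[8, 4], [0, 3], [5, 5]]
    alt = [[2, 6], [5, 2], [5, 5]]
    return make_table(ref, alt)
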