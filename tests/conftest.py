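"""Shared fixtures: the worked single-site example and small populations."""

import numpy as np
import pandas as pd
import pytest

from jsdscan import SiteCountMatrix
from jsdscan.io import write_methylation_table

#: The worked three-methylome site: counts (methylated, unmethylated).
WORKED_COUNTS = [(15, 0), (11, 1), (5, 4)]


@pytest.fixture
def worked_site() -> SiteCountMatrix:
    return SiteCountMatrix(WORKED_COUNTS, chrom="Chr1", pos=100)


@pytest.fixture
def worked_tables() -> list[pd.DataFrame]:
    """The worked site as three single-row methylation tables."""
    return [
        pd.DataFrame({"chrom": ["Chr1"], "pos": [100], "n_meth": [m], "n_unmeth": [u]})
        for m, u in WORKED_COUNTS
    ]


def random_count_matrix(rng: np.random.Generator, max_rows: int = 6,
                        max_states: int = 2, max_count: int = 40) -> np.ndarray:
    """A random count matrix with at least one positive entry."""
    while True:
        s = rng.integers(1, max_rows + 1)
        k = 2 if max_states == 2 else rng.integers(2, max_states + 1)
        counts = rng.integers(0, max_count + 1, size=(s, k))
        if counts.sum() > 0:
            return counts


@pytest.fixture
def three_sample_files(tmp_path):
    """Three on-disk MethylDackel-style tables spanning several positions."""
    paths = []
    rng = np.random.default_rng(7)
    for j in range(3):
        pos = np.arange(0, 50) * 10
        df = pd.DataFrame({
            "chrom": "Chr1",
            "pos": pos,
            "n_meth": rng.integers(0, 20, size=len(pos)),
            "n_unmeth": rng.integers(0, 20, size=len(pos)),
        })
        p = tmp_path / f"s{j}.bedGraph"
        write_methylation_table(df, p, dialect="methyldackel_bedgraph")
        paths.append(str(p))
    return paths
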