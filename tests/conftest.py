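import numpy as np
import pytest

from microclust.io import OtuCountTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table():
    """3 samples x 2 OTUs with counts [[0,5],[2,0],[7,1]]."""
    return OtuCountTable(
        ["s1", "s2", "s3"], ["o1", "o2"], np.array([[0, 5], [2, 0], [7, 1]])
    )


@pytest.fixture
def toy_tsv(tmp_path, toy_table):
    path = tmp_path / "counts.tsv"
    toy_table.to_dataframe().to_csv(path, sep="\t")
    return path


def random_distance_matrix(rng, n):
    """Symmetric zero-diagonal random matrix (not necessarily metric)."""
    M = rng.uniform(0.1, 1.0, size=(n, n))
    M = 0.5 * (M + M.T)
    np.fill_diagonal(M, 0.0)
    return M
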