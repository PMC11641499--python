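import numpy as np
import pytest

from sigrn import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """5 cells x 4 genes with simple integer values."""
    vals = np.arange(20, dtype=float).reshape(5, 4)
    return ExpressionMatrix(vals, [f"c{i}" for i in range(5)], [f"g{i}" for i in range(4)])


@pytest.fixture
def csv_matrix(tmp_path):
    path = tmp_path / "expr.csv"
    path.write_text("\n".join([
        ",g1,g2",
        "c1,0,1",
        "c2,2,3",
        "c3,4,5",
    ]) + "\n")
    return path
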