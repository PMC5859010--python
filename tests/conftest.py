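import numpy as np
import pytest

from itemboot import ScaleSpec


@pytest.fixture
def likert5():
    """Five-point scale with five items."""
    return ScaleSpec(n_items=5, scale_min=1, scale_max=5)


@pytest.fixture
def hand_matrix():
    """Fixed 4-respondent x 3-item matrix with a hand-computed alpha.

    Item variances 5/3 + 5/3 + 11/12 = 17/4 (n-1 denominator); total scores
    (6, 10, 11, 14) have variance 131/12, so
    alpha = (3/2) * (1 - (51/12)/(131/12)) = 120/131.
    """
    return np.array([[1, 2, 3], [2, 4, 4], [3, 3, 5], [4, 5, 5]])


@pytest.fixture
def write_csv(tmp_path):
    """Write a respondents x items matrix (with ids) to a CSV file."""

    def _write(name, matrix, ids=None, header=None):
        matrix = np.asarray(matrix)
        n, j = matrix.shape
        ids = ids if ids is not None else [f"r{i+1}" for i in range(n)]
        header = header if header is not None else [f"item{k+1}" for k in range(j)]
        lines = ["id," + ",".join(header)]
        for rid, row in zip(ids, matrix):
            lines.append(str(rid) + "," + ",".join(str(int(v)) for v in row))
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
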