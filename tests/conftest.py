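import numpy as np
import pytest
from hypothesis import settings

from dompop import MarkerMatrix

# property tests must replay identically from run to run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def brute_force_mic(M: np.ndarray) -> int:
    """Independent four-gamete count: plain double loop over locus pairs
    and rows, used as the oracle for the vectorised implementation.
    Missing entries (-1) are skipped pairwise."""
    n, L = M.shape
    mic = 0
    for i in range(L):
        for j in range(i + 1, L):
            combos = set()
            for r in range(n):
                a, b = int(M[r, i]), int(M[r, j])
                if a >= 0 and b >= 0:
                    combos.add((a, b))
            mic += combos == {(0, 0), (0, 1), (1, 0), (1, 1)}
    return mic


@pytest.fixture
def toy_incompatible():
    """The 4-genotype, 3-locus matrix in which every locus pair shows all
    four state combinations: MIC = 3 and any single deletion zeroes it."""
    return np.array([[0, 0, 0], [0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.int8)


@pytest.fixture
def treelike():
    """A matrix realisable by single mutations on a tree (MIC = 0)."""
    return np.array([[1, 0, 0], [1, 1, 0], [0, 0, 1]], dtype=np.int8)


@pytest.fixture
def small_matrix():
    bands = np.array(
        [[1, 0, 1, 1],
         [1, 0, 1, 1],
         [0, 1, 1, 0],
         [1, 1, -1, 0],
         [0, 0, 1, 1],
         [1, 1, 0, 0]], dtype=np.int8)
    return MarkerMatrix(
        bands,
        [f"ind{i}" for i in range(6)],
        ["A", "A", "A", "B", "B", "B"],
        [f"L{j}" for j in range(4)],
    )


@pytest.fixture
def matrix_file(tmp_path, small_matrix):
    from dompop import write_matrix
    p = tmp_path / "bands.tsv"
    write_matrix(small_matrix, p)
    return p
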