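import numpy as np
import pytest
from Bio.Align import substitution_matrices

from rbhkit.align import ScoringScheme

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def blosum62():
    """BLOSUM62 as a plain (residue, residue) -> int dict, straight from biopython."""
    mat = substitution_matrices.load("BLOSUM62")
    alph = str(mat.alphabet)
    return {(x, y): int(mat[i, j]) for i, x in enumerate(alph) for j, y in enumerate(alph)}


@pytest.fixture(scope="session")
def sw_oracle(blosum62):
    """Reference Smith-Waterman score: plain-Python Gotoh DP, affine gaps.

    A gap of length L costs go + L * ge.  Kept deliberately naive and
    independent of the package's aligner.
    """

    def _score(a: str, b: str, go: int = 11, ge: int = 1) -> int:
        NEG = -(10**9)
        n, m = len(a), len(b)
        H = [[0] * (m + 1) for _ in range(n + 1)]
        E = [[NEG] * (m + 1) for _ in range(n + 1)]
        F = [[NEG] * (m + 1) for _ in range(n + 1)]
        best = 0
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                E[i][j] = max(H[i][j - 1] - go - ge, E[i][j - 1] - ge)
                F[i][j] = max(H[i - 1][j] - go - ge, F[i - 1][j] - ge)
                H[i][j] = max(
                    0,
                    H[i - 1][j - 1] + blosum62[a[i - 1], b[j - 1]],
                    E[i][j],
                    F[i][j],
                )
                best = max(best, H[i][j])
        return best

    return _score


def random_protein(rng: np.random.Generator, lo: int = 10, hi: int = 60) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(AA20[i] for i in rng.integers(0, 20, length))
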