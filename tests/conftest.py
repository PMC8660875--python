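import numpy as np
import pytest

from fluencynet import AssociationMatrix, FluencyRecord, build_response_matrix


def random_association(n: int, seed: int) -> AssociationMatrix:
    """Seeded symmetric association matrix with positive off-diagonals."""
    rng = np.random.default_rng(seed)
    v = rng.uniform(0.01, 1.0, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return AssociationMatrix(labels=[f"w{i:03d}" for i in range(n)], values=v)


def toy_records(group: str, lists: dict[str, list[str]]) -> list[FluencyRecord]:
    return [FluencyRecord(pid, group, tuple(resp)) for pid, resp in lists.items()]


@pytest.fixture
def small_matrices():
    """Two tiny pre-normalised groups with overlapping vocabularies."""
    mat_a = build_response_matrix(
        toy_records(
            "A",
            {
                "A1": ["cat", "dog", "fox", "owl"],
                "A2": ["cat", "dog", "owl"],
                "A3": ["cat", "fox", "hen"],
                "A4": ["dog", "fox", "owl", "hen"],
            },
        )
    )
    mat_b = build_response_matrix(
        toy_records(
            "B",
            {
                "B1": ["cat", "dog", "owl", "ant"],
                "B2": ["cat", "owl", "ant"],
                "B3": ["dog", "owl", "cat"],
                "B4": ["dog", "ant", "cat", "owl"],
            },
        )
    )
    return mat_a, mat_b
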