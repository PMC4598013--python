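import numpy as np
import pytest

from hc4n.data_io import IPMSMatrix, OCCURRENCE


def occurrence_matrix(rows: dict[str, str]) -> IPMSMatrix:
    """Build an occurrence matrix from strings of 0/1 per protein."""
    protein_ids = list(rows)
    width = len(next(iter(rows.values())))
    values = np.array([[float(ch) for ch in rows[p]] for p in protein_ids])
    return IPMSMatrix(protein_ids, [f"ip{j}" for j in range(width)], values, OCCURRENCE)


@pytest.fixture
def small_matrix() -> IPMSMatrix:
    """3 proteins x 4 IPs; a occupies {0,1,2}, b {1,2,3}, c {3}."""
    return occurrence_matrix({"a": "1110", "b": "0111", "c": "0001"})


@pytest.fixture
def two_cliques() -> IPMSMatrix:
    """Two groups with identical within-group occupancy, disjoint across."""
    return occurrence_matrix(
        {
            "a1": "1100",
            "a2": "1100",
            "a3": "1100",
            "b1": "0011",
            "b2": "0011",
            "b3": "0011",
        }
    )


@pytest.fixture
def planted_hierarchy_matrix() -> IPMSMatrix:
    """Two cores that share IPs within one complex, plus an unrelated core.

    Cores A = {a1,a2,a3} and B = {b1,b2,b3} are pulled down together in 4
    complex-level IPs and separately in 3 IPs each; core D = {d1,d2,d3} has
    4 IPs of its own.  Within-core co-occurrence is 1 everywhere; A-B pairs
    co-occur at 4/10 = 0.4; A-D and B-D never co-occur.
    """
    complex_ips = "1111"
    return occurrence_matrix(
        {
            "a1": complex_ips + "111" + "000" + "0000",
            "a2": complex_ips + "111" + "000" + "0000",
            "a3": complex_ips + "111" + "000" + "0000",
            "b1": complex_ips + "000" + "111" + "0000",
            "b2": complex_ips + "000" + "111" + "0000",
            "b3": complex_ips + "000" + "111" + "0000",
            "d1": "0000" + "000" + "000" + "1111",
            "d2": "0000" + "000" + "000" + "1111",
            "d3": "0000" + "000" + "000" + "1111",
        }
    )


def random_occurrence_matrix(rng: np.random.Generator, max_proteins: int = 10, max_ips: int = 12) -> IPMSMatrix:
    """Random dense-ish occurrence matrix with no empty rows or columns."""
    n = int(rng.integers(3, max_proteins + 1))
    m = int(rng.integers(3, max_ips + 1))
    for _ in range(200):
        values = (rng.random((n, m)) < rng.uniform(0.2, 0.7)).astype(float)
        if values.any(axis=1).all() and values.any(axis=0).all():
            return IPMSMatrix([f"p{i:02d}" for i in range(n)], [f"ip{j:02d}" for j in range(m)], values, OCCURRENCE)
    raise RuntimeError("could not draw a valid random matrix")
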