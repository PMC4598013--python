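"""The three similarity measures behind near-neighbor-network strictness.

Two proteins are similar when they co-occur across IP experiments
(co-occurrence, a Jaccard index over occupied-IP sets) and, for abundance
data, when their abundance profiles point in a similar direction (a small
angle between profile vectors).  A protein *set* is tight when a large
fraction of its pairs meets the co-occurrence threshold (set-wise
completeness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from hc4n.data_io import ABUNDANCE, OCCURRENCE, IPMSMatrix

#: slack for >=-threshold comparisons on values that are ratios of small
#: integers, so that e.g. a co-occurrence of 7/20 passes a 0.35 threshold
#: despite float rounding
PASS_EPS = 1e-9


def passes(value: float, threshold: float) -> bool:
    """value >= threshold, tolerant to float representation error."""
    return value >= threshold - PASS_EPS


@dataclass
class SimilarityThresholds:
    """Strictness triple for near-neighbor-network construction.

    Parameters
    ----------
    t_co:
        Co-occurrence threshold in [0, 1]: in how many IPs two proteins must
        co-occur relative to the IPs where either occurs.  ``None`` marks it
        for automatic selection.
    t_comp:
        Set-wise completeness threshold in [0, 1]: how exhaustively the
        within-network pairs must meet ``t_co``; 1 forces cliques at level
        ``t_co``, lower values allow looser, overlapping networks.  ``None``
        marks it for automatic selection.
    t_ab:
        Abundance-similarity threshold: the maximum angle, in degrees
        ([0, 90]), between two abundance profiles.  Ignored for 0/1 data.
        Default 40.
    """

    t_co: float | None = None
    t_comp: float | None = None
    t_ab: float = 40.0

    def __post_init__(self) -> None:
        for name, v, hi in (("t_co", self.t_co, 1.0), ("t_comp", self.t_comp, 1.0), ("t_ab", self.t_ab, 90.0)):
            if v is None:
                continue
            if not (0.0 <= v <= hi):
                raise ValueError(f"{name}={v} outside [0, {hi}]")
        if self.t_ab is None:
            raise ValueError("t_ab must be a number (default 40), not None")

    @property
    def is_complete(self) -> bool:
        return self.t_co is not None and self.t_comp is not None

    def require_complete(self) -> None:
        if not self.is_complete:
            raise ValueError(
                "thresholds incomplete: t_co/t_comp unset — resolve with auto_thresholds first"
            )


@dataclass
class CoOccurrenceMatrix:
    """Symmetric protein-by-protein co-occurrence grid with unit diagonal."""

    protein_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.protein_ids)
        if self.values.shape != (n, n):
            raise ValueError("co-occurrence grid shape does not match protein count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("co-occurrence grid is not symmetric")
        if np.any(self.values < -PASS_EPS) or np.any(self.values > 1 + PASS_EPS):
            raise ValueError("co-occurrence values outside [0, 1]")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("co-occurrence diagonal must be 1")
        self._index = {p: i for i, p in enumerate(self.protein_ids)}

    def index(self, protein: str) -> int:
        try:
            return self._index[protein]
        except KeyError:
            raise KeyError(f"unknown protein identifier: {protein!r}") from None

    def value(self, i: str, j: str) -> float:
        return float(self.values[self.index(i), self.index(j)])

    def submatrix(self, proteins: Iterable[str]) -> np.ndarray:
        idx = [self.index(p) for p in proteins]
        return self.values[np.ix_(idx, idx)]


def co_occurrence(m: IPMSMatrix, i: str, j: str) -> float:
    """Jaccard co-occurrence of two proteins over their occupied-IP sets.

    |IPs where both occur| / |IPs where at least one occurs|.  1 iff the two
    occupied-IP sets are identical; 0 iff they are disjoint.
    """
    a = m.occupancy[m.protein_index(i)]
    b = m.occupancy[m.protein_index(j)]
    union = int(np.sum(a | b))
    return float(np.sum(a & b)) / union  # union > 0 by matrix invariant


def co_occurrence_matrix(m: IPMSMatrix) -> CoOccurrenceMatrix:
    """All-pairs co-occurrence, vectorized."""
    occ = m.occupancy.astype(float)
    inter = occ @ occ.T
    sizes = occ.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        values = inter / union
    # all unions positive by matrix invariant; guard anyway
    values = np.nan_to_num(values, nan=0.0)
    np.fill_diagonal(values, 1.0)
    return CoOccurrenceMatrix(list(m.protein_ids), values)


def abundance_angle(m: IPMSMatrix, i: str, j: str) -> float:
    """Angle in degrees between two abundance profiles (arccos of cosine
    similarity); 0 for proportional profiles, 90 for disjoint support."""
    if m.data_kind != ABUNDANCE:
        raise ValueError(
            "abundance_angle requires abundance data; the abundance criterion "
            "is not applicable for 0/1 occurrence data"
        )
    a = m.values[m.protein_index(i)]
    b = m.values[m.protein_index(j)]
    cos = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return math.degrees(math.acos(min(1.0, max(-1.0, cos))))


def passes_abundance(m: IPMSMatrix, i: str, j: str, t_ab: float) -> bool:
    """True iff the abundance criterion holds (vacuously true for 0/1 data)."""
    if m.data_kind == OCCURRENCE:
        return True
    return passes(t_ab, abundance_angle(m, i, j))


def set_completeness(c: CoOccurrenceMatrix, s: Iterable[str], t_co: float) -> float:
    """Fraction of unordered pairs within ``s`` whose co-occurrence meets
    ``t_co`` — 1 when the set is a clique at level ``t_co``."""
    sub = c.submatrix(s)
    n = sub.shape[0]
    if n < 2:
        raise ValueError("set-wise completeness needs at least 2 proteins")
    iu = np.triu_indices(n, k=1)
    pairs = sub[iu]
    return float(np.sum(pairs >= t_co - PASS_EPS)) / len(pairs)


def min_co_occurrence(c: CoOccurrenceMatrix, s: Iterable[str]) -> float:
    """Minimum pairwise co-occurrence within a set — the value by which a
    cluster's protein similarity (and hence interaction level) is judged."""
    sub = c.submatrix(s)
    n = sub.shape[0]
    if n < 2:
        raise ValueError("min co-occurrence needs at least 2 proteins")
    iu = np.triu_indices(n, k=1)
    return float(sub[iu].min())
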