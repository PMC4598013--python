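"""Complex-prediction quality scores (Brohée & van Helden scheme).

Given a reference catalog of complexes and a set of predicted clusters, the
contingency table T holds T[i, j] = |complex_i ∩ cluster_j|.  From it:

- sensitivity  Sn = Σ_i max_j T[i, j] / Σ_i N_i   (N_i = |complex_i|):
  the size-weighted fraction of each complex recovered by its best cluster;
- positive predictive value  PPV = Σ_j max_i T[i, j] / Σ_j Σ_i T[i, j]:
  the marginal-weighted purity of each cluster w.r.t. its best complex;
- accuracy = sqrt(Sn × PPV), their geometric mean;
- separation: with F[i, j] = (T[i, j] / row_sum_i) × (T[i, j] / col_sum_j),
  the complex-wise separation is the mean over i of Σ_j F[i, j], the
  cluster-wise separation the mean over j of Σ_i F[i, j], and the overall
  separation the geometric mean of the two.  Separation is 1 exactly when
  predicted clusters and reference complexes match one-to-one, and drops
  when one complex is smeared across several clusters (or vice versa).

Caveat worth knowing: only each complex's best-matching cluster enters the
sensitivity, so producing many spurious clusters does not hurt accuracy;
clusters made of proteins outside the reference contribute zero column
marginals and thus do not dilute the PPV either.  Separation is the score
that penalizes over-splitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from hc4n.data_io import ClusterSet, ComplexCatalog
from hc4n.fourn import join_clusters

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """Complex-by-cluster intersection counts plus per-complex sizes."""

    t: np.ndarray
    n: np.ndarray
    complex_ids: list[str]
    cluster_ids: list[str]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        if self.t.shape != (len(self.complex_ids), len(self.cluster_ids)):
            raise ValueError("contingency shape mismatch")
        if np.any(self.t < 0) or np.any(self.t.max(axis=1, initial=0) > self.n):
            raise ValueError("intersection counts exceed complex sizes or are negative")


@dataclass
class EvaluationReport:
    sensitivity: float
    ppv: float
    accuracy: float
    separation: float
    table: ContingencyTable

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "accuracy": self.accuracy,
            "separation": self.separation,
            "n_complexes": len(self.table.complex_ids),
            "n_clusters": len(self.table.cluster_ids),
        }

    def summary(self) -> str:
        d = self.as_dict()
        lines = [
            f"reference complexes : {d['n_complexes']}",
            f"predicted clusters  : {d['n_clusters']}",
            f"sensitivity         : {self.sensitivity:.4f}",
            f"PPV                 : {self.ppv:.4f}",
            f"accuracy            : {self.accuracy:.4f}",
            f"separation          : {self.separation:.4f}",
        ]
        return "\n".join(lines)


def contingency(catalog: ComplexCatalog, clusters: ClusterSet) -> ContingencyTable:
    """Exact complex-by-cluster intersection counts.

    Proteins of a complex absent from every cluster still count in N_i, so
    sensitivity reflects genuinely missed proteins.
    """
    if len(catalog) == 0:
        raise ValueError("empty reference catalog")
    if len(clusters) == 0:
        raise ValueError("empty cluster set")
    complex_ids = list(catalog.complexes)
    cluster_sets = clusters.member_sets()
    t = np.zeros((len(complex_ids), len(cluster_sets)), dtype=int)
    for i, name in enumerate(complex_ids):
        cx = catalog.complexes[name]
        for j, cl in enumerate(cluster_sets):
            t[i, j] = len(cx & cl)
    n = np.array([len(catalog.complexes[name]) for name in complex_ids])
    return ContingencyTable(t, n, complex_ids, [f"c{j}" for j in range(len(cluster_sets))])


def sensitivity(ct: ContingencyTable) -> float:
    return float(ct.t.max(axis=1).sum()) / float(ct.n.sum())


def ppv(ct: ContingencyTable) -> float:
    denom = float(ct.t.sum())
    if denom == 0:
        logger.warning("all contingency marginals are zero; PPV defined as 0")
        return 0.0
    return float(ct.t.max(axis=0).sum()) / denom


def accuracy(sn: float, ppv_value: float) -> float:
    """Geometric mean of sensitivity and PPV."""
    if not (0.0 <= sn <= 1.0 and 0.0 <= ppv_value <= 1.0):
        raise ValueError("sensitivity and PPV must lie in [0, 1]")
    return math.sqrt(sn * ppv_value)


def separation(ct: ContingencyTable) -> float:
    t = ct.t.astype(float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(t > 0, (t / np.where(row > 0, row, 1.0)) * (t / np.where(col > 0, col, 1.0)), 0.0)
    sep_complex = float(f.sum(axis=1).mean()) if f.shape[0] else 0.0
    sep_cluster = float(f.sum(axis=0).mean()) if f.shape[1] else 0.0
    return math.sqrt(sep_complex * sep_cluster)


def evaluate(
    catalog: ComplexCatalog, clusters: ClusterSet, join_overlap: float = 0.6
) -> EvaluationReport:
    """Join near-duplicate clusters (overlap coefficient > ``join_overlap``),
    then score the joined prediction against the catalog.

    The joining step mirrors how tree-less comparisons are made fair: many
    very similar small clusters, merged, represent the reference complexes
    better and raise the separation.
    """
    joined = ClusterSet(join_clusters(list(clusters), join_overlap), source=clusters.source)
    ct = contingency(catalog, joined)
    sn = sensitivity(ct)
    pv = ppv(ct)
    return EvaluationReport(sn, pv, accuracy(sn, pv), separation(ct), ct)
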