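"""The 4N near-neighbor-network algorithm.

4N grows one candidate cluster ("near neighbor network") per seed protein:
a set of proteins that all co-occur with the seed above the co-occurrence
threshold, pass the abundance criterion pairwise, and together keep the
set-wise completeness above its threshold.  Networks with identical member
sets are deduplicated and strongly overlapping networks are joined, giving
the final overlapping cluster set.  The whole procedure is deterministic:
candidates are ranked by mean co-occurrence to the current members with
lexicographic tie-breaking.

Thresholds left unset can be resolved automatically to the strictest grid
setting at which no protein is lost (i.e. every protein lands in at least
one cluster of size >= 2); see :func:`auto_thresholds`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from hc4n.data_io import ClusterSet, IPMSMatrix, OCCURRENCE
from hc4n.similarity import (
    PASS_EPS,
    CoOccurrenceMatrix,
    SimilarityThresholds,
    co_occurrence_matrix,
    min_co_occurrence,
    passes,
    passes_abundance,
    set_completeness,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Cluster:
    """A set of >= 2 proteins plus the minimum pairwise co-occurrence of its
    members (the similarity level the cluster lives at)."""

    members: frozenset[str]
    min_co: float
    seed: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least 2 proteins")

    def __len__(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass
class FourNResult:
    """Outcome of one 4N run: final clusters, the pre-join raw networks, the
    thresholds actually used (auto values filled in, returned as user
    feedback) and the proteins that ended up in no cluster."""

    clusters: ClusterSet
    raw_networks: list[Cluster]
    thresholds_used: SimilarityThresholds
    lost_proteins: frozenset[str]


def grow_network(
    c: CoOccurrenceMatrix,
    m: IPMSMatrix,
    seed: str,
    th: SimilarityThresholds,
) -> Cluster | None:
    """Grow the near neighbor network of one seed protein.

    Starting from ``{seed}``, candidates are the proteins whose co-occurrence
    with the seed meets ``t_co``.  A candidate is added when it passes the
    abundance criterion against every current member and the enlarged set
    keeps set-wise completeness >= ``t_comp``; candidates are tried in
    descending order of mean co-occurrence to the current members (ties
    broken lexicographically).  Growth stops when no candidate can be added.
    Returns ``None`` when the seed attracts nobody.
    """
    th.require_complete()
    si = c.index(seed)
    n = len(c.protein_ids)
    row = c.values[si]
    cand = [j for j in range(n) if j != si and passes(row[j], th.t_co)]
    if m.data_kind != OCCURRENCE:
        cand = [j for j in cand if passes_abundance(m, seed, c.protein_ids[j], th.t_ab)]
    members = [si]
    # incremental completeness bookkeeping: pairs meeting t_co / total pairs
    good_pairs = 0
    total_pairs = 0
    remaining = set(cand)
    while remaining:
        # rank all remaining candidates, then take the best feasible one
        ranked = sorted(
            remaining,
            key=lambda j: (-float(np.mean(c.values[j, members])), c.protein_ids[j]),
        )
        added = False
        for j in ranked:
            new_good = int(np.sum(c.values[j, members] >= th.t_co - PASS_EPS))
            if (good_pairs + new_good) < th.t_comp * (total_pairs + len(members)) - PASS_EPS:
                continue
            if m.data_kind != OCCURRENCE and not all(
                passes_abundance(m, c.protein_ids[j], c.protein_ids[k], th.t_ab)
                for k in members
            ):
                continue
            members.append(j)
            good_pairs += new_good
            total_pairs += len(members) - 1
            remaining.discard(j)
            added = True
            break
        if not added:
            break
    if len(members) < 2:
        return None
    ids = frozenset(c.protein_ids[j] for j in members)
    return Cluster(ids, min_co_occurrence(c, ids), seed=seed)


def join_clusters(
    clusters: list[Cluster],
    overlap_threshold: float,
    co: CoOccurrenceMatrix | None = None,
) -> list[Cluster]:
    """Iteratively merge clusters whose overlap coefficient
    ``|A ∩ B| / min(|A|, |B|)`` strictly exceeds ``overlap_threshold``.

    Identical member sets are deduplicated first.  Merging repeats until a
    fixed point, so the operation is idempotent.  The merged cluster's
    minimum co-occurrence is recomputed from ``co`` when given; otherwise the
    minimum of the parts is kept (a stand-in used where no matrix is at hand
    and the value is not consumed, e.g. evaluation).  Result ordering:
    decreasing size, ties by lexicographically smallest member list.
    """
    if not (0.0 < overlap_threshold <= 1.0):
        raise ValueError("overlap_threshold must be in (0, 1]")
    # dedup identical sets, keeping first occurrence
    seen: dict[frozenset[str], Cluster] = {}
    for cl in clusters:
        seen.setdefault(cl.members, cl)
    work = list(seen.values())
    changed = True
    while changed:
        changed = False
        work.sort(key=lambda cl: (-len(cl.members), cl.sorted_members()))
        for a in range(len(work)):
            for b in range(a + 1, len(work)):
                A, B = work[a].members, work[b].members
                ov = len(A & B) / min(len(A), len(B))
                if ov > overlap_threshold + PASS_EPS:
                    union = A | B
                    if co is not None:
                        min_co = min_co_occurrence(co, union)
                    else:
                        min_co = min(work[a].min_co, work[b].min_co)
                    merged = Cluster(union, min_co)
                    rest = [cl for k, cl in enumerate(work) if k not in (a, b)]
                    # the union may coincide with an existing set
                    work = [cl for cl in rest if cl.members != union] + [merged]
                    changed = True
                    break
            if changed:
                break
    work.sort(key=lambda cl: (-len(cl.members), cl.sorted_members()))
    return work


def run_4n(
    m: IPMSMatrix,
    th: SimilarityThresholds,
    join_overlap: float = 0.5,
    _co: CoOccurrenceMatrix | None = None,
) -> FourNResult:
    """One full 4N pass: one network per seed, dedup, join, report.

    ``th`` may leave ``t_co``/``t_comp`` unset, in which case they are
    resolved by :func:`auto_thresholds` first and the resolved values are
    reported back in ``thresholds_used``.
    """
    co = _co if _co is not None else co_occurrence_matrix(m)
    if not th.is_complete:
        th = auto_thresholds(m, th, join_overlap=join_overlap, _co=co)
    raw: list[Cluster] = []
    seen: set[frozenset[str]] = set()
    for seed in m.protein_ids:
        cl = grow_network(co, m, seed, th)
        if cl is None:
            continue
        if cl.members not in seen:
            seen.add(cl.members)
            raw.append(cl)
    joined = join_clusters(raw, join_overlap, co=co)
    covered: set[str] = set()
    for cl in joined:
        covered |= cl.members
    lost = frozenset(set(m.protein_ids) - covered)
    cs = ClusterSet(
        joined,
        source=f"4N t_co={th.t_co} t_comp={th.t_comp} t_ab={th.t_ab} join={join_overlap}",
    )
    return FourNResult(cs, raw, th, lost)


# ---------------------------------------------------------------------------
# automatic threshold selection
# ---------------------------------------------------------------------------

def _grid(grid_step: float) -> list[float]:
    """Descending threshold grid 1.0, 1.0 - step, ..., step."""
    n = int(round(1.0 / grid_step))
    return [round(k * grid_step, 10) for k in range(n, 0, -1)]


def _lost_at(
    m: IPMSMatrix, co: CoOccurrenceMatrix, t_co: float, t_comp: float, t_ab: float, join_overlap: float
) -> frozenset[str]:
    th = SimilarityThresholds(t_co=t_co, t_comp=t_comp, t_ab=t_ab)
    res = run_4n(m, th, join_overlap=join_overlap, _co=co)
    return res.lost_proteins


def auto_thresholds(
    m: IPMSMatrix,
    fixed: SimilarityThresholds | None = None,
    grid_step: float = 0.01,
    join_overlap: float = 0.5,
    _co: CoOccurrenceMatrix | None = None,
) -> SimilarityThresholds:
    """Strictest thresholds (on a descending grid) at which no protein is lost.

    "Lost" means assigned to no cluster of size >= 2.  Unset fields of
    ``fixed`` are searched; ``t_ab`` is always taken from ``fixed`` (default
    40).  When both ``t_co`` and ``t_comp`` are free the pair is maximized
    lexicographically, ``t_co`` first: for each grid value of ``t_co`` in
    descending order, the largest ``t_comp`` with zero lost proteins wins.
    The returned setting keeps every protein; the next stricter grid step in
    the search order loses at least one.
    """
    fixed = fixed if fixed is not None else SimilarityThresholds()
    co = _co if _co is not None else co_occurrence_matrix(m)
    grid = _grid(grid_step)
    t_ab = fixed.t_ab

    if fixed.is_complete:
        return fixed

    # a protein whose best co-occurrence to any partner is below t_co can
    # never enter any network, so t_co is capped by the min-over-proteins of
    # the best off-diagonal co-occurrence
    off = co.values.copy()
    np.fill_diagonal(off, -1.0)
    if len(m.protein_ids) < 2:
        raise ValueError("auto thresholds need at least 2 proteins")
    minmax = float(off.max(axis=1).min())

    if fixed.t_co is not None:
        # only t_comp free: largest feasible completeness under the user's t_co
        for t_comp in grid:
            if not _lost_at(m, co, fixed.t_co, t_comp, t_ab, join_overlap):
                return SimilarityThresholds(fixed.t_co, t_comp, t_ab)
        never = sorted(_lost_at(m, co, fixed.t_co, grid[-1], t_ab, join_overlap))
        raise ValueError(
            f"no completeness threshold keeps all proteins at t_co={fixed.t_co}; "
            f"never-clusterable proteins: {never}"
        )

    t_co_grid = [t for t in grid if t <= minmax + PASS_EPS]
    if fixed.t_comp is not None:  # only t_co free
        for t_co in t_co_grid:
            if not _lost_at(m, co, t_co, fixed.t_comp, t_ab, join_overlap):
                return SimilarityThresholds(t_co, fixed.t_comp, t_ab)
        raise ValueError(_infeasible_message(m, co, grid[-1], fixed.t_comp, t_ab, join_overlap))

    # both free: lexicographic (t_co, t_comp) maximization
    for t_co in t_co_grid:
        for t_comp in grid:
            if not _lost_at(m, co, t_co, t_comp, t_ab, join_overlap):
                return SimilarityThresholds(t_co, t_comp, t_ab)
    raise ValueError(_infeasible_message(m, co, grid[-1], grid[-1], t_ab, join_overlap))


def _infeasible_message(m, co, t_co, t_comp, t_ab, join_overlap) -> str:
    never = sorted(_lost_at(m, co, t_co, t_comp, t_ab, join_overlap))
    return (
        f"no threshold setting down to the grid floor keeps all proteins; "
        f"never-clusterable proteins: {never}"
    )
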