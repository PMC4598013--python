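"""The hierarchical strategy: recursive 4N on cluster subsets.

One 4N pass clusters the data at a single similarity level.  The
hierarchical run applies 4N to the full matrix first (level 1, manual or
automatic strictness), then, for every resulting cluster, extracts the
sub-matrix of its proteins plus all IPs where any of them occurs and re-runs
4N there with automatically tightened thresholds.  Because the extraction
keeps every occupied IP of every member, pairwise co-occurrence inside a
subset equals its full-data value, and the minimum co-occurrence of nodes is
non-decreasing from root to leaf: deep nodes are tight complex cores,
shallow nodes loose assemblies.

A node whose subset cannot be split further (4N returns only the node's own
member set), whose member count is below ``min_split_size``, or that sits at
``max_depth`` becomes a leaf.  Low-co-occurrence nodes with several
higher-co-occurrence children are "subsets of interest" (SOIs): stacks of
overlapping or interacting complexes worth re-analysing as a standalone
small dataset with manually lowered strictness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hc4n.data_io import ClusterSet, IPMSMatrix, extract_subset
from hc4n.fourn import Cluster, auto_thresholds, join_clusters, run_4n
from hc4n.similarity import (
    CoOccurrenceMatrix,
    SimilarityThresholds,
    co_occurrence_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class HC4NNode:
    """One node of the result tree.

    The root (level 0) holds all proteins with ``min_co`` 0 by convention;
    every other node holds a cluster computed on its parent's sub-matrix.
    ``thresholds_used`` are the thresholds of the 4N run that produced this
    node's children (``None`` on leaves).
    """

    id: str
    cluster: Cluster
    level: int
    children: list["HC4NNode"] = field(default_factory=list)
    thresholds_used: SimilarityThresholds | None = None
    parent: "HC4NNode | None" = field(default=None, repr=False)

    @property
    def members(self) -> frozenset[str]:
        return self.cluster.members

    @property
    def min_co(self) -> float:
        return self.cluster.min_co

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        """Preorder traversal (self first)."""
        yield self
        for ch in self.children:
            yield from ch.walk()

    def find(self, node_id: str) -> "HC4NNode":
        for node in self.walk():
            if node.id == node_id:
                return node
        raise KeyError(f"no node with id {node_id!r}")


@dataclass(frozen=True)
class SOIFlag:
    """Advisory pointer at a subset of interest."""

    node_id: str
    min_co: float
    n_children: int
    depth: int


class _RootCluster(Cluster):
    """Cluster subclass that tolerates a single member, for degenerate roots."""

    def __post_init__(self) -> None:  # pragma: no cover - trivial
        object.__setattr__(self, "members", frozenset(self.members))


def run_hc4n(
    m: IPMSMatrix,
    level1: SimilarityThresholds | str = "auto",
    join_overlap: float = 0.5,
    min_split_size: int = 3,
    max_depth: int = 10,
) -> HC4NNode:
    """Build the full HC4N tree.

    Parameters
    ----------
    level1:
        Thresholds for the first 4N pass, or ``"auto"`` for the strictest
        setting that loses no protein.  Higher levels are always automatic,
        computed per subset.
    join_overlap:
        Overlap coefficient above which networks are joined within each 4N
        pass (default 0.5).
    min_split_size:
        Nodes with fewer members are leaves; below 3 proteins no split into
        two clusters of >= 2 is possible.
    max_depth:
        Safety valve on recursion depth (observed trees are shallow).
    """
    if isinstance(level1, str):
        if level1 != "auto":
            raise ValueError(f"level1 must be thresholds or 'auto', got {level1!r}")
        th1 = SimilarityThresholds()
    else:
        th1 = level1
    co_full = co_occurrence_matrix(m)

    root = HC4NNode(
        id="n0",
        cluster=_RootCluster(frozenset(m.protein_ids), 0.0),
        level=0,
    )
    counter = [1]

    def new_id() -> str:
        k = counter[0]
        counter[0] += 1
        return f"n{k}"

    def attach_children(node: HC4NNode, sub: IPMSMatrix, th: SimilarityThresholds | None) -> None:
        """Run 4N on ``sub`` and attach the resulting clusters under ``node``."""
        try:
            res = run_4n(sub, th if th is not None else SimilarityThresholds(), join_overlap)
        except ValueError as exc:
            logger.warning("node %s left as leaf: %s", node.id, exc)
            return
        node.thresholds_used = res.thresholds_used
        logger.info(
            "node %s (level %d, %d proteins): t_co=%.2f t_comp=%.2f t_ab=%g, %d cluster(s), %d lost",
            node.id, node.level, len(node.members),
            res.thresholds_used.t_co, res.thresholds_used.t_comp, res.thresholds_used.t_ab,
            len(res.clusters), len(res.lost_proteins),
        )
        clusters = [cl for cl in res.clusters if cl.members != node.members]
        for cl in sorted(clusters, key=lambda cl: (-len(cl.members), cl.sorted_members())):
            _assert_subset_invariance(co_full, sub, cl)
            child = HC4NNode(
                id=new_id(),
                cluster=cl,
                level=node.level + 1,
                parent=node,
            )
            node.children.append(child)
        for child in node.children:
            if len(child.members) < min_split_size or child.level >= max_depth:
                continue
            child_sub = extract_subset(m, child.members)
            attach_children(child, child_sub, None)

    attach_children(root, m, th1)
    return root


def _assert_subset_invariance(co_full: CoOccurrenceMatrix, sub: IPMSMatrix, cl: Cluster) -> None:
    """Pairwise co-occurrence inside a subset must equal the full-data value."""
    ids = cl.sorted_members()
    sub_co = co_occurrence_matrix(extract_subset(sub, ids) if len(ids) < sub.n_proteins else sub)
    got = sub_co.submatrix(ids)
    want = co_full.submatrix(ids)
    if not np.allclose(got, want):
        raise AssertionError(
            "subset extraction changed pairwise co-occurrence — extraction rule violated"
        )


def flag_sois(root: HC4NNode, max_min_co: float, min_children: int = 2) -> list[SOIFlag]:
    """Flag subsets of interest: non-root nodes with low minimum
    co-occurrence and at least ``min_children`` children, sorted by
    ascending min_co."""
    flags: list[SOIFlag] = []
    for node in root.walk():
        if node is root:
            continue
        if node.min_co <= max_min_co and len(node.children) >= min_children:
            flags.append(
                SOIFlag(node.id, node.min_co, len(node.children), _depth_below(node))
            )
    flags.sort(key=lambda f: (f.min_co, f.node_id))
    return flags


def _depth_below(node: HC4NNode) -> int:
    if not node.children:
        return 0
    return 1 + max(_depth_below(ch) for ch in node.children)


def flatten(root: HC4NNode, join_overlap: float = 0.6) -> ClusterSet:
    """Strip the tree structure: collect all non-root clusters, drop
    duplicates, and join clusters overlapping by more than ``join_overlap``
    — the evaluation-facing flat prediction."""
    clusters: list[Cluster] = []
    seen: set[frozenset[str]] = set()
    for node in root.walk():
        if node is root:
            continue
        if node.members not in seen:
            seen.add(node.members)
            clusters.append(node.cluster)
    joined = join_clusters(clusters, join_overlap)
    return ClusterSet(joined, source=f"flattened tree, join_overlap={join_overlap}")


# ---------------------------------------------------------------------------
# JSON serialization — the canonical result format
# ---------------------------------------------------------------------------

def tree_to_dict(root: HC4NNode) -> dict:
    nodes = []
    for node in root.walk():
        th = node.thresholds_used
        nodes.append(
            {
                "id": node.id,
                "level": node.level,
                "members": node.cluster.sorted_members(),
                "min_co": round(node.min_co, 10),
                "thresholds_used": None
                if th is None
                else {"t_co": th.t_co, "t_comp": th.t_comp, "t_ab": th.t_ab},
                "children": [ch.id for ch in node.children],
                "parent": node.parent.id if node.parent is not None else None,
            }
        )
    return {"format": "hc4n-tree", "version": 1, "root": root.id, "nodes": nodes}


def write_tree(root: HC4NNode, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(tree_to_dict(root), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_tree(path: str | Path) -> HC4NNode:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != "hc4n-tree":
        raise ValueError(f"{path}: not an hc4n tree file")
    by_id: dict[str, HC4NNode] = {}
    for nd in doc["nodes"]:
        th = nd["thresholds_used"]
        members = frozenset(nd["members"])
        cluster_cls = _RootCluster if nd["parent"] is None else Cluster
        by_id[nd["id"]] = HC4NNode(
            id=nd["id"],
            cluster=cluster_cls(members, nd["min_co"]),
            level=nd["level"],
            thresholds_used=None if th is None else SimilarityThresholds(**th),
        )
    for nd in doc["nodes"]:
        node = by_id[nd["id"]]
        for cid in nd["children"]:
            child = by_id[cid]
            child.parent = node
            node.children.append(child)
    return by_id[doc["root"]]
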