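"""HC-plot rendering and result-tree export for network viewers.

The HC-plot is a protein-by-protein heatmap in co-occurrence units: cell
(i, j) carries the highest minimum co-occurrence among all tree nodes whose
cluster contains both proteins.  Nodes nest, so each cluster appears as a
square and its tighter sub-clusters as brighter squares inside it; pairs
never clustered together are drawn black.  The root is excluded from the
maximum — it contains everyone by construction and would erase the black
background.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from hc4n.tree import HC4NNode

#: cell value for "these two proteins are never in the same cluster"
SENTINEL = -1.0


@dataclass
class HCPlotMatrix:
    """Symmetric grid of cluster-level co-occurrence values (or SENTINEL)."""

    protein_order: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.protein_order)
        if self.values.shape != (n, n):
            raise ValueError("HC-plot grid shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("HC-plot grid must be symmetric")


def _dfs_order(root: HC4NNode) -> list[str]:
    """Protein order: depth-first, children by decreasing size (ties by
    sorted member list), each protein emitted at first encounter; proteins
    in no non-root node appended last in identifier order."""
    order: list[str] = []
    seen: set[str] = set()

    def visit(node: HC4NNode) -> None:
        if node.parent is not None:
            for p in node.cluster.sorted_members():
                if p not in seen:
                    seen.add(p)
                    order.append(p)
        for ch in sorted(node.children, key=lambda c: (-len(c.members), c.cluster.sorted_members())):
            visit(ch)

    for ch in sorted(root.children, key=lambda c: (-len(c.members), c.cluster.sorted_members())):
        visit(ch)
    rest = sorted(set(root.members) - seen)
    return order + rest


def hcplot_matrix(root: HC4NNode) -> HCPlotMatrix:
    """Build the HC-plot grid from a result tree."""
    order = _dfs_order(root)
    idx = {p: k for k, p in enumerate(order)}
    n = len(order)
    values = np.full((n, n), SENTINEL)
    np.fill_diagonal(values, 1.0)
    for node in root.walk():
        if node.parent is None:
            continue
        ids = [idx[p] for p in node.cluster.sorted_members()]
        block = values[np.ix_(ids, ids)]
        np.maximum(block, node.min_co, out=block)
        values[np.ix_(ids, ids)] = block
    np.fill_diagonal(values, 1.0)
    return HCPlotMatrix(order, values)


def _colormap(name: str):
    import matplotlib.colors as mcolors
    from matplotlib import colormaps

    if name == "blue-to-bright":
        return mcolors.LinearSegmentedColormap.from_list(
            "blue-to-bright",
            ["#080830", "#102a8c", "#1e62d0", "#2fa0e8", "#7fd4f0", "#e8fca0"],
        )
    return colormaps[name]


def render_hcplot(
    hm: HCPlotMatrix,
    path: str | Path,
    colormap: str = "blue-to-bright",
    label_limit: int = 100,
) -> None:
    """Render the HC-plot to PNG/SVG (by file extension) and write the
    numeric grid as a sibling ``.tsv`` (sentinel kept as -1) for exact
    inspection and testing.  Protein labels are drawn only for matrices of
    at most ``label_limit`` proteins."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    write_hcplot_tsv(hm, path.with_suffix(path.suffix + ".tsv"))

    n = len(hm.protein_order)
    masked = np.ma.masked_where(hm.values == SENTINEL, hm.values)
    cmap = _colormap(colormap)
    cmap = cmap.copy()
    cmap.set_bad(color="black")
    fig, ax = plt.subplots(figsize=(max(4.0, n * 0.12 + 2), max(4.0, n * 0.12 + 2)))
    im = ax.imshow(masked, cmap=cmap, vmin=0.0, vmax=1.0, interpolation="nearest")
    if n <= label_limit:
        ax.set_xticks(range(n), hm.protein_order, rotation=90, fontsize=6)
        ax.set_yticks(range(n), hm.protein_order, fontsize=6)
    else:
        ax.set_xticks([])
        ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="cluster co-occurrence")
    ax.set_title("HC-plot")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_hcplot_tsv(hm: HCPlotMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t" + "\t".join(hm.protein_order) + "\n")
        for p, row in zip(hm.protein_order, hm.values):
            fh.write(p + "\t" + "\t".join(format(v, ".6f") for v in row) + "\n")


def read_hcplot_tsv(path: str | Path) -> HCPlotMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in fh:
            rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
    return HCPlotMatrix(header, np.array(rows))


def export_tree(root: HC4NNode, path: str | Path, format: str = "graphml") -> list[Path]:
    """Export the result tree for network viewers.

    ``graphml``: one GraphML file, one graph node per tree node with
    attributes members (semicolon-joined), n_members, level and min_co (for
    node colouring), one edge per parent-child link.  ``sif``: a SIF edge
    file plus a sibling node-attribute TSV.  Returns the written paths.
    """
    import networkx as nx

    path = Path(path)
    g = nx.DiGraph()
    for node in root.walk():
        g.add_node(
            node.id,
            members=";".join(node.cluster.sorted_members()),
            n_members=len(node.members),
            level=node.level,
            min_co=float(node.min_co),
        )
        for ch in node.children:
            g.add_edge(node.id, ch.id, interaction="contains")
    if format == "graphml":
        nx.write_graphml(g, path)
        return [path]
    if format == "sif":
        attr_path = path.with_suffix(".attrs.tsv")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for u, v in g.edges():
                fh.write(f"{u}\tcontains\t{v}\n")
            for node in g.nodes():
                if g.degree(node) == 0:
                    fh.write(f"{node}\n")
        with open(attr_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("id\tlevel\tmin_co\tn_members\tmembers\n")
            for nid, data in g.nodes(data=True):
                fh.write(
                    f"{nid}\t{data['level']}\t{data['min_co']:.6f}\t{data['n_members']}\t{data['members']}\n"
                )
        return [path, attr_path]
    raise ValueError(f"unknown export format {format!r} (use 'graphml' or 'sif')")
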