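"""Readers, writers and containers for IP/MS matrices, complex catalogs and
cluster sets.

File dialects
-------------
- Matrix: delimited text (tab preferred, comma accepted), header row of IP
  identifiers, first column of protein identifiers.
- Complex catalog: one complex per line, first token the complex name, the
  remaining whitespace/tab-separated tokens its member proteins (the common
  layout for complex-prediction benchmarking references such as cyc2008).
- Cluster set: one cluster per line: id, minimum co-occurrence, then members,
  tab-separated.

All writers emit UTF-8 with LF line endings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OCCURRENCE = "occurrence"
ABUNDANCE = "abundance"


@dataclass
class IPMSMatrix:
    """A protein-by-IP matrix of occurrences (0/1) or non-negative abundances.

    Rows are proteins, columns are IP experiments.  A protein *occurs* in an
    IP when its value there is strictly positive.  Invariants (enforced by
    :meth:`validate`): unique identifiers, non-negative finite values, every
    protein occurs in at least one IP and every IP contains at least one
    protein, and for occurrence data all values are 0 or 1.
    """

    protein_ids: list[str]
    ip_ids: list[str]
    values: np.ndarray
    data_kind: str = OCCURRENCE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.data_kind not in (OCCURRENCE, ABUNDANCE):
            raise ValueError(f"unknown data_kind {self.data_kind!r}")
        if self.values.shape != (len(self.protein_ids), len(self.ip_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.ip_ids)} IPs"
            )
        for name, ids in (("protein", self.protein_ids), ("IP", self.ip_ids)):
            seen: set[str] = set()
            for x in ids:
                if x in seen:
                    raise ValueError(f"duplicate {name} identifier: {x!r}")
                seen.add(x)
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at protein {self.protein_ids[bad[0]]!r}, "
                f"IP {self.ip_ids[bad[1]]!r}"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at protein {self.protein_ids[bad[0]]!r}, "
                f"IP {self.ip_ids[bad[1]]!r}"
            )
        if self.data_kind == OCCURRENCE and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise ValueError("occurrence matrix contains values other than 0 and 1")
        occ = self.values > 0
        if self.protein_ids and not occ.any(axis=1).all():
            i = int(np.flatnonzero(~occ.any(axis=1))[0])
            raise ValueError(f"protein {self.protein_ids[i]!r} occurs in no IP")
        if self.ip_ids and not occ.any(axis=0).all():
            j = int(np.flatnonzero(~occ.any(axis=0))[0])
            raise ValueError(f"IP {self.ip_ids[j]!r} contains no protein")

    # -- convenience --------------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_ips(self) -> int:
        return len(self.ip_ids)

    @property
    def occupancy(self) -> np.ndarray:
        """Boolean protein-by-IP occurrence mask (value > 0)."""
        return self.values > 0

    def protein_index(self, protein: str) -> int:
        try:
            return self.protein_ids.index(protein)
        except ValueError:
            raise KeyError(f"unknown protein identifier: {protein!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.ip_ids)


@dataclass
class ComplexCatalog:
    """A reference catalog of named protein complexes.

    Complexes may overlap (share proteins); member sets are non-empty and
    complex names unique (guaranteed by the dict mapping).
    """

    complexes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.complexes.items():
            if not members:
                raise ValueError(f"complex {name!r} has no members")
            self.complexes[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.complexes)

    @property
    def all_proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.complexes.values():
            out |= members
        return frozenset(out)


@dataclass
class ClusterSet:
    """An ordered collection of (possibly overlapping) clusters.

    ``source`` is a free-form provenance note (e.g. the thresholds used).
    """

    clusters: list  # list[Cluster]; untyped to avoid a circular import
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        for cl in self.clusters:
            if len(cl.members) < 2:
                raise ValueError(f"cluster {sorted(cl.members)} has fewer than 2 members")
            key = frozenset(cl.members)
            if key in seen:
                raise ValueError(f"duplicate cluster member set {sorted(key)}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def member_sets(self) -> list[frozenset[str]]:
        return [frozenset(cl.members) for cl in self.clusters]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_delimiter(first_line: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return "\t"


def read_matrix(
    path: str | Path,
    data_kind: str = OCCURRENCE,
    binarize_threshold: float | None = None,
    delimiter: str | None = None,
) -> IPMSMatrix:
    """Read a protein-by-IP matrix from delimited text.

    Parameters
    ----------
    path:
        Delimited text file: header row of IP identifiers, leading column of
        protein identifiers; tab or comma delimited (auto-detected unless
        ``delimiter`` is given).
    data_kind:
        ``"occurrence"`` or ``"abundance"``.  For occurrence data any real
        value strictly above ``binarize_threshold`` (default 0) becomes 1.
    binarize_threshold:
        Cut-off for binarization; only meaningful for occurrence data.

    Empty rows/columns (no positive value) are dropped with a logged warning.
    Duplicate identifiers, negative values, NaN and empty files are hard
    errors.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"empty matrix file: {path}")
    sep = _sniff_delimiter(text.splitlines()[0], delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    if df.empty and df.columns.empty:
        raise ValueError(f"empty matrix file: {path}")
    protein_ids = [str(x) for x in df.index]
    ip_ids = [str(x) for x in df.columns]
    for name, ids in (("protein", protein_ids), ("IP", ip_ids)):
        dupes = pd.Series(ids)[pd.Series(ids).duplicated()]
        if not dupes.empty:
            raise ValueError(f"duplicate {name} identifier: {dupes.iloc[0]!r}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise ValueError(
            f"NaN value at protein {protein_ids[i]!r}, IP {ip_ids[j]!r}; "
            "missing values must be resolved before loading"
        )
    if np.any(values < 0):
        i, j = map(int, np.argwhere(values < 0)[0])
        raise ValueError(
            f"negative value at protein {protein_ids[i]!r}, IP {ip_ids[j]!r}"
        )
    if data_kind == OCCURRENCE:
        thr = 0.0 if binarize_threshold is None else float(binarize_threshold)
        values = (values > thr).astype(float)

    # warn-and-drop empty rows/columns so real exports with all-zero padding
    # load cleanly
    occ = values > 0
    keep_rows = occ.any(axis=1)
    if not keep_rows.all():
        dropped = [p for p, k in zip(protein_ids, keep_rows) if not k]
        logger.warning("dropping %d empty protein row(s): %s", len(dropped), dropped)
        values = values[keep_rows]
        protein_ids = [p for p, k in zip(protein_ids, keep_rows) if k]
    occ = values > 0
    keep_cols = occ.any(axis=0) if len(protein_ids) else np.zeros(len(ip_ids), bool)
    if not keep_cols.all():
        dropped = [q for q, k in zip(ip_ids, keep_cols) if not k]
        logger.warning("dropping %d empty IP column(s): %s", len(dropped), dropped)
        values = values[:, keep_cols]
        ip_ids = [q for q, k in zip(ip_ids, keep_cols) if k]
    if not protein_ids or not ip_ids:
        raise ValueError(f"matrix file {path} holds no positive value")
    return IPMSMatrix(protein_ids, ip_ids, values, data_kind)


def write_matrix(m: IPMSMatrix, path: str | Path) -> None:
    """Write a matrix in the dialect :func:`read_matrix` accepts (TSV)."""
    df = m.to_frame()
    if m.data_kind == OCCURRENCE:
        df = df.astype(int)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", lineterminator="\n")


def read_catalog(path: str | Path) -> ComplexCatalog:
    """Read a reference complex catalog (one named complex per line)."""
    complexes: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            name, *members = tokens
            if not members:
                raise ValueError(f"{path}:{lineno}: complex {name!r} lists no members")
            if len(set(members)) < len(members):
                logger.warning("%s:%d: duplicate members within complex %s deduplicated", path, lineno, name)
            if name in complexes:
                raise ValueError(f"{path}:{lineno}: duplicate complex name {name!r}")
            complexes[name] = frozenset(members)
    return ComplexCatalog(complexes)


def write_catalog(catalog: ComplexCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in catalog.complexes:
            fh.write(name + "\t" + "\t".join(sorted(catalog.complexes[name])) + "\n")


def extract_subset(m: IPMSMatrix, proteins: Iterable[str]) -> IPMSMatrix:
    """Restrict a matrix to the given proteins and the IPs where they occur.

    The sub-matrix keeps exactly the IP columns in which at least one of the
    requested proteins occurs, in parent order.  Because every such IP is
    kept, each retained protein keeps its full occupied-IP set, so pairwise
    co-occurrence between retained proteins is unchanged — the property the
    hierarchical recursion relies on.
    """
    wanted = set(proteins)
    if len(wanted) < 2:
        raise ValueError("a subset needs at least 2 proteins")
    unknown = wanted - set(m.protein_ids)
    if unknown:
        raise KeyError(f"unknown protein identifier: {sorted(unknown)[0]!r}")
    row_idx = [i for i, p in enumerate(m.protein_ids) if p in wanted]
    sub = m.values[row_idx, :]
    col_keep = (sub > 0).any(axis=0)
    col_idx = np.flatnonzero(col_keep)
    return IPMSMatrix(
        [m.protein_ids[i] for i in row_idx],
        [m.ip_ids[j] for j in col_idx],
        sub[:, col_idx],
        m.data_kind,
    )


def write_clusters(cs: ClusterSet, path: str | Path) -> None:
    """One cluster per line: id, min co-occurrence (6 decimals), members."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for k, cl in enumerate(cs.clusters):
            fields = [f"c{k}", f"{cl.min_co:.6f}", *sorted(cl.members)]
            fh.write("\t".join(fields) + "\n")


def read_clusters(path: str | Path) -> ClusterSet:
    from hc4n.fourn import Cluster

    clusters: list[Cluster] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.rstrip("\n").split("\t")
            if len(tokens) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected id, min_co and >= 2 members, "
                    f"got {len(tokens)} field(s)"
                )
            try:
                min_co = float(tokens[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad co-occurrence value {tokens[1]!r}") from None
            clusters.append(Cluster(frozenset(tokens[2:]), min_co))
    return ClusterSet(clusters, source=str(path))
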