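"""Containers and strict I/O for count tables, networks and trees.

Conventions fixed here and relied on everywhere else:

* Count tables are TSV with samples in rows. The first column is the sample
  id, the second column is the group label (named ``group``), and every
  remaining column is a taxon. Counts are non-negative integers.
* Networks are undirected, weighted by the signed correlation ``r``; the
  edge CSV interchange format has columns ``source,target,r,p_adj``, rows
  sorted lexicographically by (source, target) and ``r`` printed with six
  decimals, so identical networks produce byte-identical files.
* Trees are Newick; absent branch lengths default to 0.

Readers reject rather than coerce: duplicate ids, negative or fractional
counts, missing group labels and malformed Newick all raise ``ValueError``
naming the offending element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import skbio

__all__ = [
    "CountTable",
    "CooccurrenceNetwork",
    "read_count_table",
    "write_count_table",
    "read_newick",
    "write_newick",
    "read_taxonomy",
    "write_network",
    "read_network",
]

GROUP_COLUMN = "group"

NETWORK_DIALECTS = ("graphml", "gexf", "edge_list_csv")


@dataclass
class CountTable:
    """Sample x taxon non-negative integer abundance matrix with group labels.

    ``counts`` is a DataFrame indexed by sample id with taxon-id columns;
    ``group`` maps every sample id to its group label (e.g. season).
    """

    counts: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate taxon id: {dup!r}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            frac = values != np.floor(values)
            if frac.any():
                i, j = np.argwhere(frac)[0]
                raise ValueError(
                    "non-integer count at sample "
                    f"{self.counts.index[i]!r}, taxon {self.counts.columns[j]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                "negative count at sample "
                f"{self.counts.index[i]!r}, taxon {self.counts.columns[j]!r}"
            )
        missing = self.counts.index.difference(self.group.index)
        if len(missing):
            raise ValueError(f"sample {missing[0]!r} has no group label")
        self.group = self.group.reindex(self.counts.index)
        if self.group.isna().any():
            bad = self.group.index[self.group.isna()][0]
            raise ValueError(f"sample {bad!r} has no group label")

    # -- convenience views ------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=np.int64)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(g, None)
        return list(seen)

    def subset_group(self, label: str, drop_empty_taxa: bool = True) -> "CountTable":
        """Restrict to one group's samples, optionally dropping undetected taxa."""
        mask = self.group == label
        if not mask.any():
            raise ValueError(f"unknown group label {label!r}")
        counts = self.counts.loc[mask]
        if drop_empty_taxa:
            counts = counts.loc[:, counts.sum(axis=0) > 0]
        return CountTable(counts.copy(), self.group[mask].copy())

    def drop_taxon(self, taxon_id: str) -> "CountTable":
        if taxon_id not in self.counts.columns:
            raise KeyError(f"taxon {taxon_id!r} not present in table")
        return CountTable(self.counts.drop(columns=[taxon_id]), self.group.copy())

    def detected_taxa(self) -> list[str]:
        totals = self.counts.sum(axis=0)
        return list(totals.index[totals > 0])


@dataclass
class CooccurrenceNetwork:
    """Undirected signed network of significant taxon-taxon correlations.

    Edges carry ``weight`` (the correlation r), ``sign`` ("+"/"-") and
    ``p_adj``. ``threshold_r`` and ``alpha`` record the edge-calling
    criterion |r| >= threshold_r and p_adj < alpha.
    """

    graph: nx.Graph
    threshold_r: float = 0.75
    alpha: float = 0.05
    name: str = ""

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_tuples(self) -> list[tuple[str, str, float, float]]:
        """Edges as (source, target, r, p_adj), canonically ordered."""
        rows = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((str(u), str(v)))
            rows.append((a, b, float(d.get("weight", 1.0)), float(d.get("p_adj", 0.0))))
        rows.sort(key=lambda t: (t[0], t[1]))
        return rows


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table (sample id, group, then taxon columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2 or df.columns[1] != GROUP_COLUMN:
        raise ValueError(
            f"expected second column to be {GROUP_COLUMN!r}, got {list(df.columns[:2])}"
        )
    sample_col = df.columns[0]
    if df[sample_col].isna().any() or df.isna().any().any():
        raise ValueError("ragged or missing entries in count table")
    samples = df[sample_col].tolist()
    group = pd.Series(df[GROUP_COLUMN].tolist(), index=samples, name=GROUP_COLUMN)
    taxa = list(df.columns[2:])
    counts = pd.DataFrame(index=samples, columns=taxa, dtype=object)
    for col in taxa:
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            row = df[sample_col][parsed.isna()].iloc[0]
            raise ValueError(f"non-numeric count at sample {row!r}, taxon {col!r}")
        counts[col] = parsed.to_numpy()
    counts.index = pd.Index(samples, name=sample_col)
    counts = counts.astype(float)
    if not np.allclose(counts.to_numpy() % 1, 0):
        bad = np.argwhere(counts.to_numpy() % 1 != 0)[0]
        raise ValueError(
            f"non-integer count at sample {samples[bad[0]]!r}, taxon {taxa[bad[1]]!r}"
        )
    return CountTable(counts.astype(np.int64), group)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.insert(0, GROUP_COLUMN, table.group)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def read_taxonomy(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column TSV mapping taxon id -> semicolon-separated ranks."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("taxonomy file needs taxon id and lineage columns")
    out: dict[str, list[str]] = {}
    for taxon, lineage in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if taxon in out:
            raise ValueError(f"duplicate taxon id in taxonomy: {taxon!r}")
        out[taxon] = [r.strip() for r in str(lineage).split(";")]
    return out


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_newick(path_or_handle) -> skbio.TreeNode:
    """Read a rooted Newick tree; absent branch lengths default to 0."""
    try:
        tree = skbio.TreeNode.read(
            str(path_or_handle) if isinstance(path_or_handle, Path) else path_or_handle,
            format="newick",
        )
    except Exception as exc:  # skbio raises its own parse errors
        raise ValueError(f"Newick parse error: {exc}") from exc
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        dup = next(n for n in tips if tips.count(n) > 1)
        raise ValueError(f"duplicate tip label: {dup!r}")
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
        if not math.isfinite(node.length) or node.length < 0:
            raise ValueError(f"invalid branch length on node {node.name!r}")
    return tree


def write_newick(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _annotated_graph(net: CooccurrenceNetwork) -> nx.Graph:
    g = nx.Graph()
    for node, data in net.graph.nodes(data=True):
        attrs = {"taxon": str(node)}
        for key in ("module", "eigenvector_centrality"):
            if key in data:
                attrs[key] = data[key]
        g.add_node(str(node), **attrs)
    for u, v, d in net.graph.edges(data=True):
        r = float(d.get("weight", 1.0))
        g.add_edge(
            str(u),
            str(v),
            weight=r,
            sign=d.get("sign", "+" if r >= 0 else "-"),
            p_adj=float(d.get("p_adj", 0.0)),
        )
    return g


def write_network(net: CooccurrenceNetwork, path: str | Path, dialect: str = "graphml") -> None:
    """Write a network as GraphML, GEXF or the canonical edge-list CSV."""
    if dialect not in NETWORK_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {NETWORK_DIALECTS}")
    path = Path(path)
    g = _annotated_graph(net)
    if dialect == "graphml":
        nx.write_graphml(g, path)
    elif dialect == "gexf":
        nx.write_gexf(g, path)
    else:
        lines = ["source,target,r,p_adj"]
        for a, b, r, p in net.edge_tuples():
            lines.append(f"{a},{b},{r:.6f},{p:.6g}")
        path.write_text("\n".join(lines) + "\n")


def read_network(path: str | Path, dialect: str = "graphml") -> CooccurrenceNetwork:
    """Read a network written by :func:`write_network` (graphml/gexf only)."""
    if dialect == "graphml":
        g = nx.read_graphml(str(path))
    elif dialect == "gexf":
        g = nx.read_gexf(str(path))
    else:
        raise ValueError("edge_list_csv is write-only interchange; read graphml/gexf")
    return CooccurrenceNetwork(nx.Graph(g))
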