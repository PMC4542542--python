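"""Tree handling, patristic distances and haplotype networks.

Trees are consumed as Newick with branch lengths (typically produced
elsewhere, e.g. by Bayesian inference) and handled as ``skbio.TreeNode``.
Patristic distance — the sum of branch lengths along the unique path
between two tips — is the package's measure of evolutionary relatedness.

Haplotype networks connect lineage sequences by single-substitution steps:
a minimum spanning network (the union of all minimum spanning trees on the
Hamming distance matrix, optionally relaxed by ``epsilon``), with edges of
length d > 1 expanded through d−1 inferred intermediate haplotypes.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .errors import FormatError, InvalidArgumentError
from .seqproc import LineageSet, hamming_matrix


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string; every edge must carry a finite branch length."""
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"invalid Newick: {exc}") from exc
    tips = list(tree.tips())
    if not tips:
        raise FormatError("invalid Newick: no tips")
    labels = [t.name for t in tips]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None or not math.isfinite(node.length):
            where = node.name or "internal node"
            raise FormatError(f"missing or non-finite branch length at {where}")
        if node.length < 0:
            raise FormatError(f"negative branch length at {node.name or 'internal node'}")
    return tree


def read_newick(path) -> TreeNode:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# Patristic distances


def patristic_distances(tree: TreeNode, tips: list[str] | None = None) -> DistanceMatrix:
    """Pairwise path-length (patristic) distances between tips.

    Restricting to a subset of tips gives exactly the corresponding
    sub-matrix of the full matrix.
    """
    all_tips = {t.name for t in tree.tips()}
    if tips is not None:
        unknown = set(tips) - all_tips
        if unknown:
            raise InvalidArgumentError(f"tips not in tree: {sorted(unknown)}")
    full = tree.tip_tip_distances()
    if tips is None:
        return full
    return full.filter(tips)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining on a distance matrix (unrooted tree).

    Negative estimated branch lengths are clamped to zero; the affected
    node names are recorded on the returned tree as ``negative_clamped``.
    On additive input the generating topology and lengths are recovered
    exactly.
    """
    if distances.shape[0] < 3:
        raise InvalidArgumentError("neighbor joining needs at least 3 taxa")
    tree = _skbio_nj(distances, neg_as_zero=False)
    clamped = []
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            clamped.append(node.name or "internal")
            node.length = 0.0
    tree.negative_clamped = clamped
    return tree


# ---------------------------------------------------------------------------
# Haplotype networks


INFERRED_PREFIX = "inferred_"


@dataclass
class HaplotypeNetwork:
    """Graph of haplotypes connected by single-substitution edges.

    Observed lineages carry ``observed=True``; inferred (unsampled)
    intermediates inserted along multi-step edges carry ``observed=False``.
    Node annotations (category proportions or a scalar affinity) are set by
    :func:`annotate_network`.
    """

    graph: nx.Graph
    mst_weight: float
    annotation_mode: str | None = None

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("observed")]

    @property
    def inferred_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d.get("observed")]

    def node_table(self) -> pd.DataFrame:
        rows = []
        for n, d in self.graph.nodes(data=True):
            row = {"id": n, "observed": bool(d.get("observed"))}
            ann = d.get("annotation")
            if isinstance(ann, dict):
                row.update(ann)
            elif ann is not None:
                row["annotation"] = ann
            rows.append(row)
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"from": u, "to": v} for u, v in self.graph.edges()], columns=["from", "to"]
        )

    def write_tsv(self, nodes_path, edges_path) -> None:
        self.node_table().to_csv(nodes_path, sep="\t", index=False)
        self.edge_table().to_csv(edges_path, sep="\t", index=False)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _msn_edges(dm: DistanceMatrix) -> tuple[list[tuple[str, str, float]], float, float]:
    """All edges belonging to at least one minimum spanning tree.

    Kruskal by weight class: an edge (u, v, w) is in some MST iff u and v
    lie in different components of the graph restricted to edges of weight
    < w.  Returns (edges, total MST weight, largest weight used).
    """
    ids = list(dm.ids)
    edges = sorted(
        ((dm[ids[i], ids[j]], ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))),
        key=lambda e: e[0],
    )
    uf = _UnionFind(ids)
    kept: list[tuple[str, str, float]] = []
    mst_weight = 0.0
    max_used = 0.0
    k = 0
    while k < len(edges):
        w = edges[k][0]
        block = []
        while k < len(edges) and edges[k][0] == w:
            block.append(edges[k])
            k += 1
        in_some_mst = [(u, v, w) for w, u, v in block if uf.find(u) != uf.find(v)]
        # count MST weight with a plain Kruskal pass over the same block
        merged = 0
        for u, v, _ in in_some_mst:
            if uf.find(u) != uf.find(v):
                uf.union(u, v)
                merged += 1
        if in_some_mst:
            kept.extend(in_some_mst)
            mst_weight += merged * w
            max_used = max(max_used, w)
    return kept, mst_weight, max_used


def build_haplotype_network(lineages: LineageSet, epsilon: float = 0.0) -> HaplotypeNetwork:
    """Minimum spanning network over lineage sequences.

    Edges of every minimum spanning tree of the Hamming distance matrix are
    retained, plus any edge of length ≤ (largest MST edge length + epsilon).
    Edges longer than one substitution are expanded with inferred
    intermediate haplotype nodes so every edge in the final graph is a
    single substitution step.
    """
    if epsilon < 0:
        raise InvalidArgumentError("epsilon must be >= 0")
    g = nx.Graph()
    for lid in lineages.ids:
        g.add_node(lid, observed=True)
    if len(lineages) == 1:
        return HaplotypeNetwork(g, 0.0)
    dm = hamming_matrix(lineages)
    msn, mst_weight, max_used = _msn_edges(dm)
    extra = [
        (dm[u, v], u, v)
        for i, u in enumerate(lineages.ids)
        for v in lineages.ids[i + 1 :]
        if 0 < dm[u, v] <= max_used + epsilon
    ]
    pairs = {(min(u, v), max(u, v)): w for u, v, w in msn}
    for w, u, v in extra:
        pairs.setdefault((min(u, v), max(u, v)), w)
    counter = 0
    for (u, v), w in sorted(pairs.items()):
        d = int(round(w))
        if d <= 1:
            g.add_edge(u, v, step=1)
            continue
        prev = u
        for _ in range(d - 1):
            counter += 1
            mid = f"{INFERRED_PREFIX}{counter:03d}"
            g.add_node(mid, observed=False)
            g.add_edge(prev, mid, step=1)
            prev = mid
        g.add_edge(prev, v, step=1)
    return HaplotypeNetwork(g, mst_weight)


def annotate_network(
    network: HaplotypeNetwork,
    occurrence: pd.DataFrame,
    sample_table: pd.DataFrame,
    mode: str = "category_proportions",
    category_column: str = "vegetation",
    larix_column: str = "larix_pct",
) -> HaplotypeNetwork:
    """Attach per-node occurrence annotations to observed haplotypes.

    ``category_proportions``: each observed node gets its category-affinity
    vector normalized to sum 1 (the share of its occupancy falling in each
    category).  ``larix_affinity``: each observed node gets the mean Larix
    pollen percentage of the samples it occurs in.  Inferred nodes carry no
    annotation.
    """
    from .affinity import category_affinity, larix_affinity

    observed = network.observed_nodes
    missing = set(observed) - set(occurrence.index)
    if missing:
        raise InvalidArgumentError(
            f"lineages absent from occurrence matrix: {sorted(missing)}"
        )
    if mode == "category_proportions":
        table = category_affinity(
            occurrence.loc[observed], sample_table, category_column, normalize_rows=True
        )
        for lid in observed:
            network.graph.nodes[lid]["annotation"] = table.loc[lid].to_dict()
    elif mode == "larix_affinity":
        la = larix_affinity(occurrence.loc[observed], sample_table, larix_column)
        for lid in observed:
            network.graph.nodes[lid]["annotation"] = (
                float(la[lid]) if lid in la.index else None
            )
    else:
        raise InvalidArgumentError(f"unknown annotation mode {mode!r}")
    network.annotation_mode = mode
    return network
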