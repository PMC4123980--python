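"""Minimum-spanning haplotype networks annotated by country.

The network joins haplotypes by edges weighted with their integer
nucleotide-difference counts; the tree is the deterministic Kruskal MST
(edges considered in (weight, label-pair) order).  Because many equal-
weight spanning trees usually exist, every non-tree edge whose weight
equals the heaviest tree edge on the cycle it closes is reported as an
*alternative* edge — the ties a network-drawing tool might display
instead.  No median (inferred intermediate) haplotypes are added.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .popgen import HaplotypeTable
from .seqio_qc import _encode

__all__ = [
    "MSTNetwork",
    "NetworkNode",
    "haplotype_diff_matrix",
    "minimum_spanning_tree",
    "annotate_network",
]


@dataclass
class NetworkNode:
    hap_id: str
    count: int = 0
    country_counts: dict = field(default_factory=dict)
    country_class: str = "unknown"  # "<country>_only" | "shared" | "unknown"


@dataclass
class MSTNetwork:
    """Spanning tree over haplotypes plus co-minimal alternative edges."""

    nodes: dict  # hap_id -> NetworkNode
    edges: list  # (hap_a, hap_b, weight) in the tree
    alt_edges: list  # equal-weight swaps omitted from the tree

    @property
    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)

    def degree(self, hap_id: str) -> int:
        return sum(1 for a, b, _ in self.edges if hap_id in (a, b))

    def edges_to_tsv(self, path) -> None:
        rows = [
            {"hap_a": a, "hap_b": b, "weight": w, "kind": "tree"}
            for a, b, w in self.edges
        ] + [
            {"hap_a": a, "hap_b": b, "weight": w, "kind": "alt"}
            for a, b, w in self.alt_edges
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")

    def nodes_to_tsv(self, path) -> None:
        rows = [
            {
                "haplotype": n.hap_id,
                "count": n.count,
                "country_class": n.country_class,
                "countries": ";".join(f"{c}:{k}" for c, k in sorted(n.country_counts.items())),
            }
            for n in self.nodes.values()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def haplotype_diff_matrix(table: HaplotypeTable) -> np.ndarray:
    """Integer nucleotide-difference matrix between haplotype sequences."""
    if table.n_haplotypes == 0:
        raise ValueError("empty haplotype table")
    mat = np.vstack([_encode(h.sequence) for h in table.haplotypes])
    n = mat.shape[0]
    diff = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = int(np.count_nonzero(mat[i] != mat[j]))
            diff[i, j] = diff[j, i] = d
    return diff


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_tree(diff_matrix: np.ndarray, labels: Sequence[str] | None = None) -> MSTNetwork:
    """Deterministic Kruskal MST over the haplotype difference matrix.

    Edges are taken in (weight, hap_a, hap_b) order, so the chosen tree is
    reproducible; every non-tree edge that could replace the heaviest tree
    edge on its cycle at equal weight is listed in ``alt_edges``.
    """
    n = diff_matrix.shape[0]
    if n == 0:
        raise ValueError("empty difference matrix")
    if labels is None:
        labels = [f"Hap{i + 1:02d}" for i in range(n)]
    labels = list(labels)
    all_edges = sorted(
        (int(diff_matrix[i, j]), labels[i], labels[j])
        for i in range(n)
        for j in range(i + 1, n)
    )
    uf = _UnionFind(labels)
    tree, rest = [], []
    for w, a, b in all_edges:
        if uf.union(a, b):
            tree.append((a, b, w))
        else:
            rest.append((a, b, w))
    adj: dict = {lab: [] for lab in labels}
    for a, b, w in tree:
        adj[a].append((b, w))
        adj[b].append((a, w))
    alt = [
        (a, b, w) for a, b, w in rest if w == _max_edge_on_path(adj, a, b)
    ]
    nodes = {lab: NetworkNode(lab) for lab in labels}
    return MSTNetwork(nodes=nodes, edges=tree, alt_edges=alt)


def _max_edge_on_path(adj: Mapping, src: str, dst: str) -> int:
    """Heaviest edge weight on the unique tree path src -> dst (BFS)."""
    best = {src: 0}
    queue = deque([src])
    while queue:
        u = queue.popleft()
        if u == dst:
            return best[u]
        for v, w in adj[u]:
            if v not in best:
                best[v] = max(best[u], w)
                queue.append(v)
    raise ValueError(f"nodes {src} and {dst} are not connected in the tree")


def annotate_network(mst: MSTNetwork, table: HaplotypeTable) -> MSTNetwork:
    """Tag every node with its frequency and country composition.

    A haplotype seen in exactly one country is ``<country>_only``; in
    several, ``shared``; with no country metadata at all, ``unknown``.
    """
    by_id = {h.id: h for h in table.haplotypes}
    for hap_id, node in mst.nodes.items():
        h = by_id.get(hap_id)
        if h is None:
            continue
        node.count = h.count
        node.country_counts = dict(h.country_counts)
        known = sorted(c for c in h.country_counts if c != "unknown")
        if not known:
            node.country_class = "unknown"
        elif len(known) == 1:
            node.country_class = f"{known[0]}_only"
        else:
            node.country_class = "shared"
    return mst
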