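"""Parsimony trees with bootstrap support, neighbour joining, Newick I/O.

Tree lengths are counted with the Fitch algorithm (unordered, equally
weighted characters; gaps and ambiguity codes act as partial wildcards via
IUPAC state sets, so missing data never add changes).  The most
parsimonious tree is found exhaustively for small taxon sets (every
unrooted binary topology is scored) and by random-addition starting trees
plus nearest-neighbour-interchange hill climbing otherwise.  Support
values come from column bootstrap: the percentage of replicate best trees
containing each bipartition of the reference tree.

Neighbour joining is provided as a light distance-tree fallback (backed by
scikit-bio's implementation, with negative branch lengths clamped to zero).
"""

from __future__ import annotations

import io
import warnings
from typing import Mapping, Sequence

import numpy as np

from .distance import DistanceMatrix
from .seqio_qc import AlignmentMatrix

__all__ = [
    "PhyloTree",
    "fitch_length",
    "parsimony_search",
    "bootstrap_support",
    "neighbor_joining",
]

# IUPAC nucleotide -> bitmask over (A=1, C=2, G=4, T=8); unknown/gap = all states
_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7,
    "N": 15, "-": 15,
}


class PhyloTree:
    """Unrooted tree stored as an adjacency map with optional branch data.

    ``adjacency[u][v]`` is the length of edge (u, v) (None when unknown);
    ``labels`` maps leaf node ids to taxon names; ``support`` maps
    non-trivial bipartitions (frozenset of the taxa on the side away from
    the alphabetically first taxon) to percentages in [0, 100].
    """

    def __init__(self, adjacency: dict, labels: dict, support: dict | None = None):
        self.adjacency = {u: dict(nbrs) for u, nbrs in adjacency.items()}
        self.labels = dict(labels)
        self.support = dict(support or {})
        for u, nbrs in self.adjacency.items():
            for v in nbrs:
                if u not in self.adjacency.get(v, {}):
                    raise ValueError("adjacency is not symmetric")
        if len(set(self.labels.values())) != len(self.labels):
            raise ValueError("leaf labels must be unique")

    # -- basic queries ----------------------------------------------------

    def leaves(self) -> list:
        return sorted(self.labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def _leaf_node(self, label: str) -> int:
        for node, lab in self.labels.items():
            if lab == label:
                return node
        raise KeyError(label)

    def _side_labels(self, u: int, v: int) -> frozenset:
        """Labels reachable from u without crossing edge (u, v)."""
        seen = {v, u}
        stack = [u]
        out = []
        while stack:
            x = stack.pop()
            if x in self.labels:
                out.append(self.labels[x])
            for y in self.adjacency[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def bipartitions(self) -> set:
        """Non-trivial splits, each canonicalized to the side not holding
        the alphabetically first taxon."""
        first = min(self.leaves())
        out = set()
        n = self.n_leaves
        for u in self.adjacency:
            for v in self.adjacency[u]:
                if u < v:
                    side = self._side_labels(u, v)
                    if 1 < len(side) < n - 1:
                        out.add(side if first not in side else
                                frozenset(self.leaves()) - side)
        return out

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.adjacency, self.labels, self.support)

    # -- newick -----------------------------------------------------------

    def to_newick(self, outgroup: str | None = None, include_support: bool = False) -> str:
        """Serialize with display rooting at the outgroup edge (scores are
        root-invariant; rooting is presentational only)."""
        if self.n_leaves == 1:
            return f"{self.leaves()[0]};"
        if self.n_leaves == 2:
            a, b = self.leaves()
            na, nb = self._leaf_node(a), self._leaf_node(b)
            length = self.adjacency[na][nb]
            if length is not None:
                return f"({a}:{length:g},{b}:0);"
            return f"({a},{b});"
        anchor = self._leaf_node(outgroup) if outgroup else self._leaf_node(min(self.leaves()))
        root = next(iter(self.adjacency[anchor]))
        has_lengths = all(
            L is not None for nb in self.adjacency.values() for L in nb.values()
        )

        def render(node: int, parent: int) -> str:
            children = sorted(k for k in self.adjacency[node] if k != parent)
            if not children:
                s = self.labels[node]
            else:
                inner = ",".join(render(c, node) for c in children)
                label = ""
                if include_support:
                    side = self._side_labels(node, parent)
                    n = self.n_leaves
                    if 1 < len(side) < n - 1:
                        key = (side if min(self.leaves()) not in side
                               else frozenset(self.leaves()) - side)
                        if key in self.support:
                            label = f"{self.support[key]:.0f}"
                s = f"({inner}){label}"
            if has_lengths and parent is not None:
                s += f":{self.adjacency[node][parent]:g}"
            return s

        children = sorted(k for k in self.adjacency[root])
        inner = ",".join(render(c, root) for c in children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, source: str) -> "PhyloTree":
        """Parse a Newick string (dendropy backend); a degree-2 root from a
        rooted file is suppressed and internal node labels are read as
        support values."""
        import dendropy

        t = dendropy.Tree.get(data=source, schema="newick",
                              suppress_internal_node_taxa=True)
        ids: dict = {}
        adjacency: dict = {}
        labels: dict = {}
        raw_support: dict = {}
        for i, nd in enumerate(t.preorder_node_iter()):
            ids[nd] = i
            adjacency[i] = {}
        for nd in t.preorder_node_iter():
            if nd.parent_node is not None:
                u, v = ids[nd.parent_node], ids[nd]
                length = nd.edge.length
                adjacency[u][v] = length
                adjacency[v][u] = length
                if nd.label is not None and not nd.is_leaf():
                    try:
                        raw_support[(u, v)] = float(nd.label)
                    except ValueError:
                        pass
            if nd.is_leaf():
                labels[ids[nd]] = nd.taxon.label.replace(" ", "_")
        # suppress unlabelled degree-2 nodes (rooted-newick artifacts)
        changed = True
        while changed:
            changed = False
            for node in list(adjacency):
                if node not in labels and len(adjacency[node]) == 2:
                    (a, la), (b, lb) = adjacency[node].items()
                    merged = None if (la is None or lb is None) else la + lb
                    del adjacency[node]
                    adjacency[a].pop(node)
                    adjacency[b].pop(node)
                    adjacency[a][b] = merged
                    adjacency[b][a] = merged
                    changed = True
                    break
        tree = cls(adjacency, labels)
        for (u, v), val in raw_support.items():
            if u in tree.adjacency and v in tree.adjacency.get(u, {}):
                side = tree._side_labels(v, u)
                if 1 < len(side) < tree.n_leaves - 1:
                    key = (side if min(tree.leaves()) not in side
                           else frozenset(tree.leaves()) - side)
                    tree.support[key] = val
        return tree


# ---------------------------------------------------------------------------
# Fitch counting


def _mask_matrix(alignment) -> tuple:
    """(labels, (n, L) uint8 matrix of IUPAC state masks)."""
    if isinstance(alignment, AlignmentMatrix):
        recs = alignment.records
    else:
        recs = list(alignment)
    labels = [r.id for r in recs]
    mat = np.array(
        [[_MASK.get(c, 15) for c in r.seq] for r in recs], dtype=np.uint8
    )
    return labels, mat


def _compress(mat: np.ndarray) -> tuple:
    """Unique column patterns and their multiplicities."""
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return patterns, counts.astype(np.int64)


def _subtree_mask(adj: Mapping, node, parent, leaf_mask, changes) -> np.ndarray:
    children = [c for c in adj[node] if c != parent]
    if not children:
        return leaf_mask[node]
    masks = [_subtree_mask(adj, c, node, leaf_mask, changes) for c in children]
    m = masks[0]
    for other in masks[1:]:
        inter = m & other
        empty = inter == 0
        changes += empty
        m = np.where(empty, m | other, inter)
    return m


def _score_adjacency(adj: Mapping, leaf_mask: Mapping, weights: np.ndarray) -> int:
    """Fitch length of an unrooted tree, rooted on an arbitrary edge."""
    if len(adj) == 1:
        return 0
    u = min(adj)
    v = min(adj[u])
    changes = np.zeros(len(weights), dtype=np.int64)
    mu = _subtree_mask(adj, u, v, leaf_mask, changes)
    mv = _subtree_mask(adj, v, u, leaf_mask, changes)
    changes += (mu & mv) == 0
    return int((changes * weights).sum())


def fitch_length(tree: PhyloTree, alignment) -> int:
    """Parsimony score of a fixed topology (root-invariant).

    Missing and ambiguous symbols are wildcards over their IUPAC state
    sets, so invariant and all-missing columns contribute zero changes.
    """
    labels, mat = _mask_matrix(alignment)
    row = {lab: i for i, lab in enumerate(labels)}
    missing = [lab for lab in tree.leaves() if lab not in row]
    if missing:
        raise ValueError(f"leaves without sequences: {missing[:5]}")
    sub = mat[[row[lab] for lab in tree.leaves()], :]
    patterns, weights = _compress(sub)
    leaf_mask = {}
    for node, lab in tree.labels.items():
        leaf_mask[node] = patterns[tree.leaves().index(lab)]
    adj = {u: set(nbrs) for u, nbrs in tree.adjacency.items()}
    return _score_adjacency(adj, leaf_mask, weights)


# ---------------------------------------------------------------------------
# topology search


def _edge_list(adj: Mapping) -> list:
    return sorted((u, v) for u in adj for v in adj[u] if u < v)


def _insert_leaf(adj: dict, edge: tuple, leaf: int, internal: int) -> dict:
    """New adjacency with ``leaf`` attached in the middle of ``edge``."""
    x, y = edge
    new = {u: set(nbrs) for u, nbrs in adj.items()}
    new[x].discard(y)
    new[y].discard(x)
    new[internal] = {x, y, leaf}
    new[x].add(internal)
    new[y].add(internal)
    new[leaf] = {internal}
    return new


def _all_topologies(n: int):
    """Yield every unrooted binary topology over leaves 0..n-1."""
    if n < 3:
        if n == 1:
            yield {0: set()}
        else:
            yield {0: {1}, 1: {0}}
        return
    center = n
    base = {i: {center} for i in range(3)}
    base[center] = {0, 1, 2}

    def rec(adj, next_leaf, next_internal):
        if next_leaf == n:
            yield adj
            return
        for edge in _edge_list(adj):
            yield from rec(
                _insert_leaf(adj, edge, next_leaf, next_internal),
                next_leaf + 1,
                next_internal + 1,
            )

    yield from rec(base, 3, n + 1)


def _nni_neighbors(adj: Mapping):
    """Both NNI rearrangements of every internal edge (deterministic order)."""
    for u, v in _edge_list(adj):
        if len(adj[u]) != 3 or len(adj[v]) != 3:
            continue
        a, b = sorted(adj[u] - {v})
        c, d = sorted(adj[v] - {u})
        for x, y in ((b, c), (b, d)):
            new = {k: set(nbrs) for k, nbrs in adj.items()}
            new[u].discard(x)
            new[v].discard(y)
            new[u].add(y)
            new[v].add(x)
            new[x].discard(u)
            new[x].add(v)
            new[y].discard(v)
            new[y].add(u)
            yield new


def _adjacency_to_tree(adj: Mapping, leaf_labels: Sequence[str]) -> PhyloTree:
    adjacency = {u: {v: None for v in nbrs} for u, nbrs in adj.items()}
    labels = {i: leaf_labels[i] for i in range(len(leaf_labels))}
    return PhyloTree(adjacency, labels)


def _topology_key(adj: Mapping, leaf_labels: Sequence[str]) -> frozenset:
    return frozenset(_adjacency_to_tree(adj, leaf_labels).bipartitions())


def _greedy_addition(order, leaf_mask, weights, n):
    adj = {order[0]: {n}, order[1]: {n}, order[2]: {n}, n: set(order[:3])}
    next_internal = n + 1
    for leaf in order[3:]:
        best_score, best_adj = None, None
        for edge in _edge_list(adj):
            cand = _insert_leaf(adj, edge, leaf, next_internal)
            s = _score_adjacency(cand, leaf_mask, weights)
            if best_score is None or s < best_score:
                best_score, best_adj = s, cand
        adj = best_adj
        next_internal += 1
    return adj


def _hill_climb(adj, leaf_mask, weights):
    score = _score_adjacency(adj, leaf_mask, weights)
    improved = True
    while improved:
        improved = False
        best_adj, best_score = None, score
        for cand in _nni_neighbors(adj):
            s = _score_adjacency(cand, leaf_mask, weights)
            if s < best_score:
                best_adj, best_score = cand, s
        if best_adj is not None:
            adj, score = best_adj, best_score
            improved = True
    return adj, score


def parsimony_search(
    alignment,
    seed: int = 0,
    n_starts: int = 10,
    exhaustive_max: int = 9,
) -> tuple:
    """Find most-parsimonious topologies.

    Exhaustive enumeration of all unrooted binary topologies when the
    taxon count is <= ``exhaustive_max`` (global optimum guaranteed);
    otherwise random-addition starting trees with NNI hill climbing,
    repeated ``n_starts`` times.  Returns ``(best_trees, score)`` with all
    distinct minimal topologies found.
    """
    labels, mat = _mask_matrix(alignment)
    order_labels = sorted(labels)
    row = {lab: i for i, lab in enumerate(labels)}
    sub = mat[[row[lab] for lab in order_labels], :]
    patterns, weights = _compress(sub)
    n = len(order_labels)
    leaf_mask = {i: patterns[i] for i in range(n)}
    if n < 4:
        if n == 3:
            adj = {0: {3}, 1: {3}, 2: {3}, 3: {0, 1, 2}}
        elif n == 2:
            adj = {0: {1}, 1: {0}}
        else:
            adj = {0: set()}
        score = _score_adjacency(adj, leaf_mask, weights)
        return [_adjacency_to_tree(adj, order_labels)], score

    best_score = None
    best: dict = {}
    if n <= exhaustive_max:
        for adj in _all_topologies(n):
            s = _score_adjacency(adj, leaf_mask, weights)
            if best_score is None or s < best_score:
                best_score = s
                best = {_topology_key(adj, order_labels): adj}
            elif s == best_score:
                best.setdefault(_topology_key(adj, order_labels), adj)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(max(1, n_starts)):
            order = [int(i) for i in rng.permutation(n)]
            adj = _greedy_addition(order, leaf_mask, weights, n)
            adj, s = _hill_climb(adj, leaf_mask, weights)
            if best_score is None or s < best_score:
                best_score = s
                best = {_topology_key(adj, order_labels): adj}
            elif s == best_score:
                best.setdefault(_topology_key(adj, order_labels), adj)
    trees = [
        _adjacency_to_tree(best[k], order_labels)
        for k in sorted(best, key=lambda key: sorted(map(sorted, key)))
    ]
    return trees, int(best_score)


def bootstrap_support(
    alignment,
    reps: int = 500,
    seed: int = 0,
    n_starts: int = 2,
    exhaustive_max: int = 7,
) -> PhyloTree:
    """Column-bootstrap support for the best parsimony tree.

    Resamples alignment columns with replacement ``reps`` times, re-runs
    the parsimony search per replicate, and records the percentage of
    replicate best trees containing each bipartition of the reference
    tree.  Values below 50 are retained (callers decide whether to show
    them).  Deterministic for a fixed seed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    labels, mat = _mask_matrix(alignment)
    trees, _ = parsimony_search(alignment, seed=seed, n_starts=max(2, n_starts),
                                exhaustive_max=exhaustive_max)
    ref = trees[0]
    ref_splits = ref.bipartitions()
    counts = {split: 0 for split in ref_splits}
    rng = np.random.default_rng(seed)
    L = mat.shape[1]
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        sub = mat[:, cols]
        recs = [_FakeRecord(lab, sub[i]) for i, lab in enumerate(labels)]
        rep_trees, _ = parsimony_search(recs, seed=seed, n_starts=n_starts,
                                        exhaustive_max=exhaustive_max)
        rep_splits = rep_trees[0].bipartitions()
        for split in ref_splits:
            if split in rep_splits:
                counts[split] += 1
    ref.support = {split: 100.0 * c / reps for split, c in counts.items()}
    return ref


_MASK_TO_CHAR = {v: k for k, v in _MASK.items() if k != "-"}


class _FakeRecord:
    """Mask-row wrapper usable wherever a SequenceRecord is expected."""

    def __init__(self, rid, mask_row):
        self.id = rid
        self.seq = "".join(_MASK_TO_CHAR[int(m)] for m in mask_row)


# ---------------------------------------------------------------------------
# neighbour joining


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Distance tree via the scikit-bio NJ implementation.

    Undefined (NaN) entries are an error; negative branch lengths are
    clamped to zero with a warning.
    """
    import skbio

    if np.isnan(matrix.d).any() or matrix.undefined_pairs:
        raise ValueError("distance matrix has undefined entries; NJ needs a complete matrix")
    dm = skbio.DistanceMatrix(matrix.d, ids=list(matrix.labels))
    raw = skbio.tree.nj(dm, neg_as_zero=False)
    if any(nd.length is not None and nd.length < 0 for nd in raw.traverse()):
        warnings.warn("negative NJ branch lengths clamped to 0", stacklevel=2)
    clamped = skbio.tree.nj(dm, neg_as_zero=True)
    buf = io.StringIO()
    clamped.write(buf, format="newick")
    return PhyloTree.from_newick(buf.getvalue())
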