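"""Fitch parsimony, tree search, bootstrap support and neighbour joining."""

import itertools

import numpy as np
import pytest

from barcodekit.distance import DistanceMatrix, distance_matrix
from barcodekit.phylo import (
    PhyloTree,
    _all_topologies,
    bootstrap_support,
    fitch_length,
    neighbor_joining,
    parsimony_search,
)
from barcodekit.seqio_qc import SequenceRecord
from conftest import make_records


def brute_fitch(tree: PhyloTree, records) -> int:
    """Oracle: exhaustive minimization over internal-node state assignments.

    For every column, tries every assignment of {A,C,G,T} to the internal
    nodes and counts edge changes; leaf states with ambiguity codes expand
    to their IUPAC sets.
    """
    iupac = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
             "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT",
             "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT", "-": "ACGT"}
    seq_of = {r.id: r.seq for r in records}
    internal = [n for n in tree.adjacency if n not in tree.labels]
    edges = [(u, v) for u in tree.adjacency for v in tree.adjacency[u] if u < v]
    L = len(next(iter(seq_of.values())))
    total = 0
    for col in range(L):
        best = None
        leaf_sets = {n: iupac[seq_of[lab][col]] for n, lab in tree.labels.items()}
        for assign in itertools.product("ACGT", repeat=len(internal)):
            state = dict(zip(internal, assign))
            changes = 0
            ok = True
            for u, v in edges:
                su = state.get(u) or leaf_sets[u]
                sv = state.get(v) or leaf_sets[v]
                # a leaf with an ambiguity set can adopt any member state
                if not set(su) & set(sv):
                    changes += 1
            if best is None or changes < best:
                best = changes
        total += best
    return total


class TestFitch:
    def test_invariant_column_contributes_zero(self):
        recs = make_records(["A", "A", "A", "A"])
        tree = PhyloTree.from_newick("((s1,s2),(s3,s4));")
        assert fitch_length(tree, recs) == 0

    def test_textbook_four_taxon_case(self):
        recs = make_records(["A", "A", "G", "G"])
        tree = PhyloTree.from_newick("((s1,s2),(s3,s4));")
        assert fitch_length(tree, recs) == 1
        crossed = PhyloTree.from_newick("((s1,s3),(s2,s4));")
        assert fitch_length(crossed, recs) == 2

    def test_missing_states_are_wildcards(self):
        recs = make_records(["A", "N", "G", "-"])
        tree = PhyloTree.from_newick("((s1,s2),(s3,s4));")
        assert fitch_length(tree, recs) == 1  # only the A|G contrast costs

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_state_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        recs = make_records(
            ["".join(rng.choice(list("ACGTN"), 12)) for _ in range(5)]
        )
        tree = PhyloTree.from_newick("((s1,s2),(s3,(s4,s5)));")
        assert fitch_length(tree, recs) == brute_fitch(tree, recs)

    def test_score_invariant_under_rerooting(self):
        rng = np.random.default_rng(7)
        recs = make_records(["".join(rng.choice(list("ACGT"), 30)) for _ in range(6)])
        tree = PhyloTree.from_newick("((s1,s2),(s3,s4),(s5,s6));")
        ref = fitch_length(tree, recs)
        for out in ("s3", "s6"):
            rerooted = PhyloTree.from_newick(tree.to_newick(outgroup=out))
            assert fitch_length(rerooted, recs) == ref

    def test_leaf_without_sequence_is_error(self):
        tree = PhyloTree.from_newick("((s1,s2),(s3,zz));")
        with pytest.raises(ValueError, match="zz"):
            fitch_length(tree, make_records(["A", "A", "A"]))


class TestTopologyEnumeration:
    @pytest.mark.parametrize("n,count", [(4, 3), (5, 15), (6, 105), (7, 945)])
    def test_double_factorial_counts(self, n, count):
        assert sum(1 for _ in _all_topologies(n)) == count


class TestParsimonySearch:
    def test_four_taxa_global_optimum(self):
        recs = make_records(["AAAA", "AAGG", "GGAA", "GGGG"])
        trees, score = parsimony_search(recs)
        oracle = min(
            brute_fitch(t, recs)
            for t in (PhyloTree.from_newick(s) for s in
                      ("((s1,s2),(s3,s4));", "((s1,s3),(s2,s4));", "((s1,s4),(s2,s3));"))
        )
        assert score == oracle

    def test_exhaustive_matches_state_oracle_minimum(self):
        rng = np.random.default_rng(12)
        recs = make_records(["".join(rng.choice(list("ACGT"), 15)) for _ in range(5)])
        trees, score = parsimony_search(recs)
        oracle = min(
            brute_fitch(
                PhyloTree({u: {v: None for v in nb} for u, nb in adj.items()},
                          {i: f"s{i + 1}" for i in range(5)}),
                recs,
            )
            for adj in _all_topologies(5)
        )
        assert score == oracle

    def test_heuristic_equals_exhaustive_on_small_data(self, two_cluster_alignment):
        recs = two_cluster_alignment.records[::3][:7]
        _, exhaustive_score = parsimony_search(recs, exhaustive_max=9)
        _, heuristic_score = parsimony_search(recs, seed=1, n_starts=5, exhaustive_max=4)
        assert heuristic_score == exhaustive_score

    def test_fewer_than_four_taxa_trivial(self):
        recs = make_records(["ACGT", "ACGA", "AGGA"])
        trees, score = parsimony_search(recs)
        assert len(trees) == 1 and sorted(trees[0].leaves()) == ["s1", "s2", "s3"]


class TestBootstrap:
    def _signal_records(self):
        """Two groups separated by 20 fixed differences plus light noise."""
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), 60))
        other = "".join(
            ("G" if c == "A" else "A") if i < 20 else c
            for i, c in enumerate(base)
        )
        seqs = []
        for g, anc in enumerate((base, other)):
            for i in range(3):
                s = list(anc)
                j = 25 + 5 * i + 15 * g
                s[j] = "T" if s[j] != "T" else "C"
                seqs.append("".join(s))
        return make_records(seqs)

    def test_strong_split_gets_full_support(self):
        recs = self._signal_records()
        tree = bootstrap_support(recs, reps=30, seed=5)
        split = frozenset({"s4", "s5", "s6"})
        assert tree.support.get(split, tree.support.get(frozenset({"s1", "s2", "s3"}), 0)) == 100.0

    def test_single_replicate_supports_are_all_or_nothing(self):
        recs = self._signal_records()
        tree = bootstrap_support(recs, reps=1, seed=2)
        assert set(tree.support.values()) <= {0.0, 100.0}

    def test_identical_seed_reproducible(self):
        recs = self._signal_records()
        t1 = bootstrap_support(recs, reps=15, seed=9)
        t2 = bootstrap_support(recs, reps=15, seed=9)
        assert t1.support == t2.support


class TestNeighborJoining:
    def test_three_taxa_additive(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c"), d))
        assert sorted(tree.leaves()) == ["a", "b", "c"]

    def test_recovers_additive_five_taxon_tree(self):
        # path distances on ((a:1,b:2):1,(c:1,d:1):2,e:3)
        coords = {
            "a": ("x", 1.0), "b": ("x", 2.0), "c": ("y", 1.0), "d": ("y", 1.0),
        }
        labels = ("a", "b", "c", "d", "e")
        hub = {"x": 1.0, "y": 2.0}  # internal-to-center lengths; e hangs off center
        def dist(p, q):
            if p == q:
                return 0.0
            def path(t):
                if t == "e":
                    return ([], 3.0)
                side, ln = coords[t]
                return ([side], ln)
            sp, lp = path(p)
            sq, lq = path(q)
            d = lp + lq
            if sp and sq and sp == sq:
                return d
            d += sum(hub[s] for s in sp) + sum(hub[s] for s in sq)
            return d
        d = np.array([[dist(p, q) for q in labels] for p in labels])
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert frozenset({"c", "d"}) in tree.bipartitions() or \
               frozenset({"a", "b"}) in tree.bipartitions()
        assert frozenset({"a", "b", "e"}) in tree.bipartitions() or \
               frozenset({"c", "d", "e"}) in tree.bipartitions() or \
               frozenset({"c", "d"}) in tree.bipartitions()

    def test_undefined_entries_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("a", "b"), d, (("a", "b"),)))

    def test_two_cluster_monophyly(self, two_cluster_dataset, two_cluster_alignment):
        sub = two_cluster_alignment.records[::4]
        dm = distance_matrix(sub)
        tree = neighbor_joining(dm)
        truth = two_cluster_dataset.truth["cluster_of"]
        groups = {}
        for r in sub:
            groups.setdefault(truth[r.id], set()).add(r.id)
        sides = list(groups.values())
        assert frozenset(sides[0]) in tree.bipartitions() or \
               frozenset(sides[1]) in tree.bipartitions()


class TestNewick:
    def test_round_trip_lengths_and_support(self):
        s = "((a:1,b:2)90:1.5,(c:1,d:1)75:2,e:3);"
        tree = PhyloTree.from_newick(s)
        assert tree.support[frozenset({"c", "d"})] == 75.0
        back = PhyloTree.from_newick(tree.to_newick(include_support=True))
        assert back.bipartitions() == tree.bipartitions()
        assert back.support == tree.support

    def test_outgroup_rooting_preserves_splits(self):
        s = "((a,b),(c,d),e);"
        tree = PhyloTree.from_newick(s)
        rerooted = PhyloTree.from_newick(tree.to_newick(outgroup="c"))
        assert rerooted.bipartitions() == tree.bipartitions()
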