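"""OTU delimitation, consensus barcodes and the dual-marker translation."""

import itertools

import numpy as np
import pytest

from barcodekit.delimit import (
    ConflictError,
    ReferenceMatch,
    assign_to_reference,
    build_translation_table,
    cluster_summaries,
    consensus_barcode,
    single_linkage_clusters,
)
from barcodekit.distance import DistanceMatrix, distance_matrix
from conftest import make_records


def brute_force_components(labels, d, threshold):
    """Independent oracle: BFS connected components of the <=threshold graph."""
    adj = {a: set() for a in labels}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j and not np.isnan(d[i, j]) and d[i, j] <= threshold:
                adj[a].add(b)
    seen, comps = set(), []
    for a in labels:
        if a in seen:
            continue
        comp, stack = {a}, [a]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in comp:
                    comp.add(y)
                    stack.append(y)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestSingleLinkage:
    def test_all_zero_distances_one_cluster(self):
        dm = distance_matrix(make_records(["ACGT" * 30] * 4))
        part = single_linkage_clusters(dm, 0.02)
        assert part.n_clusters == 1
        assert set(part.assignment.values()) == {"s1"}  # lowest member id

    @pytest.mark.parametrize("threshold", [0.01, 0.03, 0.08, 0.2])
    def test_matches_brute_force_components(self, threshold):
        labels = tuple("abcde")
        d = np.array(
            [
                [0.00, 0.02, 0.09, 0.15, 0.16],
                [0.02, 0.00, 0.07, 0.14, 0.15],
                [0.09, 0.07, 0.00, 0.12, 0.13],
                [0.15, 0.14, 0.12, 0.00, 0.02],
                [0.16, 0.15, 0.13, 0.02, 0.00],
            ]
        )
        dm = DistanceMatrix(labels, d)
        part = single_linkage_clusters(dm, threshold)
        got = {frozenset(m) for m in part.clusters().values()}
        assert got == brute_force_components(labels, d, threshold)

    def test_undefined_pairs_do_not_join(self):
        labels = ("a", "b")
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        dm = DistanceMatrix(labels, d, undefined_pairs=(("a", "b"),))
        assert single_linkage_clusters(dm, 0.5).n_clusters == 2

    def test_threshold_monotone_coarsening(self, two_cluster_alignment):
        dm = distance_matrix(two_cluster_alignment)
        counts = [
            single_linkage_clusters(dm, t).n_clusters
            for t in (0.001, 0.005, 0.01, 0.05, 0.2)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_synthetic_clusters_recovered_with_label_agreement(self, two_cluster_dataset,
                                                               two_cluster_alignment):
        dm = distance_matrix(two_cluster_alignment)
        part = single_linkage_clusters(dm, 0.03)
        truth = two_cluster_dataset.truth["cluster_of"]
        assert part.n_clusters == two_cluster_dataset.config.K
        mapping = {}
        for sid, lab in part.assignment.items():
            mapping.setdefault(lab, set()).add(truth[sid])
        assert all(len(v) == 1 for v in mapping.values())

    def test_cross_cluster_distances_exceed_threshold(self, two_cluster_alignment):
        dm = distance_matrix(two_cluster_alignment)
        part = single_linkage_clusters(dm, 0.03)
        for s in cluster_summaries(dm, part):
            if s.nn_dist is not None:
                assert s.nn_dist > part.threshold


class TestClusterSummaries:
    def test_identical_cluster_max_intra_zero(self):
        dm = distance_matrix(make_records(["ACGT" * 30] * 3 + ["AGGTAGGT" * 15]))
        part = single_linkage_clusters(dm, 0.01)
        summaries = {s.cluster_id: s for s in cluster_summaries(dm, part)}
        assert summaries["s1"].max_intra == 0.0
        assert summaries["s4"].max_intra is None  # singleton

    def test_toy_values_match_enumeration(self):
        a, b = "A" * 100, "G" + "A" * 99
        c, d = "C" * 12 + "A" * 88, "C" * 12 + "G" + "A" * 87
        dm = distance_matrix(make_records([a, b, c, d]))
        part = single_linkage_clusters(dm, 0.05)
        summaries = {s.cluster_id: s for s in cluster_summaries(dm, part)}
        s1 = summaries["s1"]
        assert s1.n == 2
        assert s1.max_intra == pytest.approx(dm.value("s1", "s2"))
        cross = [dm.value(i, j) for i, j in itertools.product(("s1", "s2"), ("s3", "s4"))]
        assert s1.nn_dist == pytest.approx(min(cross))
        assert s1.nn_cluster == "s3"


class TestConsensus:
    def test_identity_on_uniform_input(self):
        assert consensus_barcode(["ACGTN"] * 4) == "ACGTN"

    @pytest.mark.parametrize(
        "column,expected",
        [(("A", "A", "G"), "A"), (("A", "G"), "R"), (("C", "T", "C", "T"), "Y"),
         (("N", "N"), "N"), (("A", "C", "G", "T"), "N"), (("A", "N", "N"), "A")],
    )
    def test_column_rules(self, column, expected):
        seqs = list(column)  # one column, len(column) sequences
        assert consensus_barcode(seqs) == expected

    def test_idempotent(self):
        seqs = ["ACGTAG", "ACGAAG", "TCGTAG"]
        cons = consensus_barcode(seqs)
        assert consensus_barcode([cons]) == cons

    def test_matches_independent_tally(self):
        rng = np.random.default_rng(9)
        seqs = ["".join(rng.choice(list("ACGTN"), 40)) for _ in range(10)]
        cons = consensus_barcode(seqs)
        iupac = {frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
                 frozenset("T"): "T", frozenset("AG"): "R", frozenset("CT"): "Y",
                 frozenset("CG"): "S", frozenset("AT"): "W", frozenset("GT"): "K",
                 frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
                 frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N"}
        for col, got in zip(zip(*seqs), cons):
            tally = {}
            for base in col:
                if base in "ACGT":
                    tally[base] = tally.get(base, 0) + 1
            if not tally:
                assert got == "N"
            else:
                top = max(tally.values())
                winners = frozenset(b for b, c in tally.items() if c == top)
                assert got == (next(iter(winners)) if len(winners) == 1 else iupac[winners])


class TestReferenceAssignment:
    PANEL = {
        "speciesA": "ATGGCTGCTGCTATGGCTGCTGCTATGGCT" * 10,
        "speciesB": "ATGTCGTCATCAATGTCGTCATCAATGTCG" * 10,
    }

    def test_exact_match_assigned_distance_zero(self):
        m = assign_to_reference(self.PANEL["speciesA"], self.PANEL, 0.035)
        assert m.status == "assigned" and m.species == ("speciesA",) and m.dist == 0.0

    def test_one_percent_mutant_assigned(self):
        rng = np.random.default_rng(2)
        seq = np.array(list(self.PANEL["speciesA"]))
        for s in rng.choice(len(seq), size=3, replace=False):
            seq[s] = rng.choice([c for c in "ACGT" if c != seq[s]])
        m = assign_to_reference("".join(seq), self.PANEL, 0.035)
        assert m.status == "assigned" and m.species == ("speciesA",)

    def test_divergent_query_flagged_novel_with_distance(self):
        rng = np.random.default_rng(3)
        seq = np.array(list(self.PANEL["speciesA"]))
        for s in rng.choice(len(seq), size=60, replace=False):
            seq[s] = rng.choice([c for c in "ACGT" if c != seq[s]])
        m = assign_to_reference("".join(seq), self.PANEL, 0.035)
        assert m.status == "novel"
        assert m.dist is not None and m.dist > 0.035

    def test_exact_tie_unresolved_reports_both(self):
        panel = {"x": "A" * 100, "y": "A" * 100}
        m = assign_to_reference("G" + "A" * 99, panel, 0.035)
        assert m.status == "unresolved" and m.species == ("x", "y")

    def test_panel_order_invariance(self):
        q = self.PANEL["speciesB"]
        m1 = assign_to_reference(q, dict(self.PANEL), 0.035)
        m2 = assign_to_reference(q, dict(reversed(list(self.PANEL.items()))), 0.035)
        assert (m1.species, m1.dist, m1.status) == (m2.species, m2.dist, m2.status)


class TestTranslationTable:
    def _partition(self, mapping):
        from barcodekit.delimit import OTUPartition

        return OTUPartition(assignment=mapping, threshold=0.02)

    def test_single_cluster_single_representative(self):
        part = self._partition({"q1": "c1"})
        rows = build_translation_table(
            part, {"c1": ["q1"]},
            {"q1": ReferenceMatch(("speciesX",), 0.004, "assigned")},
        )
        assert [(r.coi5_cluster_id, r.coi3_species, r.status) for r in rows] == [
            ("c1", "speciesX", "assigned")
        ]

    def test_many_to_one_translation(self):
        part = self._partition({"a": "c1", "b": "c2", "c": "c3"})
        match = ReferenceMatch(("sharedSpecies",), 0.01, "assigned")
        rows = build_translation_table(
            part, {"c1": ["a"], "c2": ["b"], "c3": ["c"]},
            {"a": match, "b": match, "c": match},
        )
        assert {r.coi3_species for r in rows} == {"sharedSpecies"}

    def test_conflicting_representatives_raise(self):
        part = self._partition({"a": "c1", "b": "c1"})
        with pytest.raises(ConflictError, match="c1"):
            build_translation_table(
                part, {"c1": ["a", "b"]},
                {"a": ReferenceMatch(("x",), 0.01, "assigned"),
                 "b": ReferenceMatch(("y",), 0.01, "assigned")},
            )

    def test_cluster_without_representatives_unresolved(self):
        part = self._partition({"a": "c1", "b": "c2"})
        rows = build_translation_table(
            part, {"c1": ["a"]},
            {"a": ReferenceMatch(("x",), 0.0, "assigned")},
        )
        status = {r.coi5_cluster_id: r.status for r in rows}
        assert status == {"c1": "assigned", "c2": "unresolved"}

    def test_novel_lineage_propagates(self):
        part = self._partition({"a": "c1"})
        rows = build_translation_table(
            part, {"c1": ["a"]},
            {"a": ReferenceMatch(("nearest",), 0.14, "novel")},
        )
        assert rows[0].coi3_species == "NOVEL" and rows[0].status == "novel"
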