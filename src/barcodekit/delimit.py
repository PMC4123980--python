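"""Threshold OTU delimitation, cluster summaries and dual-marker translation.

Operational taxonomic units are formed by single-linkage clustering at a
K2P threshold: two sequences belong to the same OTU when they are connected
by a chain of pairwise distances each <= threshold.  This is a documented
proxy for BIN-style barcode clustering.  Default thresholds: 0.035 for
COI-3' species delimitation (the 3.5% rule of Dinsdale-style whitefly
taxonomy) and 0.02 for COI-5' barcode OTUs (most intraspecific barcode
distances fall well below 2%).

The translation table connects COI-5' OTUs to COI-3'-defined species by
assigning representative COI-3' sequences to the nearest reference
consensus; queries whose nearest reference exceeds the threshold are
flagged as novel lineages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distance import DistanceMatrix, k2p_distance, NoComparableSitesError
from .seqio_qc import _encode

__all__ = [
    "OTUPartition",
    "ClusterSummary",
    "ReferenceMatch",
    "TranslationRow",
    "ConflictError",
    "COI3_SPECIES_THRESHOLD",
    "COI5_OTU_THRESHOLD",
    "single_linkage_clusters",
    "cluster_summaries",
    "consensus_barcode",
    "assign_to_reference",
    "build_translation_table",
]

COI3_SPECIES_THRESHOLD = 0.035
COI5_OTU_THRESHOLD = 0.02

NOVEL = "NOVEL"


class ConflictError(ValueError):
    """Representatives of one OTU mapped to different reference species."""


@dataclass
class OTUPartition:
    """Assignment of sequence ids to single-linkage clusters."""

    assignment: dict
    threshold: float
    linkage: str = "single"

    def clusters(self) -> dict:
        out: dict = {}
        for sid, lab in self.assignment.items():
            out.setdefault(lab, []).append(sid)
        return {lab: sorted(members) for lab, members in sorted(out.items())}

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            sorted(self.assignment.items()), columns=["id", "cluster"]
        )
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def single_linkage_clusters(matrix: DistanceMatrix, threshold: float) -> OTUPartition:
    """Connected components of the graph joining pairs with d <= threshold.

    Undefined (NaN) pairs are treated as exceeding the threshold.  Cluster
    labels are deterministic: the lexicographically smallest member id.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = len(matrix.labels)
    if n == 0:
        raise ValueError("empty distance matrix")
    with np.errstate(invalid="ignore"):
        adj = csr_matrix(np.nan_to_num(matrix.d, nan=np.inf) <= threshold)
    _, comp = connected_components(adj, directed=False)
    label_for_comp: dict = {}
    for c in np.unique(comp):
        members = [matrix.labels[i] for i in np.flatnonzero(comp == c)]
        label_for_comp[c] = min(members)
    assignment = {matrix.labels[i]: label_for_comp[comp[i]] for i in range(n)}
    return OTUPartition(assignment=assignment, threshold=threshold)


@dataclass
class ClusterSummary:
    """Per-cluster size, cohesion and nearest-neighbour statistics.

    Distances are fractions (substitutions/site); ``max_intra`` is None for
    singletons and ``nn_*`` fields are None when only one cluster exists.
    """

    cluster_id: str
    n: int
    max_intra: float | None
    nn_cluster: str | None
    nn_dist: float | None
    hosts: frozenset = frozenset()
    countries: frozenset = frozenset()


def cluster_summaries(
    matrix: DistanceMatrix,
    partition: OTUPartition,
    metadata: pd.DataFrame | None = None,
) -> list:
    """Table-style per-cluster statistics (max intra, NN cluster/distance)."""
    clusters = partition.clusters()
    idx = {lab: i for i, lab in enumerate(matrix.labels)}
    meta_by_id: dict = {}
    if metadata is not None:
        for _, row in metadata.iterrows():
            meta_by_id[row["id"]] = row
    out = []
    for cid, members in clusters.items():
        mi = [idx[m] for m in members]
        sub = matrix.d[np.ix_(mi, mi)]
        iu = np.triu_indices(len(mi), k=1)
        intra = sub[iu]
        intra = intra[~np.isnan(intra)]
        max_intra = float(intra.max()) if intra.size else None
        nn_cluster = nn_dist = None
        others = [i for lab, i in idx.items() if partition.assignment[lab] != cid]
        if others:
            cross = matrix.d[np.ix_(mi, others)]
            with np.errstate(invalid="ignore"):
                flat = np.where(np.isnan(cross), np.inf, cross)
            j = int(np.argmin(flat))
            r, c = divmod(j, len(others))
            if math.isfinite(flat[r, c]):
                nn_dist = float(flat[r, c])
                nn_cluster = partition.assignment[matrix.labels[others[c]]]
        hosts, countries = set(), set()
        for m in members:
            row = meta_by_id.get(m)
            if row is not None:
                if row.get("host", ""):
                    hosts.add(row["host"])
                if row.get("country", ""):
                    countries.add(row["country"])
        out.append(
            ClusterSummary(cid, len(members), max_intra, nn_cluster, nn_dist,
                           frozenset(hosts), frozenset(countries))
        )
    return out


def summaries_to_tsv(summaries: Sequence[ClusterSummary], path) -> None:
    """Export with percent distances rounded to one decimal."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "cluster": s.cluster_id,
                "n": s.n,
                "max_intra_pct": "" if s.max_intra is None else f"{100 * s.max_intra:.1f}",
                "nn_cluster": s.nn_cluster or "",
                "nn_dist_pct": "" if s.nn_dist is None else f"{100 * s.nn_dist:.1f}",
                "hosts": ";".join(sorted(s.hosts)),
                "countries": ";".join(sorted(s.countries)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


_IUPAC_FOR = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def consensus_barcode(sequences: Sequence[str]) -> str:
    """Column-wise consensus of aligned sequences.

    Per column: the unique plurality base among A/C/G/T (missing and
    ambiguous symbols excluded from the tally); ties yield the minimal
    IUPAC code covering the tied bases; all-missing columns yield N.
    Idempotent: the consensus of {consensus} is itself.
    """
    if not sequences:
        raise ValueError("no sequences")
    seqs = [str(s).upper() for s in sequences]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences must be aligned (equal length)")
    mat = np.vstack([_encode(s) for s in seqs])
    out = []
    for col in mat.T:
        counts = np.bincount(col[col < 4], minlength=4)
        if counts.sum() == 0:
            out.append("N")
            continue
        top = counts.max()
        tied = [base for base, c in zip("ACGT", counts) if c == top]
        out.append(tied[0] if len(tied) == 1 else _IUPAC_FOR[frozenset(tied)])
    return "".join(out)


@dataclass
class ReferenceMatch:
    """Outcome of assigning one query to a reference panel."""

    species: tuple  # one name, or several on a tie
    dist: float | None
    status: str  # assigned | novel | unresolved
    distances: dict = field(default_factory=dict)


def assign_to_reference(
    query_seq: str,
    panel: Mapping[str, str],
    threshold: float = COI3_SPECIES_THRESHOLD,
) -> ReferenceMatch:
    """Assign a query to the nearest reference species by K2P distance.

    Assigned when the minimum distance is <= threshold; novel when it
    exceeds it (the distance is always reported so a stricter novelty
    margin can be applied downstream); unresolved when every panel
    comparison is undefined or two species tie exactly at the minimum.
    """
    if not panel:
        raise ValueError("empty reference panel")
    dists = {}
    for name in sorted(panel):
        try:
            d, _ = k2p_distance(query_seq, panel[name])
        except NoComparableSitesError:
            d = math.nan
        dists[name] = d
    defined = {n: d for n, d in dists.items() if not math.isnan(d)}
    if not defined:
        return ReferenceMatch((), None, "unresolved", dists)
    dmin = min(defined.values())
    best = tuple(sorted(n for n, d in defined.items() if abs(d - dmin) < 1e-12))
    if len(best) > 1:
        return ReferenceMatch(best, dmin, "unresolved", dists)
    status = "assigned" if dmin <= threshold else "novel"
    return ReferenceMatch(best, dmin, status, dists)


@dataclass
class TranslationRow:
    """One COI-5' cluster and its COI-3'-determined species identity."""

    coi5_cluster_id: str
    coi3_species: str | None  # species name, NOVEL, or None when unresolved
    representative_ids: tuple
    dist_to_nearest_reference: float | None
    status: str  # assigned | novel | unresolved


def build_translation_table(
    coi5_partition: OTUPartition,
    representatives: Mapping[str, Sequence[str]],
    coi3_assignments: Mapping[str, ReferenceMatch],
) -> list:
    """One row per COI-5' cluster from its representatives' COI-3' matches.

    Several clusters may map to the same species (many-to-one translation);
    representatives of one cluster mapping to *different* species raise
    :class:`ConflictError` listing the conflicting names.  Clusters without
    representatives are reported unresolved.
    """
    rows = []
    for cid in sorted(coi5_partition.clusters()):
        reps = tuple(representatives.get(cid, ()))
        matches = [coi3_assignments[r] for r in reps if r in coi3_assignments]
        if not matches:
            rows.append(TranslationRow(cid, None, reps, None, "unresolved"))
            continue
        verdicts = set()
        for m in matches:
            if m.status == "assigned":
                verdicts.add(m.species[0])
            elif m.status == "novel":
                verdicts.add(NOVEL)
        dists = [m.dist for m in matches if m.dist is not None]
        dmin = min(dists) if dists else None
        if len(verdicts) > 1:
            raise ConflictError(
                f"cluster {cid}: representatives map to conflicting species {sorted(verdicts)}"
            )
        if not verdicts:  # every representative unresolved
            rows.append(TranslationRow(cid, None, reps, dmin, "unresolved"))
            continue
        name = verdicts.pop()
        status = "novel" if name == NOVEL else "assigned"
        rows.append(TranslationRow(cid, name, reps, dmin, status))
    return rows


def translation_to_tsv(rows: Sequence[TranslationRow], path) -> None:
    df = pd.DataFrame(
        [
            {
                "coi5_cluster": r.coi5_cluster_id,
                "coi3_species": r.coi3_species or "",
                "representatives": ";".join(r.representative_ids),
                "nn_reference_dist_pct": ""
                if r.dist_to_nearest_reference is None
                else f"{100 * r.dist_to_nearest_reference:.1f}",
                "status": r.status,
            }
            for r in rows
        ]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
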