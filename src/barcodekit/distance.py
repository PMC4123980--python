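"""Kimura 2-parameter distances and barcode-gap diagnostics.

The K2P model corrects observed divergence separately for transitions
(A<->G, C<->T; proportion P of compared sites) and transversions
(proportion Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Columns where either sequence carries anything other than A/C/G/T are
excluded pair by pair (pairwise deletion, the default of standard distance
software; complete deletion is available via :func:`complete_deletion_columns`).
Pairs saturated beyond the domain of the logarithms are reported as
*undefined* rather than clamped: silently capping distances would corrupt
the barcode gap between intra- and inter-cluster distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio_qc import AlignmentMatrix, _encode

__all__ = [
    "PairwiseSiteCounts",
    "DistanceMatrix",
    "GapSummary",
    "NoComparableSitesError",
    "k2p_distance",
    "distance_matrix",
    "summarize_distances",
    "distance_histogram",
    "ranked_distances",
    "intra_inter_summary",
    "complete_deletion_columns",
]


class NoComparableSitesError(ValueError):
    """Raised when two sequences share no unambiguous columns."""


@dataclass(frozen=True)
class PairwiseSiteCounts:
    """Transition/transversion bookkeeping for one sequence pair."""

    valid_sites: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.valid_sites

    @property
    def Q(self) -> float:
        return self.transversions / self.valid_sites


def _k2p_from_counts(counts: PairwiseSiteCounts) -> float:
    """K2P distance; NaN when the log arguments are out of domain."""
    p, q = counts.P, counts.Q
    a, b = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if a <= 0.0 or b <= 0.0:
        return math.nan
    return -0.5 * math.log(a) - 0.25 * math.log(b) + 0.0  # +0.0 avoids -0.0


def _pair_counts(a: np.ndarray, b: np.ndarray) -> PairwiseSiteCounts:
    valid = (a < 4) & (b < 4)
    nv = int(np.count_nonzero(valid))
    if nv == 0:
        raise NoComparableSitesError("no comparable sites")
    diff = valid & (a != b)
    # A=0 C=1 G=2 T=3: transitions keep parity (A<->G even, C<->T odd)
    ts = int(np.count_nonzero(diff & ((a & 1) == (b & 1))))
    tv = int(np.count_nonzero(diff)) - ts
    return PairwiseSiteCounts(nv, ts, tv)


def k2p_distance(seq_a, seq_b):
    """K2P distance between two aligned sequences.

    Returns ``(distance, PairwiseSiteCounts)``; the distance is NaN when
    the correction is undefined (saturation).  Raises
    :class:`NoComparableSitesError` when no column has A/C/G/T in both.
    """
    a = seq_a if isinstance(seq_a, np.ndarray) else _encode(str(seq_a).upper())
    b = seq_b if isinstance(seq_b, np.ndarray) else _encode(str(seq_b).upper())
    if len(a) != len(b):
        raise ValueError("sequences must be equal length (aligned)")
    counts = _pair_counts(a, b)
    return _k2p_from_counts(counts), counts


def p_distance(seq_a, seq_b) -> float:
    """Uncorrected proportion of differing sites (pairwise deletion)."""
    a = seq_a if isinstance(seq_a, np.ndarray) else _encode(str(seq_a).upper())
    b = seq_b if isinstance(seq_b, np.ndarray) else _encode(str(seq_b).upper())
    c = _pair_counts(a, b)
    return (c.transitions + c.transversions) / c.valid_sites


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with undefined-pair bookkeeping."""

    labels: tuple
    d: np.ndarray
    undefined_pairs: tuple = ()

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def value(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def defined_values(self) -> np.ndarray:
        """Upper-triangle distances excluding undefined (NaN) pairs."""
        iu = np.triu_indices(len(self.labels), k=1)
        vals = self.d[iu]
        return vals[~np.isnan(vals)]

    @property
    def n_pairs(self) -> int:
        n = len(self.labels)
        return n * (n - 1) // 2

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        sub = self.d[np.ix_(idx, idx)]
        und = tuple(p for p in self.undefined_pairs if p[0] in set(ids) and p[1] in set(ids))
        return DistanceMatrix(tuple(ids), sub.copy(), und)

    def to_square_tsv(self, path) -> None:
        df = pd.DataFrame(self.d, index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t", lineterminator="\n")

    def to_long_tsv(self, path, counts: Mapping | None = None) -> None:
        rows = []
        for i, a in enumerate(self.labels):
            for j in range(i + 1, len(self.labels)):
                b = self.labels[j]
                row = {"id_a": a, "id_b": b, "distance": self.d[i, j]}
                if counts is not None:
                    row["valid_sites"] = counts[(a, b)].valid_sites
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def distance_matrix(alignment) -> DistanceMatrix:
    """All-pairs K2P matrix over an alignment (pairwise deletion).

    Per-pair failures (no comparable sites, saturated logs) are recorded in
    ``undefined_pairs`` as NaN entries, never clamped.  The result does not
    depend on record order beyond the corresponding permutation.
    """
    if isinstance(alignment, AlignmentMatrix):
        labels, seqs = alignment.ids, alignment.seqs
    else:
        labels = [r.id for r in alignment]
        seqs = [r.seq for r in alignment]
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("records are not aligned (unequal lengths)")
    if not labels:
        raise ValueError("empty alignment")
    enc = [_encode(s) for s in seqs]
    n = len(labels)
    d = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dist, _ = k2p_distance(enc[i], enc[j])
            except NoComparableSitesError:
                dist = math.nan
            if math.isnan(dist):
                undefined.append((labels[i], labels[j]))
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(tuple(labels), d, tuple(undefined))


def pairwise_counts(alignment) -> dict:
    """Site-count bookkeeping for every pair (for long-form export)."""
    if isinstance(alignment, AlignmentMatrix):
        labels, seqs = alignment.ids, alignment.seqs
    else:
        labels, seqs = [r.id for r in alignment], [r.seq for r in alignment]
    enc = [_encode(s) for s in seqs]
    out = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            try:
                out[(labels[i], labels[j])] = _pair_counts(enc[i], enc[j])
            except NoComparableSitesError:
                out[(labels[i], labels[j])] = PairwiseSiteCounts(0, 0, 0)
    return out


def complete_deletion_columns(alignment) -> AlignmentMatrix:
    """Drop every column containing a non-A/C/G/T symbol in any record."""
    from .seqio_qc import SequenceRecord

    mat = np.vstack([_encode(s) for s in alignment.seqs])
    keep = np.all(mat < 4, axis=0)
    if not keep.any():
        raise ValueError("complete deletion removed every column")
    recs = [
        SequenceRecord(id=r.id, seq="".join(np.array(list(r.seq))[keep]), marker=r.marker,
                       meta=dict(r.meta))
        for r in alignment.records
    ]
    return AlignmentMatrix(records=recs, ncol=int(keep.sum()), frame_offset=0)


def summarize_distances(matrix: DistanceMatrix) -> dict:
    """Min/max/mean over defined pairs, plus pair and undefined counts."""
    if len(matrix.labels) < 2:
        raise ValueError("need at least two sequences")
    vals = matrix.defined_values()
    if vals.size == 0:
        raise ValueError("all pairs undefined")
    return {
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "n_pairs": int(matrix.n_pairs),
        "n_undefined": len(matrix.undefined_pairs),
    }


def distance_histogram(matrix: DistanceMatrix, bin_width: float) -> pd.DataFrame:
    """Half-open histogram [k*w, (k+1)*w) of the defined pairwise distances."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = matrix.defined_values()
    if vals.size == 0:
        raise ValueError("no defined pairs to bin")
    # tiny epsilon keeps values on a bin boundary in the upper bin despite
    # floating-point division error
    idx = np.floor(vals / bin_width + 1e-9).astype(int)
    counts = np.bincount(idx)
    return pd.DataFrame(
        {
            "bin_low": np.arange(len(counts)) * bin_width,
            "bin_high": (np.arange(len(counts)) + 1) * bin_width,
            "count": counts,
        }
    )


def ranked_distances(matrix: DistanceMatrix) -> np.ndarray:
    """Defined pairwise distances sorted ascending."""
    vals = matrix.defined_values()
    if vals.size == 0:
        raise ValueError("no defined pairs to rank")
    return np.sort(vals)


@dataclass
class GapSummary:
    """Intra- vs inter-cluster distance distributions and the barcode gap."""

    per_cluster_max_intra: dict
    intra: np.ndarray
    inter: np.ndarray
    gap: float | None  # min_inter - max_intra; None when either side is empty

    @property
    def max_intra(self) -> float | None:
        return float(self.intra.max()) if self.intra.size else None

    @property
    def min_inter(self) -> float | None:
        return float(self.inter.min()) if self.inter.size else None


def intra_inter_summary(matrix: DistanceMatrix, partition: Mapping[str, str]) -> GapSummary:
    """Split pairwise distances by a cluster partition and report the gap.

    Undefined pairs are excluded from both distributions; singleton clusters
    contribute no intra pairs.  When only one cluster exists the inter
    distribution is empty and the gap is reported as None.
    """
    missing = [lab for lab in matrix.labels if lab not in partition]
    if missing:
        raise ValueError(f"partition does not cover labels: {missing[:5]}")
    intra, inter = [], []
    per_cluster: dict = {}
    labels = matrix.labels
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            v = matrix.d[i, j]
            if math.isnan(v):
                continue
            if partition[a] == partition[b]:
                intra.append(v)
                c = partition[a]
                per_cluster[c] = max(per_cluster.get(c, 0.0), float(v))
            else:
                inter.append(v)
    for c in set(partition.values()):
        per_cluster.setdefault(c, None)  # singletons: no intra pairs
    intra_arr, inter_arr = np.array(intra), np.array(inter)
    gap = None
    if intra_arr.size and inter_arr.size:
        gap = float(inter_arr.min() - intra_arr.max())
    return GapSummary(per_cluster, intra_arr, inter_arr, gap)
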