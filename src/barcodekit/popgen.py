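"""Haplotype collapsing, diversity indices and neutrality tests.

Implements the classic summary statistics for a sample of n aligned
sequences: segregating sites S and singletons Eta(s), mean pairwise
differences k, nucleotide diversity pi = k / L, haplotype diversity
Hd = n/(n-1) (1 - sum p_i^2), Tajima's D, and Fu's Fs.

Tajima's D contrasts the pi-based and S-based estimators of theta:

    D = (k - S/a1) / sqrt(e1 S + e2 S (S-1))

with the standard constants a1, a2, b1, b2, c1, c2, e1, e2 of Tajima
(1989).  Fu's Fs is the log-odds of observing at least the sampled number
of haplotypes under the Ewens sampling formula at theta = k:

    S' = P(K >= k_obs | theta) = sum_{j>=k_obs} |S1(n,j)| theta^j / theta^(n)
    Fs = ln(S' / (1 - S'))

where |S1(n,j)| are unsigned Stirling numbers of the first kind and
theta^(n) the rising factorial.  For the sample sizes that occur in
barcode surveys (n in the hundreds) these quantities overflow, so the
whole computation runs in log space.

Missing data are handled by complete deletion by default (every column
containing a non-A/C/G/T symbol in any sequence is dropped before any
statistic is computed); a pairwise-deletion variant is available for
k and pi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .seqio_qc import AlignmentMatrix, _encode

__all__ = [
    "Haplotype",
    "HaplotypeTable",
    "DiversityStats",
    "TajimaConstants",
    "StirlingTable",
    "collapse_haplotypes",
    "segregating_sites",
    "diversity",
    "tajimas_d",
    "fus_fs",
    "diversity_report",
]


def _matrix(alignment) -> tuple:
    """Encoded (n, L) uint8 matrix plus ids and country labels."""
    if isinstance(alignment, AlignmentMatrix):
        recs = alignment.records
    else:
        recs = list(alignment)
        if len({len(r.seq) for r in recs}) > 1:
            raise ValueError("records are not aligned")
    if not recs:
        raise ValueError("empty alignment")
    mat = np.vstack([_encode(r.seq) for r in recs])
    ids = [r.id for r in recs]
    countries = [r.meta.get("country", "") for r in recs]
    return mat, ids, countries


def _complete_columns(mat: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.all(mat < 4, axis=0))


@dataclass
class Haplotype:
    id: str
    sequence: str
    count: int
    member_ids: tuple
    country_counts: dict


@dataclass
class HaplotypeTable:
    haplotypes: list
    n: int
    L_used: int

    def counts(self) -> np.ndarray:
        return np.array([h.count for h in self.haplotypes])

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def to_tsv(self, path) -> None:
        rows = []
        for h in self.haplotypes:
            rows.append(
                {
                    "haplotype": h.id,
                    "count": h.count,
                    "countries": ";".join(
                        f"{c}:{k}" for c, k in sorted(h.country_counts.items())
                    ),
                    "members": ";".join(h.member_ids),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def collapse_haplotypes(alignment, deletion_policy: str = "complete") -> HaplotypeTable:
    """Merge sequences identical on retained columns into haplotypes.

    ``deletion_policy``: "complete" drops every column with missing or
    ambiguous data before comparison; "none" compares full sequences
    literally.  Haplotypes are ordered by descending count, ties by first
    occurrence, and labelled Hap01, Hap02, ...  Note that under complete
    deletion two sequences differing only at removed columns collapse into
    the same haplotype.
    """
    mat, ids, countries = _matrix(alignment)
    if deletion_policy == "complete":
        cols = _complete_columns(mat)
        if cols.size == 0:
            raise ValueError("complete deletion removed every column")
        mat = mat[:, cols]
    elif deletion_policy != "none":
        raise ValueError("deletion_policy must be 'complete' or 'none'")
    L_used = mat.shape[1]
    groups: dict = {}
    order: list = []
    for i, row in enumerate(mat):
        key = row.tobytes()
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)
    ranked = sorted(order, key=lambda k: (-len(groups[k]), order.index(k)))
    haplotypes = []
    base = np.array(list("ACGTN"))
    for rank, key in enumerate(ranked, start=1):
        members = groups[key]
        seq = "".join(base[np.minimum(np.frombuffer(key, dtype=np.uint8), 4)])
        cc: dict = {}
        for i in members:
            c = countries[i] or "unknown"
            cc[c] = cc.get(c, 0) + 1
        haplotypes.append(
            Haplotype(f"Hap{rank:02d}", seq, len(members),
                      tuple(ids[i] for i in members), cc)
        )
    return HaplotypeTable(haplotypes, n=mat.shape[0], L_used=L_used)


def segregating_sites(alignment) -> tuple:
    """(S, Eta_s): polymorphic columns and singleton columns.

    Computed on complete-deletion columns.  A singleton column is biallelic
    with minor-allele count exactly 1.
    """
    mat, _, _ = _matrix(alignment)
    mat = mat[:, _complete_columns(mat)]
    S = 0
    eta_s = 0
    for col in mat.T:
        counts = np.bincount(col, minlength=4)
        alleles = np.flatnonzero(counts)
        if len(alleles) >= 2:
            S += 1
            if len(alleles) == 2 and counts[alleles].min() == 1:
                eta_s += 1
    return S, eta_s


def _mean_pairwise_diffs(mat: np.ndarray) -> float:
    """Mean pairwise difference count via per-column allele tallies."""
    n = mat.shape[0]
    total = 0.0
    for col in mat.T:
        counts = np.bincount(col, minlength=4)
        total += (n * n - int((counts.astype(np.int64) ** 2).sum())) / 2.0
    return total / (n * (n - 1) / 2.0)


def diversity(alignment, deletion_policy: str = "complete") -> tuple:
    """(k, pi, Hd): mean pairwise differences, per-site diversity, haplotype diversity.

    Hd always derives from complete-deletion haplotypes; k and pi honour the
    requested deletion policy ("complete" or "pairwise").
    """
    mat, _, _ = _matrix(alignment)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    if deletion_policy == "complete":
        cols = _complete_columns(mat)
        if cols.size == 0:
            raise ValueError("complete deletion removed every column")
        sub = mat[:, cols]
        k = _mean_pairwise_diffs(sub)
        pi = k / sub.shape[1]
    elif deletion_policy == "pairwise":
        ks, pis = [], []
        for i in range(n):
            for j in range(i + 1, n):
                valid = (mat[i] < 4) & (mat[j] < 4)
                nv = int(valid.sum())
                if nv == 0:
                    continue
                diff = int(np.count_nonzero(valid & (mat[i] != mat[j])))
                ks.append(diff)
                pis.append(diff / nv)
        if not ks:
            raise ValueError("no comparable pairs")
        k, pi = float(np.mean(ks)), float(np.mean(pis))
    else:
        raise ValueError("deletion_policy must be 'complete' or 'pairwise'")
    ht = collapse_haplotypes(alignment, "complete")
    p = ht.counts() / ht.n
    hd = (ht.n / (ht.n - 1)) * (1.0 - float((p**2).sum()))
    return k, pi, hd


@dataclass(frozen=True)
class TajimaConstants:
    """The a1..e2 constants of Tajima's D for sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def from_n(cls, n: int) -> "TajimaConstants":
        if n < 4:
            raise ValueError("Tajima's D requires n >= 4")
        i = np.arange(1, n)
        a1 = float((1.0 / i).sum())
        a2 = float((1.0 / i**2).sum())
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(S: int, k: float, n: int) -> float:
    """Tajima's D from segregating sites, mean pairwise differences and n.

    Returns NaN when S = 0 (the statistic is undefined, not zero).
    """
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0:
        return math.nan
    c = TajimaConstants.from_n(n)
    return (k - S / c.a1) / math.sqrt(c.e1 * S + c.e2 * S * (S - 1))


class StirlingTable:
    """Log-magnitude table of unsigned Stirling numbers of the first kind.

    ``log_s[m, j] = ln |S1(m, j)|`` for 0 <= j <= m <= n, built with the
    recurrence |S1(m, j)| = |S1(m-1, j-1)| + (m-1) |S1(m-1, j)| evaluated
    via logaddexp so that n in the hundreds stays finite.
    """

    def __init__(self, n: int):
        if n < 1:
            raise ValueError("n must be >= 1")
        self.n = n
        log_s = np.full((n + 1, n + 1), -np.inf)
        log_s[0, 0] = 0.0
        for m in range(1, n + 1):
            log_s[m, 1 : m + 1] = np.logaddexp(
                log_s[m - 1, 0:m], math.log(m - 1) + log_s[m - 1, 1 : m + 1]
                if m > 1
                else -np.inf,
            )
        self.log_s = log_s

    def __call__(self, m: int, j: int) -> float:
        return float(self.log_s[m, j])


@lru_cache(maxsize=64)
def _stirling(n: int) -> StirlingTable:
    return StirlingTable(n)


def fus_fs(n: int, k_obs: int, theta: float) -> float:
    """Fu's Fs from sample size, observed haplotype count and theta = k.

    Returns NaN when k_obs = 1 (every sample has at least one allele, so
    S' = 1 and the log-odds diverge).  theta must be positive.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 1 <= k_obs <= n:
        raise ValueError("k_obs must be in [1, n]")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if k_obs == 1:
        return math.nan
    table = _stirling(n)
    j = np.arange(k_obs, n + 1)
    log_num = logsumexp(table.log_s[n, k_obs : n + 1] + j * math.log(theta))
    log_den = float(np.log(theta + np.arange(n)).sum())
    log_sp = min(log_num - log_den, -1e-15)  # S' < 1 analytically for k_obs >= 2
    # Fs = ln S' - ln(1 - S'); 1 - S' = -expm1(ln S')
    return log_sp - math.log(-math.expm1(log_sp))


@dataclass
class DiversityStats:
    """One group's row of diversity indices and neutrality tests."""

    group: str
    n: int
    S: int
    Eta_s: int
    k: float
    pi: float
    n_haplotypes: int
    Hd: float
    tajima_D: float
    fu_Fs: float


def diversity_report(
    alignment_by_group: Mapping[str, object],
    deletion_policy: str = "complete",
) -> pd.DataFrame:
    """Diversity-table rows (one per group) combining all statistics.

    Undefined statistics (D with S = 0, Fs with a single haplotype or
    theta = 0) are reported as NaN.
    """
    rows = []
    for group in sorted(alignment_by_group):
        aln = alignment_by_group[group]
        S, eta_s = segregating_sites(aln)
        k, pi, hd = diversity(aln, deletion_policy)
        ht = collapse_haplotypes(aln, "complete")
        n = ht.n
        D = tajimas_d(S, k, n) if (S >= 1 and n >= 4) else math.nan
        Fs = fus_fs(n, ht.n_haplotypes, k) if k > 0 else math.nan
        rows.append(
            DiversityStats(group, n, S, eta_s, k, pi, ht.n_haplotypes, hd, D, Fs)
        )
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "n": r.n,
                "S": r.S,
                "k": r.k,
                "pi": r.pi,
                "Eta_s": r.Eta_s,
                "n_haplotypes": r.n_haplotypes,
                "Hd": r.Hd,
                "fu_Fs": r.fu_Fs,
                "tajima_D": r.tajima_D,
            }
            for r in rows
        ]
    )
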