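"""Synthetic barcode datasets with known ground truth.

Emulates the structure of a cryptic-species barcode survey: K deeply
divergent clusters (OTUs/species) whose ancestors sit on a star phylogeny
at a controlled expected divergence, each cluster carrying a neutral
constant-size Kingman coalescent sample of closely related haplotypes
with one dominant haplotype, two-country sampling labels, and optionally
a second linked marker evolving on the same genealogy.

The mutation process is finite-sites with a transition/transversion rate
ratio kappa (default 4, typical for insect mitochondrial DNA), so the
transition/transversion bookkeeping of K2P distances is genuinely
exercised.  All sequences stay in coding frame with no internal stop
codons (substitutions creating a stop are redrawn), so generated data
always pass translation QC.  Expectations under the coalescent:
E[S] = theta * a1(n) and E[k] = theta, which the test suite checks.

Everything is driven by one integer seed through a single PCG64 stream,
so outputs are byte-identical across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio_qc import SequenceRecord, write_fasta

__all__ = [
    "SyntheticConfig",
    "SimulatedSample",
    "SyntheticDataset",
    "simulate_cluster_ancestors",
    "simulate_coalescent_sample",
    "emit_dataset",
]

_STOPS = ("TAA", "TAG")  # invertebrate mitochondrial code
_BASES = "ACGT"
_STOP_CODES = {tuple("ACGT".index(c) for c in s) for s in _STOPS}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters with the survey-like defaults.

    ``L``/``L3`` are codon multiples (barcode ~657 bp, 3' fragment ~780 bp);
    ``theta`` is the per-cluster scaled mutation parameter (per locus, so
    E[mean pairwise differences] = theta, matching the low single-digit
    values of real barcode samples); ``d_between`` is the expected
    between-cluster divergence in substitutions/site (deep, ~8%, well
    clear of within-cluster variation); ``kappa`` the ts/tv rate ratio.
    """

    K: int = 5
    n_per: int = 20
    L: int = 657
    theta: float = 2.0
    d_between: float = 0.08
    kappa: float = 4.0
    countries: tuple = (("Pakistan", 0.6), ("India", 0.4))
    dual_marker: bool = False
    L3: int = 780
    theta3: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_per < 2:
            raise ValueError("n_per must be >= 2")
        if self.L < 60 or self.L % 3:
            raise ValueError("L must be a codon multiple >= 60")
        if self.L3 % 3:
            raise ValueError("L3 must be a codon multiple")
        if self.theta <= 0 or self.theta3 <= 0:
            raise ValueError("theta must be positive")
        if self.d_between <= 0:
            raise ValueError("d_between must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        weights = [w for _, w in self.countries]
        if not weights or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("country weights must sum to 1")


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[i] for i in arr)


def _random_coding_seq(L: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random codons avoiding stop codons (frame 0)."""
    seq = rng.integers(0, 4, size=L)
    for i in range(0, L, 3):
        while tuple(seq[i : i + 3]) in _STOP_CODES:
            seq[i : i + 3] = rng.integers(0, 4, size=3)
    return seq


def _mutate(seq: np.ndarray, n_events: int, kappa: float,
            rng: np.random.Generator, max_retry: int = 1000) -> np.ndarray:
    """Apply substitution events with ts/tv bias, never creating a stop.

    A transition is chosen with probability kappa/(kappa+2), otherwise one
    of the two transversions.  An event that would create a stop codon in
    frame is redrawn (site and target), with a bounded retry budget.
    """
    out = seq.copy()
    p_ts = kappa / (kappa + 2.0)
    for _ in range(n_events):
        for attempt in range(max_retry):
            site = int(rng.integers(0, len(out)))
            b = out[site]
            if rng.random() < p_ts:
                new = (b + 2) % 4  # A<->G, C<->T
            else:
                # the two transversion targets, in fixed order
                tv = [(b + 1) % 4, (b + 3) % 4]
                new = tv[int(rng.integers(0, 2))]
            c0 = site - site % 3
            codon = (out[c0], out[c0 + 1], out[c0 + 2])
            codon = tuple(new if c0 + k == site else codon[k] for k in range(3))
            if codon not in _STOP_CODES:
                out[site] = new
                break
        else:
            raise RuntimeError("could not place substitution without creating a stop")
    return out


def simulate_cluster_ancestors(config: SyntheticConfig,
                               rng: np.random.Generator | None = None,
                               L: int | None = None) -> list:
    """K ancestor sequences on a star phylogeny.

    Each ancestor receives Poisson(L * d_between / 2) substitutions from a
    shared root, so the expected pairwise divergence between ancestors is
    d_between substitutions/site.  K = 1 returns the root itself.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.L if L is None else L
    root = _random_coding_seq(L, rng)
    if config.K == 1:
        return [root]
    branch_mean = L * config.d_between / 2.0
    return [
        _mutate(root, int(rng.poisson(branch_mean)), config.kappa, rng)
        for _ in range(config.K)
    ]


@dataclass
class SimulatedSample:
    """A coalescent sample: sequences, genealogy and true haplotypes."""

    sequences: list  # decoded strings, tip order s1..sn
    newick: str
    haplotype_of: list  # tip index -> 0-based haplotype index (by identity)
    total_branch_length: float


def _sim_genealogy(n: int, rng: np.random.Generator):
    """Kingman coalescent: parent/branch-length arrays over 2n-1 nodes.

    Waiting time with i active lineages is Exp(i(i-1)/2); node ids are
    0..n-1 for tips, n..2n-2 for internal nodes in coalescence order (the
    root is node 2n-2).  Branch lengths are in coalescent time units.
    """
    parent = np.full(2 * n - 1, -1, dtype=int)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        i = len(active)
        t += rng.exponential(2.0 / (i * (i - 1)))
        a, b = sorted(rng.choice(i, size=2, replace=False))
        u, v = active[a], active[b]
        parent[u] = parent[v] = nxt
        time[nxt] = t
        active[a] = nxt
        active.pop(b)
        nxt += 1
    blen = np.zeros(2 * n - 1)
    for node in range(2 * n - 2):
        blen[node] = time[parent[node]] - time[node]
    return parent, blen


def _newick_from_parent(parent: np.ndarray, blen: np.ndarray, n: int) -> str:
    children: dict = {}
    for node, p in enumerate(parent):
        if p >= 0:
            children.setdefault(int(p), []).append(node)

    def render(node: int) -> str:
        if node < n:
            return f"s{node + 1}:{blen[node]:.6f}"
        inner = ",".join(render(c) for c in sorted(children[node]))
        suffix = "" if parent[node] < 0 else f":{blen[node]:.6f}"
        return f"({inner}){suffix}"

    return render(2 * n - 2) + ";"


def _drop_mutations(parent, blen, ancestor: np.ndarray, theta: float,
                    kappa: float, rng: np.random.Generator) -> list:
    """Sequences at the tips after Poisson(theta/2 * branch) mutations."""
    n_nodes = len(parent)
    n = (n_nodes + 1) // 2
    seqs: dict = {n_nodes - 1: ancestor}
    for node in range(n_nodes - 2, -1, -1):
        n_mut = int(rng.poisson(theta / 2.0 * blen[node]))
        seqs[node] = _mutate(seqs[parent[node]], n_mut, kappa, rng)
    return [seqs[i] for i in range(n)]


def simulate_coalescent_sample(
    ancestor,
    n: int,
    theta: float,
    kappa: float = 4.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> SimulatedSample:
    """Neutral constant-size coalescent sample descended from ``ancestor``.

    Mutations fall on branches at rate theta/2 per coalescent time unit
    (finite sites, kappa-biased, stop-avoiding), giving E[S] = theta*a1(n)
    and E[mean pairwise differences] = theta.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed) if rng is None else rng
    anc = ancestor if isinstance(ancestor, np.ndarray) else np.array(
        [_BASES.index(c) for c in str(ancestor)]
    )
    parent, blen = _sim_genealogy(n, rng)
    tips = _drop_mutations(parent, blen, anc, theta, kappa, rng)
    seen: dict = {}
    hap_of = []
    for t in tips:
        key = t.tobytes()
        seen.setdefault(key, len(seen))
        hap_of.append(seen[key])
    total = float(blen.sum())
    return SimulatedSample(
        sequences=[_decode(t) for t in tips],
        newick=_newick_from_parent(parent, blen, n),
        haplotype_of=hap_of,
        total_branch_length=total,
    )


@dataclass
class SyntheticDataset:
    """Emitted dataset plus its ground truth."""

    config: SyntheticConfig
    coi5_records: list
    coi3_records: list  # empty unless dual_marker
    metadata: pd.DataFrame
    truth: dict  # cluster_of, species_of_cluster, haplotype_of, country_of, species_panel

    def write(self, outdir) -> dict:
        """Write FASTA + metadata TSV + truth TSV; returns path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"coi5": outdir / "coi5.fasta", "metadata": outdir / "metadata.tsv",
                 "truth": outdir / "truth.tsv"}
        write_fasta(self.coi5_records, paths["coi5"])
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False, lineterminator="\n")
        truth_df = pd.DataFrame(
            [
                {
                    "id": sid,
                    "cluster": self.truth["cluster_of"][sid],
                    "species": self.truth["species_of_cluster"][self.truth["cluster_of"][sid]],
                    "haplotype": self.truth["haplotype_of"][sid],
                    "country": self.truth["country_of"][sid],
                }
                for sid in sorted(self.truth["cluster_of"])
            ]
        )
        truth_df.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
        if self.coi3_records:
            paths["coi3"] = outdir / "coi3.fasta"
            write_fasta(self.coi3_records, paths["coi3"])
            paths["panel"] = outdir / "reference_panel.fasta"
            panel_records = [
                SequenceRecord(id=name, seq=seq, marker="COI3")
                for name, seq in sorted(self.truth["species_panel"].items())
            ]
            write_fasta(panel_records, paths["panel"])
        return paths


def emit_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full dataset the pipeline consumes, with ground truth.

    Deterministic for a fixed config (single seeded RNG stream).  With
    ``dual_marker`` both markers evolve on the same per-cluster genealogy;
    the COI-3' cluster ancestors double as the species reference panel,
    giving a one-to-one cluster -> species truth map.
    """
    rng = np.random.default_rng(config.seed)
    anc5 = simulate_cluster_ancestors(config, rng, L=config.L)
    anc3 = (
        simulate_cluster_ancestors(config, rng, L=config.L3)
        if config.dual_marker
        else []
    )
    names = [c for c, _ in config.countries]
    weights = [w for _, w in config.countries]
    coi5_records, coi3_records = [], []
    cluster_of, haplotype_of, country_of = {}, {}, {}
    species_of_cluster, species_panel = {}, {}
    meta_rows = []
    for ci in range(config.K):
        cluster = f"C{ci + 1:02d}"
        species = f"SP{ci + 1:02d}"
        species_of_cluster[cluster] = species
        if config.dual_marker:
            species_panel[species] = _decode(anc3[ci])
        parent, blen = _sim_genealogy(config.n_per, rng)
        tips5 = _drop_mutations(parent, blen, anc5[ci], config.theta, config.kappa, rng)
        tips3 = (
            _drop_mutations(parent, blen, anc3[ci], config.theta3, config.kappa, rng)
            if config.dual_marker
            else None
        )
        seen: dict = {}
        for si in range(config.n_per):
            sid = f"C{ci + 1:02d}-{si + 1:03d}"
            country = names[int(rng.choice(len(names), p=weights))]
            key = tips5[si].tobytes()
            seen.setdefault(key, len(seen) + 1)
            cluster_of[sid] = cluster
            haplotype_of[sid] = f"{cluster}-H{seen[key]:02d}"
            country_of[sid] = country
            coi5_records.append(
                SequenceRecord(id=sid, seq=_decode(tips5[si]), marker="COI5",
                               meta={"country": country, "cluster_label": cluster})
            )
            if tips3 is not None:
                coi3_records.append(
                    SequenceRecord(id=sid, seq=_decode(tips3[si]), marker="COI3",
                                   meta={"country": country, "cluster_label": cluster})
                )
            meta_rows.append(
                {
                    "id": sid,
                    "marker": "COI5",
                    "country": country,
                    "province": "",
                    "region": "",
                    "host": "",
                    "species_label": species,
                }
            )
    metadata = pd.DataFrame(meta_rows)
    truth = {
        "cluster_of": cluster_of,
        "species_of_cluster": species_of_cluster,
        "haplotype_of": haplotype_of,
        "country_of": country_of,
        "species_panel": species_panel,
    }
    return SyntheticDataset(config, coi5_records, coi3_records, metadata, truth)
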