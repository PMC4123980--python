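# Methods

This note records the models, conventions and design choices behind
barcodekit, in the spirit of the methods documentation of simulation and
statistics packages.

## Quality control and frame-anchored alignment

COI barcode fragments are mid-gene, indel-free protein-coding sequence.
QC therefore enforces three things: (1) *barcode compliance* — strictly
more than `min_len` (default 500) unambiguous A/C/G/T bases, with
ambiguity codes and N counting as missing; (2) absence of gap characters;
(3) absence of stop codons under the invertebrate mitochondrial genetic
code (NCBI table 5, stops TAA/TAG).  A stop at *any* complete codon fails
QC, not just strictly internal ones: a terminal stop in a mid-gene
fragment is equally diagnostic of a frame error or pseudogene.  Frame
`"auto"` picks the lowest-offset stop-free frame and warns when several
frames qualify (common for short fragments).

Because gap-free coding fragments need no progressive multiple alignment,
`build_alignment` anchors each record against the longest record by
ungapped sliding-window identity (deterministic tie-breaks: most matches,
then smallest |shift|, then smallest shift), takes the intersection window
of all records, and records the codon phase of the window's first column
as `frame_offset`.  Retained bases are never modified — only trimming
occurs.  The anchoring assumes primer-anchored fragments whose true
offsets are within `max_shift` (default 60) bases; datasets violating
this need external alignment first.

## Distances

K2P distances use pairwise deletion: a column is compared for a pair only
when both sequences carry A/C/G/T there.  Pairs with no comparable sites,
or where a log argument 1−2P−Q or 1−2Q is ≤ 0 (saturation), are recorded
as *undefined* and excluded from summaries — never clamped to a ceiling,
because clamping would fabricate distance mass exactly where the barcode
gap is measured.  Histogram bins are half-open `[k·w, (k+1)·w)`; a 1e-9
epsilon in the bin index keeps boundary values in the upper bin despite
floating-point division error.  Percent exports round to one decimal;
internal values are full precision.  A complete-deletion variant is
available for cross-software comparison, since distance programs differ
in their default missing-data treatment.

## OTU delimitation and translation

OTUs are the connected components of the graph joining pairs with
d ≤ threshold (single linkage), with deterministic labels (the smallest
member id).  Undefined pairs are treated as exceeding any threshold.
Defaults: 0.02 for COI-5′ barcode OTUs (intraspecific barcode distances
in this complex fall well below 2 %), 0.035 for COI-3′ species (the
established 3.5 % convention).  Threshold clustering is a documented
proxy for registry-style barcode clustering algorithms, so cluster counts
need not equal registry cluster counts on real data; pre-existing cluster
labels can instead be supplied through metadata.

Consensus barcodes take the unique plurality base per column among
A/C/G/T; ties yield the minimal covering IUPAC code and all-missing
columns yield N, which makes the operation idempotent.

Reference assignment computes K2P from the query to every panel
consensus; `assigned` when the minimum is ≤ threshold, `novel` when it
exceeds it (the distance is always reported so a stricter novelty margin
can be imposed downstream), `unresolved` on an exact tie between species
or when every comparison is undefined — the package never silently picks
a species.  In the translation table, several COI-5′ clusters may map to
one species (many-to-one is biologically expected); representatives of a
single cluster mapping to *different* species raise a loud conflict error
rather than a quiet majority vote, because such a conflict means either
contamination or a misassembled cluster.

## Diversity statistics and neutrality tests

All population statistics use complete deletion by default (every column
with missing/ambiguous data in any sequence is dropped before anything is
computed), matching the common default of diversity software; k and π are
also available under pairwise deletion.  A consequence documented here:
haplotype identity is defined on retained columns, so two sequences
differing only at removed columns are one haplotype.

Tajima's D follows the standard constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂;
S = 0 yields an undefined (NaN) statistic, not zero.  Fu's Fs uses
θ = k (the π-estimator) and the Ewens sampling formula tail
S′ = Σ_{j≥k_obs} |S1(n,j)| θ^j / θ^{(n)}.  Unsigned Stirling numbers of
the first kind are tabulated in log space via the recurrence
|S1(m,j)| = |S1(m−1,j−1)| + (m−1)|S1(m−1,j)| with `logaddexp`, and the
tail sum uses log-sum-exp; this is required because |S1(551, j)| far
exceeds double range.  k_obs = 1 gives S′ = 1 and an undefined Fs.  A
numerical guard caps ln S′ at −1e−15 so rounding can never push S′ to or
above 1 for k_obs ≥ 2.

## Haplotype networks

Networks are minimum spanning trees over integer nucleotide-difference
counts, built with Kruskal's algorithm over edges sorted by (weight,
label pair) so the chosen tree is reproducible.  Because equal-weight
spanning trees are common in haplotype data, every non-tree edge whose
weight equals the heaviest tree edge on the cycle it closes is reported
as an alternative edge — these are exactly the ties a network-drawing
tool might display instead.  Median (inferred intermediate) haplotypes
are deliberately not added; this is a pure MST, not a median-joining
network.  Node country classes: one known country → `<country>_only`,
several → `shared`, none → `unknown`.

## Phylogenetics

Tree length is Fitch parsimony with unordered, equally weighted
characters; gaps, N and ambiguity codes enter as IUPAC state-set
wildcards, so missing data never add changes.  Scores are computed on
column patterns (unique columns with multiplicities) and are invariant to
rooting.  Search: exhaustive enumeration of all unrooted binary
topologies for ≤ 9 taxa (global optimum guaranteed; (2n−5)!! topologies),
otherwise random-addition starting trees with best-improvement NNI hill
climbing repeated over `n_starts` seeds; all distinct minimal topologies
found are returned.  The datasets this package targets (tens of consensus
sequences) are well within this search's reach; no attempt is made to
reproduce any particular program's heuristic arsenal, since the object of
interest is the most parsimonious tree itself.

Bootstrap support resamples columns with replacement, reruns the search
per replicate (with a smaller exhaustive cutoff, 7 taxa, to keep
replicates cheap) and reports the percentage of replicate best trees
containing each bipartition of the reference tree.  Values below 50 are
retained; display conventions are the caller's business.  Neighbour
joining is delegated to scikit-bio with negative branch lengths clamped
to zero (a warning reports when clamping occurred); it serves as a light
distance-tree fallback, with display rooting by declared outgroup ids not
affecting any score.

## Geography

Composition tables report percentages per region column over *assigned*
specimens; unassigned specimens appear in an `unresolved` count row and
are excluded from the denominator.  The heterogeneity test is the plain
Pearson chi-square (no continuity correction) with zero margins rejected
by label, validated against hand-computed tables; the package makes no
claim about reproducing any particular published chi-square value, whose
input counts are typically not printed.  Range comparison reduces two
surveys to (species, region) presence sets and classes each cell as
gained / lost / stable, which is the data statement behind range-shift
claims; it is antisymmetric under swapping the surveys.

## Synthetic data generator

The generator emulates the structure such surveys actually show, and its
defaults are the conditions the rest of the documentation and the
acceptance script use:

| parameter | default | meaning |
|---|---|---|
| K | 5 | number of clusters (putative species) |
| n_per | 20 | sequences per cluster |
| L / L3 | 657 / 780 | marker lengths, codon multiples (barcode / 3′ fragment) |
| theta | 2.0 | per-locus scaled mutation parameter per cluster (E[k] = θ) |
| d_between | 0.08 | expected between-cluster divergence, subs/site |
| kappa | 4.0 | transition/transversion rate ratio (typical insect mtDNA) |
| countries | Pakistan 0.6 / India 0.4 | sampling labels |

Cluster ancestors sit on a star phylogeny: each receives
Poisson(L·d_between/2) substitutions from a shared random coding root, so
expected pairwise ancestor divergence is d_between (the star keeps this
directly controllable; a random tree would make pairwise divergences
heterogeneous).  Within clusters, samples follow a neutral constant-size
Kingman coalescent — waiting time Exp(i(i−1)/2) with i lineages, mutations
Poisson(θ/2 · branch length) — giving the standard moments E[S] = θ·a₁(n)
and E[k] = θ, which the test suite verifies by simulation.  Mutation is
finite-sites with κ bias (a transition with probability κ/(κ+2)), so the
transition/transversion machinery of K2P is genuinely exercised, and any
substitution creating an in-frame stop codon is redrawn, so generated
data always pass translation QC.  With the defaults, within-cluster
variation (θ/L ≈ 0.003/site) sits far below d_between, producing the
barcode-gap geometry real surveys show.  A dual-marker mode evolves both
markers on the same per-cluster genealogy with independent mutations; the
COI-3′ cluster ancestors double as the species reference panel, so the
cluster → species truth map is exact.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: sequencing error and chromatogram
artifacts, length variation and primer slippage, NUMTs, recombination,
selection, migration between demes, unequal cluster sizes and uneven
geographic sampling.  Analyses of real surveys should treat the package's
thresholds as starting points, not as validated values for their taxa.

## Numerical and determinism choices

- All randomness flows through one seeded PCG64 stream per entry point;
  generator output and full pipeline reruns are byte-identical for a
  fixed config (the config hash embedded in outputs excludes the output
  directory, so the same analysis hashes identically wherever written).
- Log-space throughout Fu's Fs; logit guard at ln S′ ≤ −1e−15.
- Ties are always broken deterministically and documented: lowest cluster
  label, first edge in sorted order, smallest shift, lexicographic MST
  edges; reference-assignment ties are surfaced as `unresolved` instead.
- Degenerate inputs produce explicit errors or NaN-with-meaning (S = 0,
  single haplotype, saturated pairs), never silent substitutions.
- Test and acceptance problem sizes (hundreds of sequences, 1000
  coalescent replicates at n = 50, L = 600) were chosen so the entire
  suite runs in seconds on one CPU while keeping Monte-Carlo error well
  inside the asserted bands.

## Known limitations

- Single-linkage threshold clustering can chain clusters through
  intermediate haplotypes; counts on real data may differ from
  registry-assigned clusters.
- The alignment anchoring assumes co-linear, indel-free fragments; it is
  not a general aligner.
- Bootstrap support on very small consensus sets (4–6 taxa) is coarse.
- No significance testing (coalescent p-values) for Tajima's D or Fu's
  Fs; only the point statistics are computed.
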