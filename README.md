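# barcodekit

A toolkit for resolving cryptic species complexes with mitochondrial COI
DNA barcodes, built around the workflow used for whitefly (*Bemisia
tabaci*-type) surveys: screen and align barcode fragments, measure Kimura
2-parameter (K2P) distances and the barcode gap, delimit operational
taxonomic units (OTUs) by threshold clustering, connect the COI-5′
"barcode" OTUs to species defined on COI-3′ sequence variation, and
characterize each species with haplotype networks, diversity indices,
neutrality tests and geographic composition tests.  A ground-truthed
synthetic sequence generator makes every stage testable end to end without
any external data.

## Who it is for

Molecular ecologists and entomologists working with two-marker COI surveys
of species complexes: many short, indel-free coding fragments; cluster
structure with shallow within-species and deep between-species divergence;
specimens labelled by country/province/host.

## The statistics at its core

- **K2P distance** between aligned sequences with transition proportion
  *P* and transversion proportion *Q* (pairwise deletion of non-ACGT
  columns):
  *d* = −½ ln(1 − 2*P* − *Q*) − ¼ ln(1 − 2*Q*).
  Saturated pairs where a log argument is ≤ 0 are reported as *undefined*,
  never clamped.
- **OTU delimitation** by single-linkage clustering at a K2P threshold
  (default 0.02 for COI-5′ barcode OTUs, 0.035 for COI-3′ species,
  following the 3.5 % convention for this complex), with per-cluster
  maximum intra-cluster distance and nearest-neighbour (NN) distance.
- **Dual-marker translation**: representative COI-3′ sequences are
  assigned to the nearest species reference consensus; a cluster whose
  nearest reference exceeds the threshold is flagged as a novel lineage,
  with its NN distance always reported.
- **Diversity and neutrality**: segregating sites *S*, singletons η(s),
  mean pairwise differences *k*, nucleotide diversity π = *k*/*L*,
  haplotype diversity *Hd* = *n*/(*n*−1)·(1 − Σp²), **Tajima's D**
  = (*k* − *S*/a₁)/√(e₁S + e₂S(S−1)), and **Fu's Fs**
  = ln(S′/(1−S′)) with S′ = P(K ≥ k_obs | θ = k) from the Ewens sampling
  formula, computed in log space with unsigned Stirling numbers of the
  first kind so samples of many hundreds of sequences stay finite.
- **Haplotype networks**: deterministic minimum spanning trees over
  nucleotide-difference counts, with equal-weight alternative edges
  reported and nodes classed by country (`shared`, `<country>_only`).
- **Phylogenetics**: Fitch parsimony (missing data as IUPAC wildcards),
  exhaustive search for small taxon sets, random-addition + NNI hill
  climbing otherwise, column-bootstrap support, and neighbour joining as a
  distance fallback; Newick I/O.
- **Geography**: species-by-region composition percentages, Pearson
  chi-square heterogeneity (no continuity correction), and survey-to-survey
  range comparison (gained / lost / stable).

## Worked example

Generate a five-species dual-marker survey with known truth, then run the
whole pipeline:

```sh
barcodekit simulate --outdir demo/data --seed 11
barcodekit all \
  --coi5 demo/data/coi5.fasta --coi3 demo/data/coi3.fasta \
  --metadata demo/data/metadata.tsv \
  --reference-panel demo/data/reference_panel.fasta \
  --outdir demo/results --bootstrap-reps 100 --seed 11
```

which prints the stage log:

```
qc: 100/100 records passed
dist: {'min': 0.0, 'max': 0.11206505947489068, 'mean': 0.07284931851196573, 'n_pairs': 4950, 'n_undefined': 0}
delimit: 5 clusters at 0.02
translate: 5 clusters assigned
popgen/network: 5 groups
tree: 5 consensus taxa, 100 reps
geo: composition written
```

All 100 sequences pass QC; pairwise K2P distances span 0–11.2 % with the
bimodal structure of a barcode gap; single-linkage at 2 % recovers exactly
the five simulated clusters, and every cluster's COI-3′ representatives
are assigned to the correct reference species.  `demo/results/` then holds
the per-stage tables, e.g. `cluster_summaries.tsv`:

```
cluster   n   max_intra_pct  nn_cluster  nn_dist_pct  hosts  countries
C01-001   20  1.2            C04-001     9.3                 India;Pakistan
C02-001   20  2.3            C04-001     7.9                 India;Pakistan
C03-001   20  0.5            C04-001     7.2                 India;Pakistan
C04-001   20  0.6            C05-001     7.2                 India;Pakistan
C05-001   20  0.6            C04-001     7.2                 India;Pakistan
```

(maximum within-OTU distances ≤ 2.3 %, nearest neighbours ≥ 7.2 % — a
clean gap), the diversity/neutrality table `diversity.tsv` (*n*, S, k, π,
η(s), haplotype count, Hd, Fu's Fs, Tajima's D per cluster), annotated
haplotype networks (`network_edges.tsv`, `network_nodes.tsv`), the
bootstrap-annotated parsimony tree

```
(C01-001,C02-001,(C04-001,(C03-001,C05-001)48)73);
```

and the species-by-country composition with its chi-square test.  Every
TSV carries the run's config hash in a header comment, and `MANIFEST.tsv`
records a sha256 for every output; rerunning with the same config is
byte-identical.

The same functionality is available as a library
(`barcodekit.distance.k2p_distance`, `barcodekit.delimit`,
`barcodekit.popgen`, ...), which is what the test suite exercises.

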