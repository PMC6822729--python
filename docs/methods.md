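# Methods

This note documents the models, conventions, and design choices behind
`strepnet`, and what its synthetic fixture does and does not establish.

## Networks from assays

A community's inhibition network is a simple labeled digraph over its
isolates. From raw data, each ordered pair has three replicates of two
perpendicular zone-of-inhibition measurements (mm). Binarization averages
the perpendicular pair within each replicate, then averages replicate
means, and writes an edge iff that grand mean is **strictly greater** than
the threshold (default 2 mm); an exact tie is no edge. Averaging
perpendicular-first is numerically identical to the grand mean of all six
readings but keeps per-replicate means available for QC. Replicate
disagreement (e.g. 2 of 3 replicates above threshold) is resolved by the
mean, not by voting — a deliberate choice where the assay convention is
ambiguous. Self-pairs are always excluded, and only within-community
(sympatric) pairs are used; isolates without a community assignment are an
error rather than silently dropped.

## Whole-network metrics

* **L** — mean directed shortest-path hop count over ordered pairs (u, v)
  with v reachable from u. Unreachable pairs are excluded from numerator
  and denominator; infinities are never averaged. L is NaN when no pair is
  reachable.
* **C** — directed transitivity: the number of ordered distinct triples
  with u→v, v→w, u→w divided by the number with u→v, v→w. Its Erdős–Rényi
  expectation is ≈ m/(n(n−1)) (more precisely (m−2)/(n(n−1)−2) conditional
  on two edges), which is what makes the published ER baselines
  (0.25/0.32/0.29 at densities 0.258/0.327/0.294) diagnostic: they match
  the *directed* closure definition and not an undirected collapse, whose
  ER expectation would be ≈ 1−(1−p)² ≈ 0.45 at density 0.258.
* **Small-world indices** — γ = C/C̄_ER, λ = L/L̄_ER, S = γ/λ. The
  published table's definition line inverts the ratio, but only γ/λ
  reproduces all three printed S values (3.12/0.95 = 3.28, 2.31/1.07 =
  2.16, 1.88/1.48 = 1.27), so S = γ/λ is implemented. The printed λ values
  themselves are not L/L̄_ER of the printed rows (e.g. 1.48/2.00 ≠ 0.95);
  whatever ensemble produced them is not recoverable, so
  `small_world_indices` computes λ = L/L̄_ER and also accepts a
  user-supplied λ for the S ratio. Reproducing the printed λ is not
  promised.
* Degree standard deviations are sample (ddof = 1) standard deviations.

## Null models

All three ensembles default to 10,000 networks (reduced in tests and the
bundled drivers; sizes are printed alongside every result).

* **Erdős–Rényi**: exactly m edges placed uniformly among the n(n−1)
  ordered pairs.
* **Dyad-conditioned**: the observed counts of mutual / asymmetric / null
  unordered pairs are assigned uniformly at random to pairs; asymmetric
  dyads are oriented by fair coin. Reciprocity is preserved exactly.
* **Degree-conditioned**: attempted edge swaps from the observed network —
  choose two edges (a→b, c→d), propose (a→d, c→b), apply only if the graph
  stays simple. "1000 swaps" counts **attempts**, matching the trial
  semantics of the standard rewiring implementations; acceptances are also
  reported. Degrees are exact in every sample; the dyad census is *not*
  preserved (mutual edges can be created or destroyed).

Observed-vs-ensemble comparison is a plain two-sided z-test on the
ensemble mean and sd. When an ensemble is degenerate (sd = 0, e.g. a
structurally forced statistic), p is 1 on exact match and 0 otherwise.
Statistics undefined on a sample (no two-path, no reachable pair) are
excluded for that statistic and the exclusion count reported. Each
ensemble runs on its own seeded generator spawned from one master seed, so
whole analyses are bit-reproducible.

## Triads and motifs

Triad classes use the standard 16-class census order (003, 012, 102,
021D, 021U, 021C, 111D, 111U, 030T, 030C, 201, 120D, 120U, 120C, 210,
300), indexed 1..16. This matches the study's numbering: census row sums
equal C(n,3), class 4 is the out-star, and class 10 is the 3-cycle. The
census encodes each node triple as a 6-bit code over its ordered pairs and
maps codes to classes through a precomputed 64-entry table (derived from
canonical forms under all six relabelings), so a full census is a few
vectorized gathers; tests cross-check it against `networkx.triadic_census`
and against per-triple classification.

Motif detection z-tests each class against its ensemble mean/sd and
adjusts the 16 p-values of one network × model comparison with
Benjamini–Hochberg FDR (flag at adjusted p < 0.05). Whole-census fit uses
Σ(O−E)²/E over all 16 classes without pooling small expectations —
pooling is deliberately avoided because the reported statistic (71.3 for
community B) is reproduced exactly without it. Monte-Carlo p-values
(default 2000 simulations, add-one estimator, never exactly 0) draw
multinomial censuses at the observed total with probabilities E/ΣE; the
statistic is computed against E rescaled to the observed total so
simulated and observed statistics are comparable even when ΣE ≠ ΣO.
Cross-community comparison is Pearson's chi-squared on the communities ×
16 table with fixed-margin Monte-Carlo resampling (`scipy.stats.random_table`);
all-zero columns are dropped with a note. Per-class comparisons test each
class's counts against expectations proportional to community census
totals — with equal-size communities this reduces to the equal-expected
statistic; for the study's 816/680/680 totals the rare 3-cycle class gives
4.4 rather than the printed 4, a difference attributable to that
convention choice.

## Orbits, signatures, and diversity

The 13 connected triad classes contain 30 automorphism orbits
(multiplicities 2,2,3,3,3,3,1,2,2,2,3,3,1 for classes 4..16). Orbits are
derived at import by automorphism analysis of each class representative
and keyed by (class, within-triad out-degree, within-triad in-degree);
the build asserts this key is unique, which holds for directed triads.
A node's signature counts its appearances in each orbit over all connected
triads containing it. Heatmap/clustering use square-root-transformed
proportions (the transform the study displays); a flag switches to raw
proportions. Clustering distance is 1 − Pearson correlation with average
linkage — a standard pairing for correlation distances; linkage is
configurable. Nodes in no connected triad (or with zero-variance vectors,
for which correlation is undefined) are excluded from the tree and
reported. Diversity is Shannon H′ = −Σ p ln p of a node's orbit
proportions (natural log; base configurable; H′ = 0 for non-participating
nodes), compared among communities with a one-way fixed-effects ANOVA
treating isolates as independent replicates.

## Synthetic data

The generator reproduces the structure the analysis assumes: communities
of 17–18 isolates at densities ≈ 0.26–0.33; out-degree models `bimodal`
(default p_super = 0.2 with high range 12–16 and low range 0–4 —
"super-killers" plus many weak inhibitors), `even`, and `unimodal`;
optional `mutual_excess` reciprocity bias (default 0, independent edges);
`plant_triads` overwrites disjoint triples to realize chosen classes for
power experiments; `simulate_zone_table` emits replicated perpendicular
zone measurements with truncated-normal noise (edges ~N(8, 1) mm,
non-edges ~N(0, 1) mm, truncated at 0 — the simplest non-negative error
model). `simulate_from_degrees` realizes exact in/out-degree sequences by
a Havel–Hakimi-style construction followed by degree-preserving edge
swaps; this is exact on degrees and does not stall on dense sequences the
way configuration-with-rejection can.

The fixture emulates degree structure, density, and reciprocity — not the
phylogenetic correlations, spatial structure, or assay-specific error of
real communities. Tests passing on it show the *machinery* is correct and
that the pipeline detects planted structure at realistic sizes; they do
not certify the biological conclusions for any particular real community.

## Problem sizes and numerical choices

Bundled drivers and tests use reduced ensembles (typically 300–2,000
networks, 2,000 Monte-Carlo simulations) chosen so the whole suite runs in
minutes on one core; every output records its n. The planted-motif power
experiment uses sparse 15-isolate communities (10 background edges) with 5
planted 3-cycles against 300-network degree ensembles — an effect size at
which detection power exceeds 90%; denser backgrounds make planted
3-cycles statistically invisible at these sample sizes, which is a
property of the test, not a bug. Ties in clustering are broken
deterministically by input order; all generators take explicit
`numpy.random.Generator` streams.

## Known limitations

* The study's raw interaction matrices (supplementary spreadsheet) are not
  redistributable here; matrix-level results are demonstrated on the
  synthetic fixture, while table-level statistics (chi-squared, ER
  baselines, small-world ratios) are recomputed from the embedded
  published summaries.
* The printed λ values cannot be reproduced from the printed tables (see
  above).
* Degree-conditioned sampling relies on swap mixing; 1000 attempts matches
  the study's protocol but is not a certified uniform sampler — a flag
  allows more swaps for mixing-sensitivity checks.
* Weighted (zone-size) networks, tetrad motifs, and centrality analyses
  are out of scope.
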