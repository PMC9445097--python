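# Methods

## The model

A skull is represented as a finite simple graph: one node per bone, or per
fused unit when elements are joined without visible sutures; one edge per
direct bony contact.  Edges are unweighted and undirected — the model keeps
*which* bones touch, not how large or mobile the joint is.  Joints bridged
only by soft tissue carry no edge; the reader trusts the 0/1 matrix it is
given and performs no image-based inference.  An unpaired midline bone is
represented, by convention, as two sagittal halves joined by an edge
(`split_midline_bone`); which of the bone's neighbors attach to the left
half, the right half, or both is an anatomical judgment, so the operation
takes the assignment explicitly instead of guessing.

Adjacency CSVs may populate one triangle only (it is mirrored) but two
populated triangles that disagree are rejected: conflicting entries are
data-entry faults and must fail loudly rather than be OR-ed away.

## Per-network parameters

N, K, and D = 2K/N(N−1) are exact counts.  Two parameters carry numeric
conventions that published values in this literature silently depend on,
so both are exposed as options:

- **C** (mean local clustering): a node of degree < 2 has no neighbor
  pairs.  `low_degree_rule="exclude"` (default) drops such nodes from the
  mean — the behavior of igraph's local transitivity with NaN removal,
  which the R workflows this analysis descends from use.  `"zero"` counts
  them as 0 instead.
- **H** (degree heterogeneity, sd/mean): `sd_rule="sample"` (default,
  n−1 denominator, R's `sd`) or `"population"`.

L is the mean breadth-first distance over all unordered pairs and is only
defined for connected graphs.  A disconnected network raises an error that
names the components; there is no largest-component fallback, because every
real skull is connected and a silent fallback would corrupt cross-specimen
comparison.

## Module detection

1. **GTOM.** Topological overlap of order m (default m = 1):
   t_ij = (|shared neighbors| + a_ij) / (min(k_i, k_j) + 1 − a_ij), with
   unit diagonal.  For m > 1 the same formula is applied to the m-step
   reachability graph.  The clustering dissimilarity is 1 − t, the standard
   transform in the topological-overlap literature.
2. **Ward.D2.** Implemented via the Lance–Williams recurrence on *squared*
   distances with heights reported on the distance scale (the `hclust`
   ward.D2 convention).  Ties are broken toward the cluster pair whose
   smallest member labels sort first, which makes merge order — and hence
   partitions — bit-reproducible across platforms.  The scipy `ward`
   linkage serves as an independent cross-check in the test suite, not as
   the implementation, precisely because its tie behavior is unspecified.
3. **Q cut.** Every cut k = 1..N of the dendrogram is scored with
   Newman–Girvan modularity; the maximizing cut gives Q-modules and Q_max,
   ties going to fewer modules.  Searching cuts by k rather than by height
   is equivalent for strictly increasing heights and remains well defined
   under ties.  The dendrogram restricts the partition search space, so
   Q_max is a lower bound on the global maximum over all partitions; the
   tests verify that inequality by Bell-number enumeration at small N.
4. **S-modules.** Per module, the per-node internal contact counts are
   compared with the external counts by a Wilcoxon rank-sum test, one-sided
   (internal > external) by default since that inequality is what *defines*
   a well-formed anatomical module; two-sided is available.  Modules of
   size < 2 cannot be tested and are recorded as not significant with a
   warning.  α defaults to 0.05.

## Comparative statistics

- **Mann–Whitney U**: midranks for ties; exact p by enumeration of all
  C(n_a+n_b, n_a) rank assignments when both samples have ≤ 10 observations
  and no ties, otherwise a tie-corrected normal approximation.  The z
  statistic carries no continuity correction by default (exposed as an
  option) and is reported unsigned alongside p, the form in which such
  tables are usually printed.
- **PCA** standardizes to unit variance by default (correlation PCA): the
  nine parameters mix counts (N, K) with ratios (D, C, H), so covariance
  PCA would be dominated by K.  Axis signs are fixed by a declared
  convention — D loads positively on axis 1 and K on axis 2, matching the
  interpretation that positive PC1 means denser, more integrated skulls and
  positive PC2 means more contacts — so scores are reproducible across
  runs and platforms with no arbitrary sign flips.
- **pPCA** builds the Brownian-motion tip covariance Σ from shared
  root-to-ancestor path lengths, estimates the phylogenetic mean
  a = (1ᵀΣ⁻¹1)⁻¹1ᵀΣ⁻¹X, eigen-decomposes the evolutionary covariance
  P = (X−1aᵀ)ᵀΣ⁻¹(X−1aᵀ)/(n−1) — of its correlation rescaling when
  standardizing, mirroring the ordinary-PCA choice — and projects the
  phylogenetically centered data.  On a star tree with equal branch
  lengths Σ ∝ I and pPCA provably reduces to ordinary PCA; the tests
  assert this numerically.  Taxon names are matched between table and tree
  after case-folding, trimming, and treating underscores as spaces;
  mismatches are errors naming the missing taxa.
- **FDA** uses optimal scoring with a linear basis: class-indicator scores
  are regressed on the features and updated by eigen-decomposition of the
  projected indicator cross-product (the trivial constant score deflated
  explicitly), which with a linear basis is equivalent to linear
  discriminant analysis.  Observations are classified by Gaussian
  discriminant in the variate space (pooled-within sphering, log
  class-frequency priors); the reported error is the training
  (resubstitution) rate, the convention for such published error rates.
  Collinear features fall back to a pseudo-inverse with a warning.
  MARS/polynomial bases are out of scope.

## Synthetic data

`simulate_skull` generates the structure the pipeline consumes, not lizard
anatomy: a left side with planted modules (within-module edge probability
0.8, between 0.05 by default), mirrored exactly to the right, midline
halves joined, sparse symmetric cross-midline contacts (0.02), optional
fusion of bone pairs into single units, and deterministic symmetric bridge
edges if the draw is disconnected.  Defaults (14 bone pairs + 2 midline
bones = 32 nodes, 2 modules per side) give four planted modules of 8 nodes
— large enough that module recovery is statistically meaningful, small
enough that a 100-replicate recovery experiment runs in seconds.  The
planted partition is returned as ground truth.

`simulate_clade` grows a pure-birth (Yule) tree (default 32 tips, rate 1),
keeps the root stem so even a two-tip cherry has nonzero shared ancestry,
evolves each parameter by independent Brownian motion from realistic root
states (e.g. N ≈ 44, D ≈ 0.11, C ≈ 0.40 — typical of published lepidosaur
skull networks), and assigns categorical traits either to one monophyletic
clade (the realistic, phylogenetically confounded case) or i.i.d.  One
global seed expands into per-component substreams (tree, Brownian traits,
categorical traits) so components can be regenerated independently; all
outputs are byte-identical under a fixed seed.

What the simulations do **not** emulate: realistic bone counts per clade,
ossification sequences, correlated trait evolution, measurement error in
contact coding, or any dependence of network topology on the tree.  Tests
passing on synthetic data therefore validate the *machinery* (formulas,
clustering, ordination, classification), not biological conclusions about
real skulls.

## Numerical choices and degenerate inputs

- Q-cut ties: smaller k wins (tolerance 1e−12).
- Rank-sum variance of zero (all values tied): z = 0, p = 1.
- Eigenvalues clipped at 0 before variance fractions (guards tiny negative
  round-off); eigenvectors ordered by descending eigenvalue.
- The pipeline drops zero-variance parameter columns before standardized
  ordinations (with a logged warning) — a batch of same-size synthetic
  skulls otherwise has a degenerate N column — but keeps the full table in
  `parameters.csv`.
- Pipeline outputs embed the package version, the full effective
  configuration, and SHA-256 checksums of every input, so a run report
  fully determines its outputs.

## Published-value arbitration

For users holding the original studies' supplementary files,
`skullnet.reference.sweep_conventions` recomputes per-species C and H and
the pooled PCA scores under all 8 combinations of the exposed conventions
and reports each combination's nearest value and discrepancy against the
published per-species numbers, flagging the combination (if any) that
matches to 4 significant figures.  Those input files are not bundled;
without them the harness raises a specific error describing the expected
directory layout, and the package's validation rests on the oracle-backed
property suites and the hand-verified fixture.

## Problem sizes

The test suite and acceptance script run at desk scale by design: exhaustive
checks over all connected graphs on ≤ 7 nodes, 500 random graphs up to 30
nodes, 100-replicate recovery experiments on 32-node networks, and a
24-specimen synthetic study — sizes at which brute-force oracles
(Floyd–Warshall, Bell-number partition enumeration, exact rank-sum
enumeration) are feasible and every comparison can be made to 1e−12.
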