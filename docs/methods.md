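# Methods

## Filtration model

All persistence quantities are computed exactly from the minimum
spanning tree, never from a sampled λ grid.  The filtration convention
is *closed*: an edge is present at λ iff d_ij ≤ λ, making β₀
right-continuous and every breakpoint attainable.  Kruskal's algorithm
with union-find (path halving + union by rank) yields the MST; ties are
broken by sorting edges on (weight, smaller index, larger index).  Under
tied distances the MST edge *set* is not unique, but everything exposed
as a result — total weight, β₀ curve, barcode, single-linkage
ultrametric — is tie-invariant, and only those are exposed.

The SIP AUC integrates β₀ over [0, 1].  The upper limit is fixed at 1
(the ceiling of the 1 − |r| dissimilarity) rather than the largest
observed distance, so the statistic is comparable across networks of
equal size: a network still fragmented near λ = 1 is charged for it.
The identity SIP AUC = 1 + Σ MST weights is asserted at build time with
tolerance 1e−9.

Anticorrelation: the dissimilarity takes |r|, so strong negative
coupling counts as proximity.  A signed variant (1 − r, range [0, 2])
exists for sensitivity analyses but is off by default.  Note d is not
guaranteed metric (the triangle inequality can fail); no downstream
step assumes it — CPL/ND re-derive shortest paths on the filtered
graph, and the single-linkage ultrametric is computed from the merge
sequence, not from d directly.

## Graph metrics

Edge filtering is deliberately explicit because "the filtered network"
is underdetermined: the default rule keeps pairs with d ≤ 0.5, a
density rule (strongest k% of pairs) is available, and the rule used is
recorded in every output row.  Path metrics use d as edge length;
eigenvector centrality uses similarity 1 − d, since centrality presumes
larger = stronger.  Disconnected pairs are excluded from CPL/ND and
counted (the count is itself diagnostic); they are never imputed with a
ceiling value, which would make the metrics discontinuous in the
threshold.  With no connected pair the metric is undefined (reported as
such, not 0).  EC is computed by shifted power iteration on the largest
component (warning when the graph is disconnected), sign-fixed to the
nonnegative Perron vector, normalised to unit maximum, and checked
against the eigen-equation with residual ≤ 1e−8.  Edge lengths are
floored at 1e−12 so a numerically perfect correlation cannot create a
zero-length edge.

## Permutation inference

Network statistics are group-level functionals (a correlation matrix
needs many subjects), so the exchangeable unit is the subject label:
both groups are pooled, labels reshuffled preserving group sizes, and
the statistic recomputed from the correlation step onward per shuffle.
Tests are two-sided on the absolute difference with add-one smoothing,
p = (1 + #{|null| ≥ |obs|}) / (1 + N); p is never exactly 0.  The
default N = 10,000 matches the design this pipeline emulates; the
analysis drivers and tests use desk-scale N (500–1000), which the exact
binomial calibration check shows is already well calibrated at
α = 0.05.  The fixed significance threshold 0.001 is applied as-is, with
no additional multiplicity correction, matching the emulated design;
per-row seeds are derived from the master seed and the row identity
(pathway, statistic, pair) so result tables are bit-reproducible and
independent of iteration order.

EC is reduced to its node mean for testing.  For cohort-level
contrasts, the registered statistic `sip_auc_pathway_mean` averages the
per-pathway SIP AUC over a pathway list; because the pathway blocks are
nearly independent, this shrinks the statistic's sampling noise by
about √7 and is what makes group contrasts detectable at n ≈ 20 — the
whole-69-ROI-network SIP AUC, by contrast, is dominated by the many
weak cross-pathway edges and has essentially no power at these sizes.

## Synthetic cohort generator

The generator emulates the study design at the ROI-value level (no
image simulation): four groups of sizes 16/18/16/23, 69 ROIs in seven
pathway blocks mirroring the default atlas.  Each group is multivariate
normal with unit variances, correlation `within` inside a block and
`between` (default 0.1) across blocks — the minimal distribution fixing
the second moments that the Pearson analysis consumes — plus i.i.d.
Gaussian noise (default SD 0.5), which attenuates all correlations by
1/(1 + noise_sd²).  Group differences are encoded solely through the
within-pathway strength (HC 0.70, SCD 0.60, AD 0.45, MCI 0.35): disease
severity = weaker metabolic coupling = larger aggregation cost.  Means
are equal across groups, so nothing can be detected from uptake levels,
only from connectivity.  Per-group random streams are keyed by the CRC32
of the group name under the master seed, so adding a group never
perturbs existing draws.

What the generator does *not* emulate: spatial autocorrelation and
partial-volume coupling between neighbouring ROIs, ROI sharing between
pathways (synthetic blocks are disjoint; real pathways overlap, e.g.
the amygdala), non-Gaussian uptake distributions, and site/scanner
effects.  Passing tests therefore demonstrate the correctness and
calibration of the machinery under a clean second-moment model, not the
clinical effect sizes of real cohorts.

## Known limitation: strict severity ordering is noisy at n ≈ 20

With the default gradient and group sizes, the *expected* cohort-level
SIP AUC is cleanly ordered MCI > AD > SCD > HC (the generator-recovery
test verifies this on averaged cohorts).  The strict four-way ordering
within a single cohort, however, recurs in only ~60–70% of replicates
(computed by `analysis/04_severity_ordering.py` and the acceptance
script).  The limiting pair is SCD (n=16, within 0.60) vs HC (n=23,
within 0.70): MST edges are minima over noisy sample correlations, so
smaller samples bias the aggregation cost downward, and the larger HC
group's weaker bias partially offsets its stronger coupling — the
expected gap (~0.24) is comparable to the replicate SD (~0.32).  This
is an intrinsic small-sample property of the statistic, not an
implementation artifact; pairwise contrasts with larger coupling gaps
(MCI vs AD, AD vs SCD, MCI vs HC) order correctly in ≥90% of cohorts.

## Numerical and interface choices

* Correlation matrices are symmetrised, clipped to [−1, 1], and given
  exact unit diagonals; zero-variance ROIs are a named error, never a
  silent NaN.
* Subject tables are plain delimited text (delimiter sniffed from the
  extension); missing or non-numeric cells error with their location.
  Tables with fewer than 3 rows are rejected — the usual symptom of a
  transposed file.
* The default pathway atlas uses descriptive bilateral region names
  (left before right, fixing dendrogram leaf order); its granularity
  for composite entries is an editorial default meant to be replaced by
  a user parcellation for real data.
* Dendrograms export as Newick with merge heights as node heights, so
  leaf-to-leaf path length equals twice the single-linkage distance.
* CLI runs save their effective config; `simulate → analyze → compare`
  from a saved config is byte-deterministic, verified by SHA-256
  manifests.
* Problem sizes in the test suite and acceptance script (100 replicate
  cohorts; 200 null cohorts × 1000 permutations; desk-scale permutation
  counts in drivers) are chosen to give stable Monte-Carlo estimates on
  a single CPU in a few minutes.
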