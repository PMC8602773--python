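# Methods

## Model and assumptions

The pipeline assumes (i) cells of the same type or stage are more similar
to each other than to cells of other stages, and (ii) development is
linear and directional. Pseudotime inference is cast as an open
Hamiltonian-path problem: each node is a cell (or a cluster centroid), the
directed edge weight from node *i* to node *j* is the Kullback–Leibler
divergence between their expression profiles, and the goal is the
minimum-cost path visiting every node once. Because KL is asymmetric, the
two directions of an edge differ, which gives the path a weak directional
preference consistent with differentiation being effectively irreversible.
The linear assumption is softened by the consensus step: many path
solutions at different clustering granularities are merged, and branching
shows up in the transition-matrix embedding rather than in the
one-dimensional score itself.

### Distances

- **Spearman distance** (clustering): `D = (1 − ρ_s)/2` over per-cell
  rank vectors with average-rank tie handling, so identical cells have
  distance 0 and perfectly anti-ranked cells distance 1. A config switch
  `as_printed` gives the similarity-like variant `(ρ_s + 1)/2`. Cells with
  zero rank variance get neutral correlations (0) with a warning.
- **Double centering**: `B = −½ J D∘D J` (classical MDS operator) on the
  element-squared distances; cells are clustered on rows of `B` by
  average-linkage hierarchical clustering (options: complete, ward). The
  linkage tree is computed once and cut at every k.
- **KL cost**: raw nonnegative profiles are shifted by a pseudocount
  (default 1e−6), normalized to the simplex, and compared with
  `Σ p ln(p/q)` in nats. The log base is irrelevant to path orderings
  (positive rescaling); the pseudocount only matters for profiles with
  exact zeros and is a single documented knob.

### Path heuristic

The open-path variant of arbitrary insertion, adapted to asymmetric costs:

- **Seeding**: each restart starts the path with a directed pair (a, b)
  sampled among the 10 largest off-diagonal costs. Far-apart nodes are
  likely endpoints of a good open path, so spending the two free endpoints
  on them early helps.
- **Insertion**: remaining nodes are visited in a seeded random order and
  inserted at the position minimizing the directed cost delta
  `d(u,v) + d(v,w) − d(u,w)` for interior slots, or `d(v, head)` /
  `d(tail, v)` at the two open ends. No symmetrization anywhere.
- **Restarts**: 10 by default; best total cost wins, ties broken
  lexicographically so results are reproducible per seed.

On 200 random planar Euclidean instances with n = 7 the heuristic attains
the exhaustive optimum in ~97% of cases and never beats it (it cannot);
the factorial solver in `hampath.brute_force_path` (guarded at n ≤ 9) is
kept as a permanent oracle.

### Consensus

Per-k paths are projected to per-cell scores (cluster rank along the path,
min-max scaled; cluster mates share a score). The k = 3..7 vectors form
the reference: all 2⁵ orientation assignments are enumerated and scored by
the summed C(5,2) pairwise Spearman correlations (reflection `s → 1−s`
negates Spearman, so the search reduces to sign products of precomputed
correlations, but the full 32-assignment enumeration is kept and counted
for verifiability). The k = 7..N vectors are then folded in one at a time:
each is reflected if that raises its Spearman correlation with the running
mean, then averaged in with equal weight per contribution (the reference
enters with weight 5). k = 7 deliberately contributes once to the
reference and once to the merge stream. The final vector is min-max
scaled; its global direction is arbitrary unless stage labels or a root
cell are supplied, in which case the root/first stage is anchored at low
pseudotime and the choice is recorded in `direction_anchor`.

### Transition matrix and embedding

Each consecutive node pair of each path adds unit transition mass; for
cluster-level paths the unit is split uniformly over all member-cell pairs
of the adjacent clusters, so total mass is `Σ (len(path) − 1)` regardless
of cluster sizes. The embedding is PCA on rows of the symmetrized
`T + Tᵀ` (flags for directed and row-normalized variants), with component
signs fixed by the largest-magnitude loading. Note that PCA of a *sharp*
band matrix (a single repeated cell-level chain) has an alternating
leading mode — a smooth, order-tracking PC1 requires the multi-width band
that the consensus over many k produces; the tests assert rank agreement
on that realistic input and arm separation on branched fixtures.

## Gene dynamics

- **dCor**: Szekely's sample distance correlation via double-centered
  absolute-difference matrices; constant vectors return 0 with a warning.
  Cross-checked in tests against an independent raw-moment
  (S1 + S2 − 2S3) implementation to 1e−10.
- **MIC**: equal-frequency grid estimator. For every grid shape
  (kx, ky) with `kx · ky ≤ n^0.6` (axis cap 15), both axes are partitioned
  into equal-frequency bins and the normalized mutual information
  `I/log min(kx, ky)` is maximized over shapes. This estimator is exact
  (MIC = 1) for noiseless monotone relationships, stays ≈ 0.05 on
  independent data at n = 200, and is monotone-transform invariant. It
  searches grid *shapes* with equal-mass partitions rather than optimizing
  irregular partitions; heavily non-functional patterns (e.g. a circle)
  score lower than a partition-optimizing estimator would.
- **Selection**: genes ranked by max(dCor, MIC), kept at ≥ 0.5 by default
  (a `both` rule and the threshold itself are configurable — analyses of
  coupled processes typically use a stricter 0.65).
- **HMM segmentation**: univariate Gaussian HMM with 2 (optionally 3)
  states. Emissions are initialized from the sorted expression values
  split into equal blocks (block mean/sd, sd floored at 1e−3);
  Baum–Welch (hmmlearn) re-estimates start and transition probabilities
  only by default (`update_emissions` turns on full re-estimation), and
  the log-likelihood history is checked for monotonicity after every fit.
  Viterbi returns the MAP path; states are relabeled mean-ascending so
  state 0 is always "off". Constant genes short-circuit to a flagged
  degenerate single-state track. Decoding is verified in tests against
  exhaustive 2^L MAP enumeration for L ≤ 12.
- **Modules**: binary state tracks clustered by Hamming distance with
  average linkage; leaf order plus a flat cut (height 0.5 by default, or a
  requested module count) are exported for heatmaps. Three-state tracks
  collapse the top two states for this step.

## G0 detection and coupling

The six phase scores are per-cell means over user-supplied phase gene
lists (e.g. Cyclebase-derived; no annotation is bundled). k-means with
k = 5 (G0, G1, S, G2, M) partitions cells on the score table; the cluster
with the lowest grand mean is the candidate, and it is reported as G0 only
if a one-sided Welch test (candidate lower) reaches P < 0.001 for **all**
6 × (k−1) (score, other-cluster) pairs. No multiple-testing correction is
applied — the criterion is deliberately conjunctive and raw, which makes
it conservative. A `classic_anova` switch substitutes the two-sided
two-group one-way ANOVA, and `pooled` compares against all remaining cells
at once. Coupling coordinates place a cyclic pseudotime (supplied
externally, e.g. from a cell-cycle ordering tool) on the unit circle and
the differentiation pseudotime on z.

## Evaluation metrics

With `ns` ordered stages over `N` cells and `s` adjacent stage changes
along the ordering: `CI = 1 − (s − ns + 1)/(N − ns)`, which is exactly 1
for stage-contiguous orderings and 0 at maximal alternation (an
`as_printed` flag retains a variant whose scale is shifted by
`2/(N − ns)`). `BI = 1 − s/S` where `s` counts cross-stage inversions and
`S` all cross-stage pairs; `POS = 2·BI − 1` identically. KC is Kendall
tau-b; note that ties in the stage labels cap |tau-b| strictly below 1
(e.g. 0.819 for 150 cells in three balanced stages), so KC values should
be read against that ceiling. All metrics report the better of the
ordering and its reverse by default because the consensus direction is
arbitrary; signed variants are available.

## Synthetic fixtures

`simulate_linear` (defaults: 150 cells, 3 stages, 300 genes, 30%
monotone + 30% switch genes, noise sd 0.5, dropout 0.2) emulates a
log-scale, feature-selected matrix for a linear lineage: latent pseudotime
uniform on [0, 1], stages as equal quantile bins, monotone genes
`a·t + b` with |a| ∈ [2, 6], switch genes as sharp sigmoids at stage
boundaries, additive Gaussian noise, and thresholded dropout (values
below 2.0 zeroed with probability 0.2), clipped at 0. `simulate_branch`
adds a post-branch binary fate split with disjoint arm-marker genes.
`simulate_cycle_scores` draws quiescent cells low on all six phase scores
and gives cycling cells a round-robin phase identity with a +2 boost in
their own phase columns — without that phase structure the cycling
population is one homogeneous blob, k-means at k = 5 fragments it, and the
per-cluster significance criterion (correctly) refuses to call G0.

What the fixtures do **not** emulate: count-level noise (negative
binomial), library-size variation, batch effects, doublets, or realistic
gene–gene correlation beyond the shared latent time. Passing tests
demonstrate that the algorithms recover structure they assume, not
performance on arbitrary real data.

Because the fixtures are generated on a log₂-like scale where
variance/mean sits in ≈ 1–5, end-to-end fixture runs skip the dispersion
filter (`skip_dispersion=True`): the fixture stands in for the
*post-selection* matrix. The default cutoff of 10 is calibrated to
TPM/FPKM-scale real data, where it retains a few hundred genes.

## Problem sizes and numerical choices

The standard end-to-end runs use 150 cells × 300 genes with the full
k = 3..N sweep (148 clusterings and path solves, ~1.5 s each run); a
`k_stride` knob thins the merge stream for larger N. Path-cost ties break
lexicographically; PCA signs are fixed by the leading loading; dispersion
of zero-mean genes is 0 (always filtered); KL entries are clipped at 0 to
absorb rounding; min-max scaling of a constant vector returns zeros rather
than dividing by zero. Duplicate gene columns keep the highest-mean copy
with a warning; duplicate cell ids are an error.

## Known limitations

- The insertion heuristic is O(n²) per restart and approximate; it is not
  an exact TSP solver and offers no optimality guarantee beyond the
  regression-tested agreement rate on small instances.
- A single pseudotime cannot represent branches; branch detection is
  visual/embedding-based (silhouette-quantified in tests), with no
  automatic branch assignment.
- dCor/MIC cannot distinguish positive from negative association; the HMM
  states recover direction per gene instead.
- G0 detection assumes the quiescent population is a *cluster-scale*
  group; a handful of scattered quiescent cells will not be called.
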