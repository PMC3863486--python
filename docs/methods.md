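# Methods

## Problem and scope

The package asks a model-selection question about structural brain
networks: given a subject's binarized connectome, which of seven
random-graph wiring rules produces networks most similar to it? The
similarity is judged on two levels — global summary statistics and local
graphlet composition — and aggregated over cohorts of subjects. The
package covers everything from the connectivity matrix onward; image
acquisition, tractography, and ROI discovery are out of scope, and ROIs
are treated as given node indices `0..N-1`.

## Network construction

A connectivity matrix is a symmetric non-negative integer matrix of
fiber counts with a zero diagonal. A single global threshold `T`
binarizes it: edge `{i, j}` exists iff `count[i, j] > T`. Conventions:

- **Strict inequality.** "Stronger than the noise threshold" reads most
  naturally as `>`; a `strict=False` flag gives `>=`.
- **Isolated nodes stay.** The node set is fixed by the ROI atlas before
  thresholding, so `N` equals the matrix dimension regardless of how many
  nodes lose all edges.
- **One `T` for all subjects** of a study, enforced at the pipeline
  level. The default `T = 40` was chosen once so that the synthetic
  generator's default profile yields a median network density of about
  0.05 (at both N=100 and N=358); it is a property of the default
  synthetic profile, not a biological constant, and is fully exposed in
  the study configuration.

Thresholding is monotone (raising `T` only removes edges), which the
property suite asserts.

## The seven null models

Every generator is calibrated to the input graph and returns a simple
graph on the same node count. Calibration anchors:

| model  | matches exactly            | matches in expectation |
|--------|----------------------------|------------------------|
| ER     | node and edge count        | —                      |
| ER-DD  | full degree sequence       | —                      |
| GEO    | edge count                 | —                      |
| GEO-GD | edge count                 | —                      |
| SF     | edge count given its attachment granularity m | — |
| SF-GD  | —                          | edge count (±5%)       |
| STICKY | —                          | degree sequence        |

- **ER** is `G(N, m)` with a fixed edge count, not `G(N, p)`: every
  instance then has exactly the input's density, which keeps per-instance
  metric comparisons meaningful.
- **ER-DD** uses stub matching: stubs proportional to target degrees are
  paired uniformly, rejecting self-loops and duplicates; residual
  deadlocks are resolved by degree-preserving edge-swap repairs rather
  than full restarts, so the degree sequence is always matched exactly.
- **GEO** places `N` uniform points in `[0,1]^3` (dimension is a
  parameter; 3 is the default) and connects the `m` closest pairs. This
  "rank cutoff" equals thresholding the distance at the `m`-th smallest
  pairwise distance with ties broken by distance rank, and makes the edge
  count exact rather than approximate.
- **GEO-GD** grows the point set by duplication: a uniform seed of 5
  points, then each new point copies a uniformly chosen existing point
  plus a uniform per-coordinate offset in `[-ε, ε]`, wrapped into the
  unit cube (torus). Wrapping keeps the metric space compact and gives a
  clean limiting law — as ε grows the process converges to the uniform
  point process, so GEO-GD degenerates to GEO (a tested limit). The
  published duplication-geometry family has several variants; this
  parent-proximity placement with a post-hoc distance cutoff is the
  implemented one.
- **SF** is Barabási–Albert growth from a seed clique on `m+1` nodes
  with `m = round(|E|/N)` edges per new node, sampled
  degree-proportionally without multi-edges. Inputs with `m < 1` (mean
  degree below 2) cannot be modeled and raise an error, which the
  pipeline records as a missing model rather than aborting.
- **SF-GD** is duplication–divergence: duplicate a uniform node `u` into
  `v` (inheriting all neighbors), add `{u, v}` with probability
  `p_link`, then for each common neighbor delete one of the two parallel
  edges with probability `q_delete`. The free parameters are calibrated
  by coarse grid search over `(p_link, q_delete)` followed by secant
  iterations on `q_delete` (the mean edge count is steep and monotone
  decreasing in it), accepting when the mean instance edge count over
  ~1200 replicates is within 2.5% of the target — comfortably inside the
  5% contract the tests check. The per-instance edge count of this
  process is highly dispersed (SD ≈ half the mean); that is a property
  of the model, not of the calibration.
- **STICKY** assigns `θ_i = d_i/√(Σ d_k)` from the input degrees and
  includes each pair independently with probability
  `min(θ_i θ_j, 1)`. Clipped pairs are counted and logged; without
  clipping the expected degree of node `i` is `d_i (1 − d_i/Σd) ≈ d_i`.

Repeated instances derive their seeds from a single spawned
`SeedSequence`, so a model spec reproduces its instance list exactly.

## Global metrics

- Degree distributions are empirical `P(k)` vectors; for the Pearson
  correlation two vectors are aligned on the union degree range with
  zero padding (unequal degree supports have no canonical alignment;
  zero padding is this package's documented choice). Zero-variance vectors make the
  correlation undefined and are reported as missing.
- Characteristic path length averages shortest paths over **connected
  pairs only** (a largest-component variant is available); global
  efficiency instead counts disconnected pairs as zero, which keeps it
  meaningful on fragmented graphs. Both use unweighted BFS distances via
  `scipy.sparse.csgraph`.
- Clustering uses `C_i = 2E_neighbor,i/(k_i(k_i−1))` with `C_i = 0` for
  degree < 2 (the formula is undefined there; zero is the common
  convention), averaged over **all** nodes.
- PathDiff and ClustDiff are percentages normalized by the real
  network's value; they are deliberately asymmetric in their arguments.
- Small-worldness σ uses an ER `G(N, m)` reference ensemble
  (20 instances by default); the reference ensemble is a documented
  convention; other ensembles (e.g. degree-preserving) are equally
  defensible.

## Graphlet machinery

The catalog enumerates every labeled simple graph on 2–5 nodes,
keeps the connected ones, and canonicalizes by the minimum edge-bitmask
over all node permutations: 30 graphlets. Automorphism orbits come from
brute-force permutation testing: 73 orbits. The ordering is
deterministic — graphlets sorted by (size, edge count, canonical
bitmask), orbits by smallest canonical node — which places the single
edge first, so orbit 0 is the edge endpoint and every node's orbit-0
touch count equals its degree.

Counting is exact, not sampled: an ESU-style enumeration visits every
connected induced subgraph on ≤5 nodes exactly once (extend a growing
subset by exclusive neighbors with labels above the root) and classifies
it in O(1) through precomputed lookup tables over all labeled graphs on
≤5 nodes (2^10 masks at size 5). The kernel is JIT-compiled with numba;
a pure-Python enumerate-all-subsets oracle in the test suite verifies
exact agreement on hundreds of random graphs.

**RGF distance** uses `F_i(X) = −ln(N_i(X)/T(X))` and sums absolute
differences over all 30 graphlets, edge included — the 29-graphlet
variant of the original formulation is available via
`include_edge=False`. Zero counts are replaced by 1 before
normalization to keep `F_i` finite; natural logarithm throughout (the
base only rescales distances). A graph with no graphlets at all has no
defined distance.

**GDD agreement** builds, per orbit `j`, the distribution `d^j(k)` of
nodes touching the orbit exactly `k ≥ 1` times, scales by `1/k`,
normalizes to total 1, and compares two graphs by
`A^j = 1 − ‖N_G^j − N_H^j‖₂/√2`; the total is the arithmetic mean over
the 73 orbits by default, with the geometric mean available as an
alternative convention. Orbits
empty in both graphs agree perfectly; an orbit empty in exactly one
graph is compared against the zero vector.

## Synthetic connectomes

The generator stands in for non-deposited tractography data. It emulates:
a fixed spatial ROI set (default 358 landmarks, the DICCCOL atlas size)
with spatially coherent modules (default 6); connection probability set
by module co-membership (defaults 0.35 intra / 0.06 inter) damped by
`exp(−2·distance)`; lognormal fiber counts (median 30 fibers);
and cohorts (defaults 28/53/23 subjects for adolescent/adult/elderly)
sharing a group backbone with multiplicative lognormal subject noise
(sd 0.3). Groups differ only by profile seed — no aging effect is
imposed, since the comparison treats cohorts as independent replicates
rather than modeling development. Defaults were fixed once so that the default threshold yields
density ≈ 0.05, ≥ 90% largest component, and clustering above a
density-matched ER graph — the regime the small-world and graphlet
comparisons presuppose — and are not tuned per experiment.

What it does **not** emulate: true hemispheric/lobar geometry,
degree-distribution details of real connectomes, distance-dependent
noise in tractography, group-specific topology changes, or any
weighted-network structure beyond counts. Passing tests therefore
demonstrate that the pipeline is correct and self-consistent on data of
this statistical shape, not that any particular model describes real
brains.

## Pipeline conventions

- Tables report mean ± std **over subjects**, each subject contributing
  its 10-instance mean; sample (n−1) std by default with a population
  option. Undefined values are excluded pairwise and counted.
- Rankings: ascending for distances/difference ratios, descending for
  agreement/correlation; ER-DD is excluded from the Pearson ranking
  (its correlation is 1 by construction); ties break by smaller std,
  then model name; the overall order is by mean per-metric rank.
- Rendered tables use 2 decimal places.
- Whole-model failures (infeasible calibration) are recorded as missing
  and rank last.
- End-to-end runs are deterministic: all seeds derive from the single
  config seed via spawned `SeedSequence`s, and rerunning a config
  produces byte-identical CSV/JSON outputs (wall-clock timing is written
  to a separate file for this reason).

## Problem sizes

Unit and property tests run at N ≈ 15–100 with the synthetic profile's
default densities; the end-to-end study test uses 3 cohorts × 5 subjects
at N = 100 with all 7 models × 10 instances, and generator distribution
checks use up to 30,000 draws (ER uniformity), 10,000 draws (stickiness
pair frequency), and N = 2000 (preferential-attachment tail). These
sizes were chosen as the smallest at which the asserted statistical
properties are stable.

## Known limitations

- Exact counting of all 2–5-node graphlets is O(#connected 5-subsets);
  dense graphs beyond a few thousand nodes call for sampled counting,
  which is deliberately not implemented.
- The duplication-divergence calibration targets the *mean* edge count;
  its instance-level dispersion remains large, and fit metrics that are
  sensitive to density inherit that variance.
- The degree-sequence-conditioned nulls (ER-DD, STICKY) mimic any single
  input graph more closely than an independent redraw from the input's
  own generative family can; rankings on degree-based metrics should be
  interpreted with that in mind.
- GEO-GD implements one variant of the duplication-geometry family;
  other published variants (e.g. probability cutoffs) are out of scope.
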