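# Methods

## Neighborhood graphs

Graphs are built strictly per image (images are independent samples) and
are always symmetric and self-loop-free.

- **Delaunay** — edges of the Delaunay triangulation of the cell
  centroids (equivalently: Voronoi cells sharing a boundary). Requires
  ≥ 3 non-collinear cells. Exact duplicate coordinates are collapsed
  for the triangulation; duplicates then inherit their representative's
  edges and become mutually adjacent.
- **kNN** — union of the directed k-nearest relations (so degrees are
  ≥ k); distance ties are broken by (distance, cell index) lexicographic
  order for reproducibility on gridded coordinates. Default k = 5 where
  a kNN graph is requested.
- **radius** — edge iff 0 < d ≤ r (closed boundary). r is in the same
  unit as the coordinates; the unit itself (px vs µm) is metadata only.

Only 1-hop neighborhoods are scored. Multi-hop neighborhoods appear in
one place — the in-silico annotation heuristic (below) borrows labels
within graph distance 2 — never in the scores.

## Counting and normalization

For one image with K declared cell types (the declared label set may
include types absent from an image):

- `N[i,j]` — ordered-pair edge count. The diagonal counts both
  orientations of each undirected homotypic edge (a literal double sum
  over s ∈ Cᵢ, t ∈ Cⱼ), so `N[i,i]` is always even.
- `M[i,j]` — number of type-i cells with at least one type-j neighbor.
- total normalization `O_total = N / |Cᵢ|`; conditional normalization
  `O_cond = N / M`; conditional cell ratio `CCR = M / |Cᵢ|`.

Missing-value policy: a pair with observed `M = 0` has no conditional
statistic — the score is NaN (not 0, not ±∞) and `CCR = 0` is recorded;
"no interacting index cells" is a different statement from "interaction
at its expected level". Rows for types absent from an image are NaN.

## Permutation engine

Cell-type labels are shuffled uniformly across all cells of the image
while the graph stays fixed; `N` and `M` are recomputed per draw.
Defaults: `n_perm = 300`, population standard deviation (ddof = 0) —
the permutation set is treated as the reference distribution itself.

One seeded permutation stream per image serves every ordered pair and
every score. Consequences:

- the total z-score is computed on raw counts (the constant |Cᵢ|
  denominators cancel algebraically), which makes it *bitwise* symmetric
  in (i,j);
- the conditional z-score shares the identical null draws, so
  directional differences are attributable to the normalization, not to
  Monte-Carlo noise;
- score types are directly comparable within an image.

The conditional statistic recomputes **both** numerator and denominator
per permutation: the null is the null of O, and O depends on M. Draws
with a permuted `M = 0` are excluded from the null moments (at realistic
image sizes they essentially never occur); a null degenerate after that
(σ_perm = 0) yields a NaN score with a `degenerate_null` flag.

Empirical tail probabilities for the categorical sigval use the add-one
estimator `p = (1 + #{perm ≥ obs}) / (n_valid + 1)`, avoiding p = 0 at
finite n. sigval is +1 / −1 when the upper / lower tail is ≤ α
(default α = 0.01, configurable; the threshold behind the ±1 calls is a
convention, and values ≥ 0.5 are accepted but make a two-tailed reading
meaningless). CPscore divides the undirected observed count (homotypic
edges counted once) by the permutation-null mean count; NaN if that mean
is zero.

Size correction (optional, off by default) divides every z-score of an
image by √(cell count of that image) and does nothing else. It is
intended for datasets whose samples differ strongly in cell number,
where z magnitudes otherwise scale with cell count.

Per-image seeds are derived as SHA-256(master_seed ":" image_id) mod
2³¹, so results are independent of image processing order. Cells labeled
with the exclusion token (default `"exclude"`) are dropped before graph
construction.

## In-silico tissue generator

Scaffolds: random circle packing by rejection sampling — radii uniform
in [r_min, r_max] (defaults 10, 10), centers uniform in the field,
accepted when no overlap with accepted circles; packing stops after
10,000 consecutive rejections, i.e. near saturation density. Field
f = 1000 at full scale; the study protocol uses f = 600 (~580 cells) to
keep desk runtimes in minutes. The scaffold graph is the Delaunay/
Voronoi adjacency of the centers.

Annotation toward (p, H), where p is the target abundance vector and
H[i,j] the probability that a neighbor of a type-i cell is type j
(row-stochastic):

1. the field is partitioned into t×t regions (t = 200), traversed
   row-major;
2. one random region is seeded with labels drawn iid from
   Multinomial(p);
3. growth: each unlabeled node takes a label sampled from the H-row of
   its nearest labeled neighbor within graph distance 2 (nearest by hop
   count, ties by lowest index); the grid is shifted by t/2 in x and y
   and the pass repeats, alternating, until all nodes are labeled
   (guaranteed on a connected scaffold);
4. refinement, I = 300 iterations of S = 50 proposals: for a random
   node, its distance-2 neighborhood composition is compared with the
   H-row of its own label; a nearby node of the most over-represented
   type is either relabeled to the most under-represented type or
   label-exchanged with a random node of that type — whichever move,
   if either, reduces the squared error between the image's realized
   adjacency fractions and H. Moves that do not improve are reverted.

The acceptance rule in step 4 is the key design choice. An unconditional
local swap rule is self-defeating: enforcing "composition = H-row" at
every node separately dissolves exactly the clusters that global
adherence to H requires (measured on the strong self-preference preset,
it pushed realized homotypic adjacency *below* random). The hill climb
keeps the described move vocabulary but accepts only improvements, and
converges to realized fractions ≈ H whenever H is feasible. Plain
relabels let abundances drift when H demands it — adjacency adherence
deliberately has priority over exact abundances, so cohorts with
strongly preferential rare types show abundance deviations; at the equal
abundance presets used in the study protocol the drift is ≪ 0.05.

Not every H is feasible: the asymmetric strong cross-preference preset
(H[0,1] = 0.60 vs H[1,0] = 0.29) is over-constrained at equal abundances
(edge-count bookkeeping forces incompatible degree ratios), and the
generator converges to a compromise (realized ≈ 0.49 vs 0.41) that still
carries the directional asymmetry the benchmark detects.

Preset p vectors (type-0 abundance 0.05–0.55, remainder split equally)
and the three-level self-/cross-preference H families (0.25 / 0.45 /
0.60) are shipped as `ABUNDANCE_VECTORS`, `self_preference_matrix`,
`cross_preference_matrix`.

## Hard-core cluster/infiltration generator

Background: candidate points uniform in the field at oversampling × n
(defaults 1.6 × 5000 in 2000 × 2000), greedily thinned in draw order to
enforce a minimum pairwise spacing min_d = 10, truncated to n; a
packing failure (too few survivors) raises with a remedial hint.
Clusters are axis-aligned ellipses (default semi-axes 460 × 320, sized
so the default background density yields ≥ 500 interior cells);
interior background cells are relabeled nearest-center-first up to the
cluster size. Infiltration relabels a uniform random fraction of a
cluster's cells (without replacement) to the infiltrating type.

Three preset scenarios: (I) one purple 500-cell cluster with green
infiltration at proportion p; (II) additionally a green cluster whose
size steps 510, 500, …, 440 as p rises 0 … 0.7, counter-balancing the
growing infiltrate; (III) = II with the colors switched. The printed
size sequence is reproduced verbatim; it compensates the infiltrate only
approximately (total green and purple counts are equal only near p = 0),
which is inherent to the sequence, not to this implementation.

## Cohort-distinction benchmark

Per-image feature vectors hold one NEP score per ordered type pair
(index-type-major column order); non-directional CPscores are copied to
both directions; missing scores are imputed as 0 ("no evidence of
preference") before training. For each of n_repeats = 20 repeats: a
stratified 80/20 train/validation split; a random forest (100 trees)
tuned by 5-fold CV over max_features ∈ {√p, p} on the training split;
F1 on the held-out 20% (the lexicographically larger cohort is the
positive class); impurity-based feature importances from the refit best
model, averaged over repeats. The forest is deliberately modest — the
benchmark measures score quality, not classifier quality, and at 16
features × ~50 samples more trees only add runtime.

Baselines, same protocol: (a) cell-type abundance features only — near
chance when cohorts share abundances, confirming the signal is
architectural; (b) cohort labels shuffled per repeat — F1 ≈ 0.5, the
chance level of a balanced binary problem.

Ground-truth recovery: scaled cosine similarity
(cos θ + 1)/2 ∈ [0, 1] between the mean importance vector and
vec(H_a − H_b) in the same column order. Importances are nonnegative
while the truth difference is signed, so the comparison rewards
importance mass on pairs whose adjacency increased from b to a; order
the comparison (enriched cohort first) accordingly. A zero truth vector
(identical specs) yields NaN with a warning.

## Study protocol and problem sizes

`nepscore.study.run_cohort_study` fixes the validation protocol: three
adjacency levels on shared scaffolds (identical coordinates, cohort-
specific labels), equal 25% abundances, 30 images per cohort, field 600,
300 permutations, COZI + total z. These sizes keep the full suite and
the acceptance script at minutes-scale on one CPU; the simulators accept
f = 1000 and 100 images per cohort for full-scale runs.

## What the simulations do and do not show

The generators control the directed adjacency distribution and
abundances — precisely the quantities the scores estimate — so passing
tests demonstrate calibration (z mean ≈ 0, ~5% |z| > 1.96 under random
labels), power (cohort separation), and directionality recovery under
known ground truth. They do not emulate segmentation errors, label
noise, holes/vessels and tissue-boundary effects, density gradients, or
3-D structure; conclusions about robustness to those belong to real
data, not to these tests.

## Other numerical conventions

- Score tables serialize floats at repr fidelity and are re-read with
  round-trip float parsing, so write → read is bit-stable.
- Monte-Carlo nulls are validated against exhaustive permutation
  enumeration on ≤ 8-cell graphs (≤ 40,320 orderings) within 3 SE.
- Degenerate images (fewer than 3 non-collinear cells, k ≥ n) are
  skipped with a machine-parsable warning (`SKIP_IMAGE`), not fatal;
  invalid global parameters (k = 0, α ∉ (0,1), n_perm < 1) fail fast.

## Known limitations

- The conditional null excludes permuted draws with M = 0 rather than
  modeling them; on very small images with rare types this slightly
  narrows the null.
- The annotation heuristic is a local optimizer: for infeasible H it
  returns a compromise without reporting the residual; inspect realized
  fractions via `adjacency_fractions` when designing new cohorts.
- CPscore inherits the instability of ratio statistics when the null
  mean count is small.
- No 3-D support; coordinates are strictly planar.
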