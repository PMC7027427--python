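# Methods

## The model

`swarmtopo` simulates N self-propelled agents in the plane. Each agent
carries position x_i and velocity v_i obeying

    dx_i/dt = v_i
    dv_i/dt = (alpha - beta |v_i|^2) v_i - grad_i U(x_i)
    U(x_i)  = sum_{j != i} [ C exp(-|x_i - x_j| / ell) - exp(-|x_i - x_j|) ]

in the nondimensional gauge m = C_a = ell_a = 1, which leaves four
dimensionless parameters: self-propulsion strength alpha (default 1.5),
nonlinear drag beta (default 0.5), repulsion amplitude ratio C = C_r/C_a and
repulsion length ratio ell = ell_r/ell_a. An isolated agent relaxes to the
terminal speed sqrt(alpha/beta) (= sqrt(3) at the defaults); the interplay
of propulsion, drag and Morse-type attraction-repulsion produces the
paradigmatic collective phenotypes: single and double mills, double rings,
collective swarms, and three escape variants. The library maps the 5 x 5
grid C, ell in {0.1, 0.5, 0.9, 2, 3} to those seven phenotypes
(`swarmtopo.model.PHENOTYPE_MAP`).

### Numerical integration

The equations are integrated with an adaptive Dormand-Prince 4(5) pair
(the classic ode45 tableau), implemented as a single compiled (numba)
kernel so that the O(N^2) pairwise force loop and the step controller run
without interpreter overhead. Default tolerances are rtol = 1e-3,
atol = 1e-6, the conventional defaults for this pair; both are arguments of
`simulate`. Steps are clipped so that every output time t_j = (j-1) * 0.05
is hit exactly, which substitutes for a dense-output interpolant without
changing the local error control. Initial conditions are drawn uniformly
from [-1, 1]^2 for both position and velocity from a seeded generator;
per-simulation seeds are base_seed + 1000 * combo_index + rep_index so any
single run is reproducible in isolation. The standard protocol integrates
to t = 100 and records M = 2001 frames.

Two numerical regularizations, both far below every analyzed length scale:

* pairs separated by more than 45 * max(1, ell) interaction lengths are
  skipped (their forces are below double-precision resolution);
* the force *direction* (x_i - x_j)/r is softened to
  (x_i - x_j)/sqrt(r^2 + R_SOFT^2) with R_SOFT = 1e-4. In clumping regimes
  (attraction dominating as r -> 0, e.g. collective swarms and collective
  escapes) agents repeatedly cross through near-coincidence, where the exact
  direction is discontinuous; without softening the adaptive controller
  collapses its steps indefinitely there. The softening perturbs the force
  at separation r by a relative (R_SOFT/r)^2 / 2 — about 0.5% at r = 1e-3,
  the smallest nearest-neighbor scale the analyses see — and makes exactly
  coincident pairs exert zero force on each other.

## Order parameters

Four classical scalar summaries per frame: polarization
P = |sum v_i| / sum |v_i|; angular momentum
M_ang = |sum r_i x v_i| / sum |r_i||v_i| about the center of mass; absolute
angular momentum M_abs, the same with the cross products' absolute values
(counter-rotating groups cancel in M_ang but not in M_abs, which is what
separates a double mill from a single mill); and the mean nearest-neighbor
distance D_NN, which diverges for escapes. The planar cross product is the
scalar r_x v_y - r_y v_x. Frames where every agent is at rest make the
normalized parameters undefined; these raise immediately rather than
returning a sentinel, to surface degenerate simulations early.

Series are evaluated on frames j = 23, 46, ..., 2001 (one-based) — the
downsampling factor 23 divides 2001 and yields 87 samples. Order parameters
are always computed on raw trajectories; escape capping (below) applies
only to the topological branch.

## Topological summaries (crockers)

For the topological branch, each agent whose sup-norm distance from the
origin reaches 10 is frozen at its first-crossing position for all later
frames (`cap_escape`), and all positions are then divided by one global
constant — the maximum sup-norm over the whole library — so every cloud
lives in [-1, 1]^2. With escape runs present the constant is the cap (up to
one frame's travel past it, since crossings are detected at sample times).

Three cloud sequences per simulation:

* position: the 2D clouds at the 87 downsampled frames;
* time-delay: 4D points [x_i(t_j), x_i(t_j - 5 dt)] on the same grid with
  the first frame dropped (86 clouds); the lag injects velocity information
  while staying in position units, so no cross-scale normalization is
  needed. (The stated sample range would allow 87 delayed frames; the
  86-frame convention drops the first, matching the published feature
  dimensions. This choice is recorded as a convention, not a derivation.)
* position+velocity: 4D points [x-hat_i, v-hat_i] with velocity scaled by
  its own library-wide maximum speed — the naive alternative the delay
  embedding improves on (it sees only one loop in a double ring).

Vietoris-Rips persistence is computed per cloud under the ball-diameter
convention (an edge enters at a scale equal to the pairwise distance), and
Betti numbers b0, b1 are evaluated on the fixed logarithmic grid
eps_q = 10^(-4 + q * 0.02), q = 1..200 (10^-3.98 through 1.0; the grid
formula's first point is just below 10^-4 times ten to the spacing). A
Betti curve counts diagram points with birth <= eps < death; stacking the
87 (or 86) curves as columns gives the crocker matrix, 200 x 87 = 17400
entries for a position crocker (b0 and b1 concatenated: 34800).

### The persistence engine

No fast persistent-homology backend is assumed; the engine is part of the
package:

* H0 via union-find over the distance-sorted edge list — the merge heights
  are single-linkage dendrogram heights, and b0(eps) = N - #{merges <= eps};
* H1 via persistent cohomology with clearing: only positive (non-tree)
  edges are processed, in decreasing filtration order, as implicit
  coboundary columns. A column whose minimal cofacet is unclaimed pairs
  with it immediately at zero arithmetic cost (the dominant case); colliding
  columns are reduced in a lazy binary min-heap keyed by (triangle
  diameter, colexicographic index), where GF(2) additions are push-only and
  duplicates cancel by parity at pop time. The filtration is truncated at
  min(grid max, enclosing radius): beyond the enclosing radius the complex
  is a cone, hence contractible, so b1 vanishes and every class has already
  died.

Correctness is pinned three independent ways in the test suite: an exact
brute-force GF(2) boundary-matrix oracle on all small random clouds at all
200 grid scales; a structurally different mid-scale route (incremental rank
of the triangle boundary matrix, bucketed by grid bin — rank of a column
set is order-independent, so no triangle sort is needed); and closed-form
configurations (unit square, rings, rigid-motion and relabeling
invariance). Typical 200-point frames cost tens of milliseconds; worst-case
frames (thin double rings in the 4D delay embedding, whose long-lived
cycles force long reduction cascades) stay in the low seconds.

## Machine learning

Feature vectors per simulation: each order-parameter series (87-dim), their
concatenation (348-dim), and vectorized crockers b0, b1 or b0&b1 per
embedding. Two routes:

* unsupervised: PAM k-medoids (greedy BUILD, then best-improvement SWAP to
  a fixed point) under Euclidean distance with k = 25, one cluster per
  generating (C, ell) pair. The algorithm is deterministic; ties break
  toward the lowest index. Accuracy maps each cluster to its majority true
  label (Hungarian one-to-one assignment available as an option) and scores
  the fraction of simulations whose cluster label matches their own.
  BUILD+SWAP is a local search: on unstructured clouds it can stop at a
  swap-local optimum (as does the reference R implementation, which the
  tests cross-check via Rscript); on separated clusters it attains the
  global optimum.
* supervised: one-vs-one linear SVM (C = 1, no feature standardization)
  under stratified 5-fold cross-validation — with equal class sizes each
  fold withholds exactly 20% of every class. Reported accuracy is the mean
  out-of-sample fraction across folds.

Optional PCA reduces features to 87 or 3 dimensions before the SVM. The
projection is fit on the full matrix before splitting, mirroring the
original workflow for comparability; this leaks held-out information into
the basis, and a per-fold (`pca_scope="train"`) alternative is provided.
Phenotype accuracy maps predicted (C, ell) classes through the phenotype
table, so supervised phenotype accuracy can never fall below parameter
accuracy.

## Scaled-down study sizes

Full-scale replication (2500 simulations of 200 agents plus ~2 x 10^5
Rips computations) is a multi-hour batch run; `PipelineConfig()` defaults
reproduce it exactly. The bundled test suite instead runs:

* signature checks on four full-protocol runs (N = 200, t = 100) — single
  mill (0.5, 0.1), double mill (0.9, 0.5), double ring (0.1, 0.1), escape
  (2, 0.9) — asserting M_ang ≈ M_abs ≈ 1, M_abs > M_ang, the b1 = 2
  time-delay plateau, and diverging D_NN respectively;
* an accuracy regression on a 25-combination x 10-run library with N = 50
  agents (protocol otherwise unchanged). At this scale the qualitative
  conclusion is robust — topological features beat concatenated order
  parameters for parameter recovery by ~20 percentage points on both the
  supervised and unsupervised routes — while absolute accuracies sit below
  the full-scale values because several collective-swarm parameter
  combinations become genuinely hard to distinguish with 50 agents. One
  test asserts the full-scale 90% bar anyway and is expected to fail at
  this scale; the bar is kept rather than softened.

What the synthetic data does not emulate: measurement noise, missing or
swapped agent identities, unequal frame rates, and three-dimensional
motion. Passing tests demonstrate internal correctness of the pipeline and
the robustness of the topology-vs-order-parameter ordering at reduced
scale, not performance on experimental tracking data.

## Known limitations

* The double-mill regime at (0.9, 0.5) is delicate; with unlucky initial
  conditions it can settle toward a single mill, which is why signature
  checks average the last sampled frames and use a fixed seed.
* b1 computation cost is strongly geometry-dependent (ring-like clouds with
  long-lived cycles are the slow case); the engine is single-threaded.
* The k-medoids route, like the reference implementation, is a local
  search and offers no global-optimality guarantee.
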