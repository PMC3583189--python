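# Methods

This note records the models and procedures implemented in `ixprofile`,
the defaults and why they were chosen, and what the synthetic
experiments do and do not establish.

## Disease subnetwork construction

Interaction records are canonicalized on read (upper-case symbols,
self-loops dropped, duplicate unordered pairs collapsed to the maximum
confidence) and optionally filtered by a confidence threshold. Seed
genes are expanded by breadth-first search to every gene within `hops`
interaction edges (default 1 — the literal nearest-neighbor reading;
deeper expansions are a parameter), and the subnetwork is the *induced*
subgraph on that node set: every surviving record with both endpoints
inside it becomes an edge. Reordering requires reachability, so the
pipeline operates on the largest connected component (ties broken by
the lexicographically smallest member gene). Duplicate probe rows in
expression input are collapsed by arithmetic mean; mean is symmetric,
standard, and exposed as a policy parameter (`max`, `first`).

Gene weights are `w(g) = deg(g) / max_degree` in degree mode (degree is
the unweighted edge count — confidence scores gate which edges exist
but do not enter the weight), or all ones in uniform mode. Max-degree
normalization keeps w ∈ (0, 1] so profile magnitudes are comparable
across networks of different density.

## ACOR reordering

The reordering heuristic evolves an ant-visit density over nodes:

* Each iteration launches one ant per node (*populated* mode; *single*
  mode launches all ants from the highest-degree node) for
  `walk_length` steps. A step from u to neighbor v has probability
  ∝ τ(u,v)^α · deg(v)^β; τ is the per-edge pheromone, updated per
  iteration by τ ← (1 − ρ)τ + deposits (normalized per step) and kept
  above a floor ε.
* Visit counts accumulate across iterations into a node density, which
  is normalized to sum to one; genes are ranked by density
  (ties broken lexicographically) to give the initial ordering.
* The ordering is refined by an insertion local search: for each
  position, the node there is slid left and right through chained
  adjacent transpositions with exactly accumulated cost deltas, and the
  best strictly improving stop point is committed. Single adjacent
  swaps are the one-step special case of these slides; the longer
  slides are essential, because pure one-step swap search stalls in
  shallow local optima far above block contiguity (about 1660 vs about
  700 arrangement cost on the default 40-gene planted-partition case),
  while insertion search reliably reaches module-contiguous
  arrangements within the default 5 passes (at or below the
  hierarchical-clustering baseline). Only strictly decreasing moves
  are accepted, so the final cost never exceeds the density-ranked
  initial cost, and the whole procedure is deterministic given the
  seed.

Defaults (`AcorParams`): `n_ants = N`, `walk_length = 10`,
`alpha = beta = 1`, `rho = 0.1`, `n_iterations = 50`,
`refine_passes = 5`, `pheromone_floor = 1e-6` — conventional
ant-colony settings; every one is exposed in the config. Ordering
quality is quantified throughout by the linear arrangement cost
Σ|π(u) − π(v)| over edges; a brute-force exhaustive minimizer (N ≤ 9)
provides ground truth on small graphs, and on random small instances
the ACOR cost sits between the optimum and the random-ordering median
(mean cost ratio to optimal ≈ 1.01–1.02).

Baseline orderings: damped random-walk ranking by power iteration
(damping 0.85, L1 tolerance 1e-10, hard cap 10 000 iterations, scores
descending, lexicographic ties); average-linkage hierarchical
clustering on d(u, v) = 1 − Jaccard(closed neighborhoods), leaf order
with deterministic child ordering (smaller cluster first, then
lexicographically smallest member); uniform random permutation.

## The IXP transform

A sample's expression map x is integrated along the ordering as

    F(i) = sum_j w(g_j) * x(g_j) * exp(-(i - pos(g_j))^2 / (2 sigma^2)),

with σ = r · b. The horizontal influence coefficient r (swept 0.0–0.9)
is dimensionless; the base bandwidth b (default 10 positions) makes the
r-to-width conversion explicit, and results should always be read
together with b. At r = 0 the kernel degenerates to a delta and the
transform is exactly the weighted, position-permuted raw matrix (used
as the benchmark anchor). Three deliberate choices:

* **No kernel renormalization.** Dividing by the local kernel mass
  would equalize peak heights and erase the additive "new peak" effect
  — several adjacent weak genes outgrowing one strong gene — which is
  the point of the method.
* **Missing expression.** Network genes without measurements contribute
  a configurable fill value (default 0, i.e. no evidence after
  centering); expression genes absent from the network are ignored and
  counted. Real networks typically have ~10% unmeasured genes.
* **Per-gene z-normalization** (default in the sweep harness)
  standardizes each gene across the samples of each dataset
  *independently*, the simple device for train/test sets from
  different platforms; zero-variance genes become all-zero.

Because the kernel mass grows ∝ σ, the total variation of F is *not*
monotone in r in general; the monotone quantities are TV per unit
kernel mass (up to ~1% discretization effects at the profile
boundaries) and TV relative to the raw profile. The transform is exactly
linear in x and equivariant under consistent gene relabeling.

## Classification harness

A linear-kernel SVM (C = 1; both exposed) is trained on the IXP
features of the training dataset and scored by plain accuracy on the
blind test dataset. Orderings and weights are functions of the network
only — never of any expression data — computed once per method and
reused across the whole r grid, so no test information can leak into
the representation. The `random+uniweight` arm reuses the random
permutation with unit weights to separate the contribution of weights
from that of ordering. Feature columns are the N positions directly.

## Synthetic data generator

`SyntheticConfig` draws a planted-partition graph (intra-module edge
probability p_in, inter-module p_out, rejection-resampled to
connectivity) and two-class Gaussian expression: class-0 values are
N(0, noise_sd²); in class 1, every gene of the first
⌈affected_fraction · n_modules⌉ modules shifts by weak_effect · noise_sd
and `n_strong_singletons` genes in unaffected modules shift by
strong_effect · noise_sd. One network and two independent expression
draws (train/test) form a case; all draws derive from one seed.

Default condition: 4 modules × 10 genes, p_in = 0.9, p_out = 0.03,
20 + 20 samples per dataset, weak_effect = 0.4, noise_sd = 1,
affected_fraction = 0.5, and **no strong singletons**. At these
settings a per-gene t-test on a weak gene has power < 0.5 at α = 0.05
while the 10-gene module mean is detected with power > 0.9 — weak
individually, strong coordinately, which is the regime the transform
targets. The default deliberately isolates that regime: strong isolated
markers are delta-like signals along the ordering, exactly what a
smoothing prior penalizes, so adding them (n_strong_singletons > 0,
effect 2 sd) hands the advantage back to the raw r = 0 profile and
makes accuracy ordering-independent. That behavior is itself a faithful
property of kernel-smoothed features and is exercised in the unit
tests; it is a caution for applying the method to diseases driven by a
few strong markers rather than diffuse module-level dysregulation.

What the generator does *not* emulate: probe-level artifacts, platform
batch effects, heavy-tailed intensity distributions, degree-corrected
hub structure, or disease-specific topology. Passing the synthetic
experiments therefore shows that the pipeline recovers coordinated
module signal through contiguity — not that it reproduces any specific
published accuracy on real cohorts.

## Experiment sizes and numerical choices

The bundled experiments run at desk scale: 40-gene networks, 40 + 40
samples, 20 replicate studies for the recovery comparison, 50 for null
calibration, 20 random graphs (N ≤ 8) for the brute-force sandwich —
sizes at which every experiment completes in seconds while the planted
effects remain in the intended weak-signal regime. Determinism: all
stochastic components take explicit integer seeds (NumPy Generator /
SeedSequence); ties in every ranking break by descending score then
lexicographic gene symbol. σ below 1e-9 is treated as the delta kernel
to avoid underflow. Degenerate inputs (disconnected networks, N < 2,
single-class labels, empty gene intersections) raise informative errors
rather than proceeding.

## Known limitations

* The ACOR walk parameters are conventional, not tuned; the refinement
  stage does most of the arrangement-cost work on small graphs, while
  the density ranking contributes the global layout.
* Arrangement cost is a proxy: minimum linear arrangement is NP-hard
  and the heuristic offers no approximation guarantee beyond the
  oracle-sandwich checks at small N.
* The r-to-bandwidth mapping is linear by construction; other
  monotone mappings would relabel the sweep axis without changing the
  family of transforms.
* Cross-platform transfer is emulated only by independent
  standardization of train and test draws from the same distribution;
  real platform shifts are harsher.
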