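# Methods

This note records the model, the numerical choices, and the reasoning behind
defaults, at the level of detail a maintainer or reviewer needs.

## 1. Integration model

### Networks

Every technology has an encoder MLP (features → 2·d outputs read as
posterior mean and log-variance; d = 8 by default) and a decoder MLP
(latent → per-feature Gaussian mean with fixed unit variance, so the
reconstruction NLL is a scaled squared error plus a constant). Hidden
layers are ReLU; defaults are two hidden layers of 64 units for
encoder/decoder and two of 8 for the discriminator. The discriminator acts
on a latent code concatenated with a one-hot label block that always
includes one extra *censored* class; spectral normalization (one
power-iteration step per training pass, scale treated as constant in the
backward pass) bounds each layer's Lipschitz constant near 1.

All networks are implemented directly in numpy (`scmatch._nn`): dense
layers with cached forward passes, hand-derived backprop, Adam. At these
sizes a deep-learning framework buys nothing; float64 throughout and a
single-threaded BLAS give bit-reproducible training from a seed. Gradient
correctness is pinned by central-finite-difference tests (relative error
≤ 1e-4 through the full reconstruction + adversarial path).

### Losses

* VAE phase: `L = NLL + β·KL` with the closed-form Gaussian KL; β = 0.01 —
  the KL acts as a weak regularizer only, so the latent codes keep the
  data's branch structure. Trained with Adam, lr 5e-4, on the source
  technology; codes are the posterior means.
* Alignment phase: each target minimizes `NLL + β_adv · (−log D(z_t))`
  against the frozen source codes, one discriminator update (binary
  cross-entropy, source = 1) after every autoencoder update. The encoder
  runs deterministically (posterior means) in this phase: the codes used
  for matching and divergence are means, and aligning sampled codes while
  consuming means downstream left the means systematically offset.

### Choices that mattered (found during development, kept as defaults)

* **Source-code standardization.** After VAE init the frozen source codes
  are standardized per dimension (a fixed affine reparameterization of the
  latent space; matching is unaffected). Without it the 1-Lipschitz
  discriminator spends its entire output range on the raw scale and offset
  of the code cloud and cannot signal finer misalignment.
* **Label scaling.** The one-hot label block at the discriminator input is
  multiplied by `label_scale` = 3 so class conditioning is commensurate
  with the (standardized) code coordinates; with scale 1 the discriminator
  largely ignored the labels and branches were swapped during alignment.
* **β_adv = 50.** The reconstruction NLL is a per-cell *sum* over features
  (~240 nats at 256 features), so the adversarial term needs a weight of
  this order to contribute meaningfully to the encoder gradient. Exposed in
  the config; the divergence score is the tool for tuning it per dataset.
* **Batch size 64, discriminator lr 2e-3 (4× the autoencoder lr).** The
  adversarial game needs enough update steps to equilibrate: with batch 256
  at a 64-epoch budget the discriminator sits at chance while per-branch
  centroids remain several units apart; batch 64 quadruples the step count
  and the divergence then falls clearly below its initialization value.
* **Label censoring.** `label_fraction` of cells (chosen once per run,
  uniformly) reveal their label to the discriminator; all others carry the
  censored class. Fully supervised (1.0) by default; 0.1 mirrors the
  semi-supervised real-data regime.

Training faults (non-finite losses) abort with epoch/batch context rather
than silently continuing.

## 2. Divergence score

`knn_kl(P, Q, k)` estimates KL(P‖Q) from k-nearest-neighbor distances:
`(d/|P|) Σ_i log(ν_k(p_i)/ρ_k(p_i)) + log(|P|/(|Q|−1))`, with ν_k the
distance from p_i to its k-th neighbor in Q and ρ_k the k-th neighbor
within P excluding p_i itself (the self-distance would be degenerate).
`divergence_score` is the symmetric average of the two directions — exactly
symmetric by construction. Distances are floored at 1e-12 so duplicated
cells cannot produce infinities. Default k = 5; Euclidean metric,
consistent with the matching module.

Two estimator properties worth knowing:

* It is consistent but slowly converging when the two distributions barely
  overlap: for 1-D unit Gaussians three standard deviations apart (true KL
  = 4.5) it reads ≈3.8 at n = 5000 and ≈4.3 at n = 200 000. Verified
  against an exhaustive all-pairs-distance implementation; the bias is the
  estimator's, not the code's.
* On code clouds concentrated near low-dimensional manifolds (exactly what
  trajectory-structured latent spaces look like) its absolute value grows
  with n, because within-sample spacing shrinks while any cross-sample
  offset does not. Compare divergences only at equal sample sizes, and read
  the score comparatively (across epochs or configurations), not as an
  absolute KL.

`select_model` filters runs by dual thresholds (divergence and
reconstruction error) and returns the minimal-divergence passer, ties
broken by reconstruction error; when nothing passes it returns `None`
rather than an arbitrary run.

## 3. Matching

The candidate graph is the union of the two directed kNN queries (each side
queried against the other, k per query, duplicates kept once, ties broken
by index). The flow network places the bigger dataset (n cells) on the root
side: root→cell arcs of capacity 1, candidate arcs of capacity 1 costed by
Euclidean distance, sink arcs from the m smaller-side cells with capacities
⌊n/m⌋ (the first n mod m incremented) summing to n, and a null node
connected to every left cell at the p-th percentile (linear interpolation)
of candidate costs, with capacity n. Costs are integerized at ×1e6 (well
below matching-relevant scale); the null cost gets +1 on the integer scale
so exact ties resolve to a real match rather than a null assignment. An
`unbounded_sink` variant lifts the per-cell capacity to n.

The min-cost-flow program is solved as an LP over the node-arc incidence
matrix with HiGHS (via `scipy.optimize.linprog`). Min-cost-flow constraint
matrices are totally unimodular, so the simplex optimum is integral; the
solver asserts integrality and total flow = n after every solve, and raises
on infeasibility (only possible when the null node is disabled and the
candidate graph too sparse). Correctness is cross-checked in the test suite
against exhaustive enumeration (n, m ≤ 8), the Hungarian algorithm on dense
balanced instances, and an independent network-simplex implementation.
At the benchmark scale (8000×8000 cells, k=64, ~7·10⁵ arcs) one solve takes
well under a minute on a single CPU.

## 4. Simulator

The default lineage tree has five branches with pairwise-distinct lengths:
a root of length 20, children of lengths 15 and 25, and two grandchildren
(off the length-25 branch) of lengths 10 and 30 — shallow and deep tips,
total length 100. Cells are placed uniformly over total tree length, so
branch occupancy is proportional to branch length and the within-branch
offset is uniform. (The *global pseudotime* marginal is deliberately not
uniform: sibling branches overlap in time, so the marginal is multimodal —
any test of the sampling density must look at arc-length position, not
pseudotime.)

Per technology, each feature's log-mean performs an independent Gaussian
random walk along a unit-step pseudotime grid (increments N(0,
walk_sd²·Δt)), continuing from the parent's terminal value at branch points
so means are continuous. Exponentiated walks are scaled once so the
expected per-cell total count is 10 000 (typical scRNA depth). Counts are
negative binomial via the gamma–Poisson mixture with per-feature dispersion
r drawn log-uniformly from [1, 100] (Var = μ + μ²/r). Defaults: walk_sd =
0.3 per √(pseudotime unit) — strong enough that branches are separable,
chosen a priori as a plausible trajectory-data roughness; dispersion range
and library size as above.

What the simulator emulates: shared latent branching structure, fully
disjoint feature spaces, NB count noise, per-cell ground truth. What it
does not: dropout, batch effects, CyTOF-specific noise, doublets, and —
importantly — correlated feature programs. Because all 256 features diffuse
independently, a cell's tree position is more identifiable here than in
real data or in module-based simulators where features are mixtures of a
few latent functions. Passing the pipeline tests therefore demonstrates
that integration and matching recover shared structure under count noise;
it does not bound performance on real tissues, and the benchmark accuracy
(≈0.89–0.96) sits somewhat above what the harder published simulation
reported (0.86).

## 5. Benchmark protocol and problem sizes

`run_simulated_benchmark` (used by the acceptance script and the
acceptance tests) runs: two technologies × 8000 cells × 256 features,
independent program seeds; VAE init 64 epochs; adversarial phase 64 epochs
fully supervised on branch labels; matching with k = 64, p = 95; metrics
over non-null pairs (branch-label accuracy, Pearson/Spearman of
pseudotime), with null share reported separately via matched fractions.
These sizes keep one full run at ~90 s on a single CPU; the published
experiment used 64 000 cells and 256 epochs, and matching quality improves
with both. Unit tests use 1200–3000 cells, where every qualitative property
(structure retention, divergence decrease on duplicated data) already
holds.

## 6. Known limitations

* The divergence score's manifold sensitivity (above) makes absolute
  thresholds dataset-specific; `select_model` thresholds are deliberately
  caller-supplied.
* The matching LP holds the full candidate arc set in memory (~100 MB at
  the benchmark scale); far larger datasets would need a streaming or
  blocked solver.
* Orientation of the latent space relies on label conditioning; with no
  labels at all (`label_fraction` = 0 and no label columns) integration
  still mixes distributions but within-cluster orientation can flip,
  exactly the failure mode label conditioning exists to prevent.
* Decoding expression values across technologies is out of scope by
  design: the latent space is used solely for matching, and downstream
  analysis should use the measured values of the matched cells.
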