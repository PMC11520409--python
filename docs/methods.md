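# Methods

`spotalign` integrates two or more spatial transcriptomics (ST) slices by
jointly learning (i) a shared low-dimensional embedding of all spots with a
graph-attention autoencoder and (ii) an unbalanced entropic optimal-transport
(UOT) plan coupling spots across slices in that embedding. The plan is then
used downstream for hard spot matching, evaluation metrics, and rigid 2D/3D
coordinate registration. This note records the model, the numerical choices,
and the places where the design was genuinely open.

## Model

**Inputs.** Each slice contributes a spot × gene matrix of log-normalized
expression over a shared ordered gene list, plus 2D spot coordinates. Within
each slice a spatial neighbor graph connects spots at Euclidean distance
strictly less than a radius `r`; neighbor sets `S_i` include the spot itself
so isolated spots still aggregate their own features. Slices are concatenated
row-wise with a block-diagonal graph, so no message passing crosses slices.

**Graph-attention autoencoder.** Encoder layer `k` computes
`h_i = act( sum_{j in S_i} att_ij (W_k h_j) )` with attention logits
`e_ij = sigmoid(v_s.(W_k h_i) + v_r.(W_k h_j))` normalized by a softmax over
`S_i`. The decoder mirrors the encoder with tied weights (`W_k^T`) and
transposed attention matrices, so the trainable parameters are exactly the
encoder's `W_k, v_s, v_r`. Defaults: two layers `[g -> 512 -> 30]`, ELU
feature activation, sigmoid attention gate, linear latent and output layers
(the latent space is unbounded and reconstructions live on the normalized
expression scale). The two activation slots are deliberately different: a
bounded gate keeps the softmax logits in a narrow range, which stabilizes the
attention early in training.

**Transport plan.** With embeddings `z_x, z_y` of the two slices, the cost is
the plain Euclidean distance `C_ij = ||z_xi - z_yj||` (a flag switches to the
squared distance), max-normalized before solving so the entropic scale is
problem-independent. The plan minimizes

    <C,T> - eps*H(T) + rho1*KL(T1 || a) + rho2*KL(T'1 || b)

with `H(T) = -sum T(logT - 1)`, generalized KL marginal penalties, and
uniform spot weights `a, b`. Finite `rho` lets mass be created or destroyed —
the mechanism behind partial alignment. Defaults: `eps = 0.05`,
`rho1 = rho2 = 1` (global regime); the partial regime sets `rho1 = inf`
(every source spot ships its full mass, exactly) and `rho2 = 0.01` (target
spots may be skipped).

**Solver.** An inexact proximal-point scheme: each outer step builds the
kernel `G = T^l * exp(-C/eps)` and runs a short inner loop of unbalanced
Sinkhorn scalings with exponents `rho/(rho+eps)` (exactly 1 at `rho = inf`),
Gauss–Seidel order, ending on the row scaling so a hard row constraint holds
to machine precision in the returned plan. Two numerical points matter:

* *Initialization.* The initial plan is the **all-ones matrix**, which makes
  the first proximal step an exact entropic UOT solve of the objective above.
  Starting instead from the uniform plan `1/(n_x n_y)` adds a mass-dependent
  offset `eps*log(n_x n_y)*mass(T)` to the effective objective of the first
  step.
* *Objective monitoring.* Iterating the re-centered kernel to a fixed point
  provably anneals the entropy term away — the fixed point solves the
  *unregularized* UOT problem, not the entropic one (we verified the gap
  numerically: at `eps = 0.1` the entropic objective at the annealed fixed
  point is ~2% off its true minimum). Because the package defines the plan as
  the minimizer of the entropic objective, the outer loop evaluates the
  objective after each step and keeps only steps that decrease it. Users who
  want the sharpened (near-unregularized) plan can pass a uniform `T_init`
  and disable nothing else — the monitor simply stops later.

Scalings run in the log domain when `eps < 1e-2`. The solver is validated
against an independent oracle (L-BFGS on the log-parametrized objective) on
small instances; agreement is ~1e-12 relative at inner-loop convergence.

**Joint training.** The total objective is
`L = (1-gamma)*L_recon + gamma*L_UOT` with `gamma = 0.2`. `L_recon` is the
sum of squared reconstruction residuals *averaged per matrix entry*, and
`L_UOT = sum C_ij T_ij` on the max-normalized cost; both terms are therefore
O(1) at any spot/gene count and `gamma` is a meaningful trade-off. (The raw
summed residual would grow with `n*g` and reduce the transport term to
noise; the summed form is still what `reconstruction_loss` returns.) Training
alternates in envelope style: the plan is re-solved from the current
embeddings every 10 epochs and held fixed in between, so the transport
gradient flows only through the cost (hence the embeddings). The cost
normalizer is likewise frozen between refreshes. A reconstruction-only warmup
(first 20% of epochs by default) lets the latent space form before alignment
starts. Optimization is full-batch Adam (lr 1e-3); with a fixed seed, runs
are bit-reproducible. All gradients are analytic (hand-derived backward pass
through the tied decoder, the masked softmax, and the attention logits) and
are checked against central finite differences in the test suite; agreement
is ~1e-5 relative on non-degenerate toys. The finite-difference comparison
itself is only meaningful when no two embeddings nearly coincide — the
Euclidean cost has curvature `1/C_ij`, so FD noise dominates near `C = 0`.

**Multi-slice integration.** A trained network acts as a reference model: a
new slice is encoded with it (optionally after a brief reconstruction-only
fine-tune on the new slice, default 50 epochs; 0 keeps the parameters
bit-identical) and coupled to a designated reference slice by a fresh UOT
plan. The existing embedding is never recomputed.

**Rigid registration.** The plan provides soft correspondences, so "weighted
ICP" reduces to a single weighted Procrustes solve: weighted centroids are
removed, the rotation is the SVD solution on the weighted cross-covariance
`H = X~' T Y~` with the determinant-sign correction (reflections projected
out; an `allow_reflection` flag exists), and `t = mu_y - R mu_x`. Plan
entries below `1/(10 n_x n_y)` are dropped for speed (noise-level mass in an
entropic plan). An optional true-ICP mode re-matches nearest neighbors after
transforming and re-solves. 3D stacking registers every slice onto one
reference and assigns z-offsets as ordinal index × spacing.

## Parameters that matter

| parameter | default | units / meaning |
|---|---|---|
| radius `r` | per-slice, ~6 mean neighbors | coordinate units; `suggest_radius` picks the smallest pairwise distance reaching the target mean degree |
| layer dims | `[g, 512, 30]` | latent dimension 30 is the embedding used by all metrics |
| `gamma` | 0.2 | reconstruction/transport trade-off |
| `eps` | 0.05 | entropic scale on the max-normalized cost (in [0,1]) |
| `rho1, rho2` | 1, 1 (global); inf, 0.01 (partial) | marginal KL penalties |
| epochs / warmup / refresh | 500 / 100 / 10 | full-batch Adam steps; synthetic-scale runs in the tests and the acceptance script use 200 / 60 (the 400–800-spot grids converge well within that) |
| `n_hvg` | 3000 | highly variable genes kept after per-slice selection |
| `k_neighbors` | 50 | kNN size for batch entropy |

## Synthetic data: what it emulates, and what it does not

The generator plants ground truth for every claim the tool makes: spots on a
regular grid, cell-type labels in horizontal bands with per-layer marker
genes (`layer_effect = 1.0` on the log scale, 15 markers/layer, 80 genes
total), additive per-slice batch effects on a random 30% gene subset, rigid
motions of the second slice, and partial crops with configurable overlap
(default 70%, so two crops share 40% of spots).

Two structural choices deserve justification:

* **Positional gradients.** The non-marker genes split into a lateral (x) and
  a depth (y) gradient block (`gradient_effect = 1.0` across the tissue
  span). The lateral gradient makes the geometry identifiable: a purely
  band-structured slice is exactly mirror-symmetric, so *no* method could
  recover a planted rotation from expression alone. The depth gradient makes
  adjacent layers more similar than distant ones — the graded transcriptional
  structure of cortical depth. Real tissue has both properties.
* **Oblique partial crops.** Partial crops are taken along a 45° axis, so
  every layer appears in both subslices in different proportions — the
  situation straight crop lines create when crossing curved layers in real
  tissue. Crops parallel to the bands would preserve label composition
  exactly, in which case a balanced coupling is harmless and the partial
  regime has nothing to demonstrate (and the label-transfer ARI, being
  permutation-invariant, scores even a wholesale wrong-but-consistent block
  mapping as perfect).

What the generator does **not** emulate: realistic count distributions
(expression is Gaussian on the log scale; a Poisson count mode exists only to
exercise normalization), spatial autocorrelation beyond bands and gradients,
unequal spot densities, hexagonal array geometry, or segmentation/annotation
noise. Passing tests therefore demonstrate that the machinery is correct and
that the method behaves as designed under controlled nuisances — not that it
will reach the same scores on real tissue.

## Numerical choices and degenerate inputs

* Softmax over neighbor sets uses per-row max subtraction; empty rows cannot
  occur (self-inclusion).
* `rho = inf` uses scaling exponent exactly 1; ending each inner loop on the
  row update makes hard row marginals exact, not approximate.
* Matching ties break to the smallest target index; rows with maximum mass
  below `min_mass` (or all-zero rows) are left unmatched (sentinel −1) and
  excluded from accuracy denominators.
* ARI of two identical single-cluster partitions is defined as 1.0.
* Rank-deficient cross-covariance (collinear point sets) in Procrustes warns
  and returns the SVD solution anyway; zero-mass plans are an error.
* `suggest_radius` on all-identical coordinates warns and returns a token
  positive radius.
* Euclidean-cost gradients at coincident embeddings use a guarded `1/C`
  (zero contribution at exactly zero distance).
* Non-finite training losses abort with the epoch and per-term values.

## Known limitations

* Dense `n × n` attention masks and `n_x × n_y` plans: memory is quadratic in
  spots per comparison; the intended scale is up to a few thousand spots per
  slice. Per-slice graphs are stored sparse.
* The decoder's tied attention means `decode` needs the encoder's attention
  matrices; it cannot run from a latent matrix alone.
* Radius graphs only (no kNN variant); rigid registration only (no
  deformable alignment); no fused expression+structure transport term.
* Label-transfer ARI is permutation-invariant and can reward consistent but
  wrong block mappings when whole cell types are absent from one slice;
  alignment accuracy does not have this failure mode and should be read
  alongside it.
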