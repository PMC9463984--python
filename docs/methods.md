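# Methods

## Model

`vsdbn` implements a two-stage decomposition of multi-subject volumetric
fMRI into hierarchical functional brain networks (FBNs), with the network
architecture chosen by a particle-swarm search.

**Data layout.** Each subject's 4D scan is reduced, through a common brain
mask, to a matrix with one row per TR and one column per in-mask voxel;
voxel time series are z-scored (population SD, so the operation is
idempotent). Subjects are concatenated along time and the result is used
volume-as-sample: the group matrix `F` has `v x n` rows (TRs times
subjects) and `m` columns (voxels), and every row — a brain volume — is one
training sample.

**Volumetric sparse DBN.** The model is a stack of restricted Boltzmann
machines. The first layer uses Gaussian visible units with unit conditional
variance, energy `E(v,h) = sum_i (v_i - a_i)^2/2 - b.h - v.W.h`, because
z-scored BOLD values are unbounded reals; upper layers are Bernoulli RBMs
fed the layer below's mean-field hidden probabilities. The classical
all-Bernoulli energy `E = -a.v - b.h - v.W.h` is retained both as a layer
option and as the basis of the exact enumeration oracles used in testing.
Training is contrastive divergence (CD-1 by default) with momentum
(0.5 to 0.9 at epoch 5), weight decay 2e-4, mini-batches of 64, and a
sparsity penalty that pulls each hidden unit's mean activation toward a
target rate rho (default 0.1). The penalty follows the cross-entropy form:
the hidden-bias gradient gains `lambda * (rho - q_j)` and the weight
gradient the matching term through the logistic derivative.

Two deliberate numerical choices:

* **Mean-field negative phase.** By default the CD chain propagates
  probabilities rather than sampled binary states. This removes all
  sampling noise from the gradient, makes entire training runs
  bit-reproducible given a seed, and recovered planted networks better in
  our experiments; the classical sampled-hidden chain is available via
  `sample_hidden=True`.
* **Strong sparsity for the pipeline (`lambda = 3`, hidden biases
  initialized at -2).** A purely reconstruction-driven factorization of a
  linear mixture is defined only up to rotation of the latent space;
  sparsity is the pressure that aligns hidden units with individual
  networks instead of mixtures of them. At the weak setting
  (`lambda = 0.1`, kept as the `RBMLayer` default for generic use) learned
  maps converge to rotations of the planted ones.

**Two stages.** Stage 1 trains the DBN greedily, layer by layer, on the
group matrix. Stage 2 copies the group weights into one model per subject
(`W1` initializes visible-to-hidden-1, `W2`, `W3` the higher couplings) and
continues CD on that subject's data alone. Because stage 2 starts from the
group solution, atom `k` of a subject model corresponds to atom `k` of the
group model by construction; the 0-epoch fine-tune is an exact identity.
Fine-tuning uses the full stage-1 learning rate (a reduced rate times a
short budget was measured to leave the weights numerically unchanged,
which would make the individual stage vacuous); the pipeline default is
100 epochs per layer.

**Spatial maps and temporal features.** Layer-`L` maps are the columns of
the linear product `W1 @ ... @ WL` (one row per atom, `m` voxels),
deliberately ignoring the logistic nonlinearities — a linear read-out of
each voxel's contribution to each atom. Maps are sign-normalized (the
largest-magnitude voxel made positive; an RBM's weight sign is arbitrary)
and z-scored per map. Temporal features are the mean-field hidden
probabilities of each layer, one row per TR; they are left on the (0,1)
probability scale, where correlation-based metrics are unaffected by the
maps' sign convention.

## Architecture search

Particles carry a continuous 2-D position: number of layers and one shared
node count (the searched optimum in the motivating setting is a uniform
three-by-146 stack, and a shared count keeps the search space 2-D). The
update is

    v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x),   x <- x + v

with `w = 0.1`, `c1 = c2 = 2`, and `r1, r2 ~ U[-1, 1]` drawn per step and
dimension; `U[0, 1]` (the classical variant) is a config switch, and a
linearly decreasing inertia schedule is supported. Positions are clipped to
[2, 10] layers x [100, 800] nodes and rounded to integers only when a
fitness is evaluated, which keeps the discrete landscape from freezing the
dynamics. Each iteration one aging-evolution step retires the oldest
particle and inserts a mutated copy of a tournament winner (size 3;
mutation: +-1 layer and/or +-U(10, 50) nodes); the global best is tracked
outside the swarm and cannot be lost. Fitness is the held-out (20%)
top-layer mean-field reconstruction MSE of a DBN trained at a reduced
budget (15 epochs per layer by default); evaluations are cached per rounded
architecture, and training failures score +inf. Defaults: 30 particles, 40
iterations.

## Consistency metrics

* **ISC** (inter-subject correlation), leave-one-out variant: for each atom
  and subject, the Pearson correlation between that subject's time course
  and the mean course of all other subjects; a mean-pairwise variant is
  available. Constant courses are excluded as undefined, with a warning.
* **SCC** (spatial correlation coefficient): Pearson correlation of two
  voxel-wise maps over their z-scores (identical to plain Pearson).
* **Overlap rate** `R(S, T) = |S ∩ T| / |T|` on binarized maps, with `T`
  the group-level network — intentionally asymmetric. Binarization keeps
  voxels with map z-score above 1.96, positive side only (configurable).
* **Atom matching** (used only against synthetic ground truth; between
  stages the identity correspondence holds by construction): Hungarian
  assignment maximizing total |SCC|.
* **Group comparisons**: all pairwise two-sample t tests between network
  groups, Benjamini-Hochberg corrected, reported as a lower-triangular
  p-value table.

## Dynamic connectivity

Windows are tapered by convolving a 22-TR rectangle with a Gaussian
(sigma = 3 TRs) truncated at +-11 TRs. The truncation half-width is a
reconstruction: with full convolution support the window spans
22 + 2*11 = 44 TRs, the unique even-step-compatible length that yields 82
fully contained windows at step 2 in a 206-TR series. Within each window
the connectivity between component time courses is the taper-weighted
Pearson correlation. Windowed matrices (vectorized upper triangles) are
clustered with k-means, k = 4, 20 restarts, Euclidean distance; states are
renumbered by order of first occurrence, so the first window is always
state 1. SDFC between the group-level and individual-level results is the
per-window Spearman rank correlation between the two assigned state
(centroid) matrices, averaged over windows; Pearson and raw-window
comparisons are config switches.

## Synthetic data

The generator plants everything the pipeline is asked to recover. Each
subject's matrix is `Y_i = S_i M_i^T + sigma_n * noise` with:

* `M`: k1 = 8 Gaussian blobs (sigma 1.6 voxels, centers at least 3.5 voxels
  apart) in a ~1,380-voxel superellipsoid mask on a 12^3 grid — small
  enough that the full two-stage pipeline trains in seconds per model on
  one CPU. Composite maps (sums of 2-3 blobs) play the role of deep-layer
  networks.
* `S_i`: latent smooth sources — moving-average(5) white noise — mixed as
  `sqrt(1 - alpha) G + sqrt(alpha) U_i` from a group-shared `G` and
  subject-specific `U_i`, then rectified by `max(x - 0.5, 0)` and
  standardized. The rectification matters beyond surface realism: jointly
  Gaussian sources make a linear mixture distributionally invariant under
  latent rotations, so no blind decomposition could identify the planted
  maps even in principle; sparse nonnegative transients make the problem
  identifiable and are the regime a sparsity-regularized DBN targets.
* Subject specificity on both axes: `alpha` mixes subject-specific sources
  *and* scales a per-subject displacement of blob centers (SD 2 voxels at
  alpha = 1). With spatially identical subjects, fine-tuning has no
  subject-specific spatial target and the stage-1/stage-2 map agreement
  carries no information about alpha. At alpha = 0, subjects are identical
  up to noise. Default alpha = 0.2, noise SD 0.1, v = 100 TRs, n = 8
  subjects.

What the generator does **not** emulate: hemodynamic-response convolution,
physiological noise and scanner drift, anatomical variability beyond blob
displacement, and negative/overlapping network interactions. Passing
recovery tests on these fixtures demonstrates the machinery is correct and
well-conditioned, not that real whole-brain recordings decompose this
cleanly.

The planted dynamic-connectivity fixture draws component time courses
segment-by-segment from zero-mean Gaussians whose correlation matrices are
the planted states (Cholesky coloring), cycling with a fixed dwell time
(>= the 44-TR window length; the recovery experiments use dwell 100 over
800 TRs). A window overlapping a state change is labelled by the state
holding the taper-weighted majority of the window.

## Degenerate inputs and tie-breaks

Zero-variance voxels are dropped (and removed from the mask) with their
indices recorded; zero-variance components inside a window produce zero
connectivity entries with a warning; all-identical windows collapse the
clustering to the number of distinct patterns and flag the result
degenerate; empty binarized group networks make the overlap rate undefined
(recorded as NaN in pipeline output). K-means ties and the oldest-particle
tie in the aging step resolve to the lowest index. All randomness flows
from explicit seeds; two runs of any stage with the same seed are
byte-identical (model files are written without HDF5 timestamps, and run
manifests record content digests, not wall-clock times).

## Problem sizes

The shipped defaults (12^3 grid, ~1,380 voxels, 8 subjects x 100 TRs,
16-8-8 architecture, 500 group epochs, 100 fine-tune epochs) put the full
pipeline at roughly a minute on one CPU core and the complete test suite
under ten minutes. The search ranges, window parameters and k = 4 are kept
at the motivating study's values; only the data scale is reduced.

## Known limitations

* The linear-product map rule ignores the sigmoid nonlinearities; deep-layer
  maps are an approximation inherited from the modeling approach.
* CD with a mean-field chain is a biased estimator of the likelihood
  gradient; we treat the RBM as a feature learner, not a density model.
* Blind recovery is evaluated against blob-shaped, mostly disjoint
  networks; heavily overlapping networks would lower matched SCC for any
  method.
* The PSO benchmark landscape is analytic; full DBN-in-the-loop searches
  are supported but sized down (reduced epoch budgets) for CPU use.
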