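# Methods

## Task

The network solves two problems at once on a periodic domain:

1. **Path integration.** Per spatial dimension, the angular velocity at step
   t is `dth_t = mean + eps_t`, with the per-sequence mean drawn from
   N(0, 0.1 rad) and per-step noise from N(0, 0.3 rad). The initial angle is
   uniform on [0, 2*pi) and enters only through the initial-condition
   encoding `z = (sin th_0, cos th_0)`. The target at every step is
   `(cos th_t, sin th_t)`; predicting the raw angle would force the linear
   readout through a discontinuity, the (cos, sin) pair avoids that.
2. **Latent-state inference.** One of K >= 2 discrete states is active at
   all times. State-change events follow a per-step Bernoulli process with
   rate 1/50 (the discrete-time homogeneous Poisson approximation); at each
   event the new state is drawn uniformly from the K-1 inactive states and
   announced only by a 2-step unit pulse on that state's cue channel. The
   target is the active state at every step, switching at pulse onset.

Two conventions the task statement leaves open, fixed here once:

- **Initial state.** The initial-condition encoding carries position only,
  so the first active state is announced by a cue pulse over the first two
  steps; without it the state target before the first event is unlearnable.
- **Overlapping cues.** An event arriving while a pulse is still being
  emitted is deferred step-by-step until the channel is free, so pulses
  never overlap and every event still produces a state change.

**Session mode** emulates the trial structure of a circular-track recording
session: the initial angle is 0, velocities are `abs(mean + eps_t)` so the
trajectory sweeps the track one way, and state changes are rare (1/500 per
step). Rollouts are cut into track traversals at crossings of th = 0,
incomplete traversals are dropped, and each traversal is labeled by its
predominant true latent state — its "map".

## Model and training

Elman network, `x_{t+1} = ReLU(A x_t + B u_t + beta)`, linear readout
`y_t = C x_t + alpha`, linear initial-condition encoder `x_0 = D z + gamma`
(not rectified, so x_0 may contain negative entries; all later states are
nonnegative rates). `gamma` has length N for dimensional consistency with
x_0. Weights initialize uniform on (-1/sqrt(N), 1/sqrt(N)) for the recurrent
and readout groups and (-1/sqrt(M0), 1/sqrt(M0)) for the encoder (fan-in).

Loss = position MSE + state cross-entropy, both averaged over batch and
time, summed with unit weights; the cross-entropy is graded at every step,
including during cue pulses. Training generates a fresh batch (default 124
sequences) every update, follows a sequence-length curriculum (length
1 + floor(update / 50), reaching 600 after the full 30000 updates), and
clips the global gradient norm at 2. Gradients come from backpropagation
through time implemented in NumPy; the update arithmetic runs in float32.

**Optimizer.** Plain SGD trains the state component but destabilizes the
position integrator as the curriculum lengthens: at every learning rate we
tried, the position MSE rises once sequences exceed a few tens of steps.
Adam (default lr 1e-3, beta = 0.9/0.999) with the same clipping and
curriculum trains both components reliably and is the default;
`TrainConfig(optimizer="sgd")` restores plain SGD. Training is bitwise
reproducible from the seed on a fixed platform.

**Evaluation.** State accuracy is the fraction of held-out steps where the
argmax logit matches the true state. Angular error is the circular distance
`min(|d|, 2*pi - |d|)` between decoded and true angle at the evaluation
horizon, in degrees.

## Session analyses

- **Tuning curves**: per map, the mean hidden activation in each of P
  equal position bins (left-closed) over [0, 2*pi); P = 50 for alignment
  and remap-vector analyses, 250 for subspace estimates, 80 for per-trial
  vectors. Empty (map, bin) cells raise rather than silently interpolate.
- **Per-traversal vectors** (80 bins): a single traversal covers the track
  in ~25 steps, so most bins are empty per traversal; they are filled by
  circular linear interpolation per unit before correlating or clustering
  (the source procedure does not state its handling; this is the simplest
  choice that preserves the circular topology).
- **Map detection**: Euclidean k-means (k-means++ init, 50 restarts) on
  per-traversal vectors z-scored per unit. On trained models the detected
  partition agrees with the true-state traversal labels at ~100% after
  permutation matching.
- **Stability filter**: within each map, a traversal is kept iff its mean
  Pearson correlation with the other same-map traversals is >= 0.25; maps
  with fewer than two traversals are kept trivially with a warning.
- **2D models** have no traversal structure; toroidal tuning curves are
  pooled from training-regime rollouts on an n x n grid over both angles
  and flattened row-major, giving one (n^2, N) manifold per state.

## Geometry

- **Variance spectra**: cumulative explained-variance fractions of the
  mean-centered activity (SVD).
- **Procrustes misalignment**: both (P, N) manifolds are column-mean-
  centered and scaled to unit Frobenius norm. Observed RMSE is computed
  before any alignment; the optimal rotation (proper, det +1 — a reflecting
  optimum is projected to the nearest rotation) gives the score's zero
  anchor, and the 25th percentile of RMSEs under 1000 Haar-random rotations
  of the second manifold gives the unit anchor:
  `score = (obs - opt) / (null_25 - opt)`. A rotated copy therefore has
  optimal RMSE 0 but scores like a null draw — alignment is a property of
  the embedding, not of shape.
- **Position subspace**: top principal axes of stacked position-binned
  activity; 2 components for a ring, 4 for a torus. For orthogonality
  statements about the remapping dimension the per-map subspace is the
  right reference: at reduced training scale the across-map stack can be
  dominated by the between-map separation itself.
- **Remapping dimension**: unit-normalized difference of the two maps'
  mean activations.
- **Remapping vectors**: `xi_p = x_p^(2) - x_p^(1)` on raw bin-matched
  curves, so the identity `W xi_p = W x_p^(2) - W x_p^(1)` is exact
  (W = position-readout rows of C). Reported: per-bin `||W xi_p||`, the
  mean vector v, normalized deviations `||xi_p - v|| / mean_p ||xi_p||`
  (the normalizer is unstated at the source; the mean remap-vector norm
  makes the statistic scale-free), the PCA spectrum of the uncentered xi
  matrix (a pure translation is exactly rank 1), and the bin-by-bin
  covariance of the centered vectors.
- **Nullspace rotation control**: deviations of map 2 from its centroid are
  split into the row space and nullspace of W; a Haar-random rotation is
  applied to the nullspace component only. Decoded position is preserved to
  machine precision while ring alignment is destroyed — the chance
  benchmark for the observed alignment.
- **Weight/subspace cosines**: norm of the orthogonal projection divided by
  the vector norm (Hermitian inner product for complex eigenvectors).

## Fixed points

Approximate fixed points of the zero-input map minimize
`q(x) = ||x - ReLU(A x + beta)||^2` by gradient descent with per-point
adaptive steps (grow 1.1x on improvement, halve otherwise), iteration cap
10000-20000. Initializations: 1024 states sampled from a session rollout,
every second one perturbed with isotropic noise at 10% of the mean state
norm. Points with q < 1e-8 are kept and deduplicated at a 0.01 Euclidean
merge radius (lowest residual wins). The Jacobian at x* is `diag(g) A` with
g the ReLU activity pattern (subgradient 0 at exact kinks, which are
flagged); classification uses a marginality band of 0.05 around
`|lambda|_max = 1` — marginally stable inside, unstable above, discarded
(contracting) below.

**Ring membership.** The census of "on-ring vs between-ring" points uses
the remap-dimension projection coordinate (map-1 centroid at -1, map-2 at
+1): |coord| > 0.5 counts as ring-resident. A distance-to-tuning-curve rule
is unreliable here because integrator drift within session sequences smears
the binned curves toward their centroid, shrinking the curve estimate
relative to the true attractor ring.

## Problem sizes and what the tests show

The package's own study conditions for tests and the acceptance script are
scaled down from the full configuration (N = 248, 30000 updates): N = 128
with 6000 updates (two-state, 1D), 6000-8000 updates (three-state), and
4500 updates with a 25-update curriculum step (2D). Sessions use 80-100
sequences of 150 steps, short enough that within-sequence drift does not
wash out the position-binned manifolds.

At this scale the qualitative results are stable across seeds: state
inference is perfect (100% of held-out steps), three-state remapping
dimensions sit at 60 degrees (mean across pairs 60.0 on every seed tested),
rings are aligned well below the rotation null, remapping vectors are
suppressed in the readout row space below the random-direction expectation
sqrt(2/N), and the fixed-point skeleton shows marginal ring points bridged
by remap-aligned saddles. Quantities that mature only with full training —
the 8-degree angular error at 300 steps, the ~50% top-3 variance share, the
printed position MSEs — are checked at test scale only as bounds consistent
with the mechanism (errors far below chance, low-dimensional spectra, small
MSEs), not at their full-scale printed values.

## What the generator does and does not emulate

The synthetic session reproduces the *structure* of a circular-track
recording — trialized traversals, position-binned tuning curves, discrete
map labels, trial-by-trial correlation matrices — with ground-truth state
labels available. It does not emulate spiking variability, behavioral
covariates (running-speed changes that correlate with biological remapping),
reward or landmark structure, or probe/waveform artifacts; passing tests
demonstrate properties of the trained dynamical system, not goodness-of-fit
to any recorded dataset.

## Known limitations

- The float32 training path means runs are reproducible per platform but
  not necessarily bit-identical across BLAS implementations.
- The fixed-point optimizer finds tens of distinct points per run at the
  default pool size; exhaustive enumeration of the slow manifold would need
  a larger initialization pool and looser merge radius.
- Session emulation is defined for the 1D track; 2D analyses use pooled
  rollouts rather than trialized sessions.
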