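# Methods

This note records the models, estimators, numerical choices and known
limitations behind `neurospd`, in the spirit of a methods appendix: every
claim here is either a definition or something the test suite and
`scripts/acceptance.py` actually compute.

## Signal model and protocol

The target data layout is a multichannel EEG recording protocol common in
emotion decoding: C = 62 channels sampled at 1000 Hz, downsampled to
200 Hz, band-passed 1–47 Hz with a 4th-order Butterworth filter, cut into
1-s non-overlapping epochs taken from the final two minutes of each of 15
trials, and split train/test by whole trials (first 9 train, last 6 test).

Two protocol decisions are fixed here because the filter family and order
alone do not determine them:

- **Zero-phase filtering.** The Butterworth filter is applied
  forward–backward (`sosfiltfilt`). Phase-locking estimates depend on
  undistorted instantaneous phase, and a causal filter's group delay would
  bias them. The effective magnitude response is the squared 4-pole
  response.
- **Polyphase resampling.** Downsampling uses rational-factor polyphase
  filtering (`resample_poly`) with its built-in anti-aliasing filter;
  output length is `ceil(n·fs_out/fs_in)`.

Trials shorter than the kept tail (120 s) raise an error instead of being
silently truncated — short trials would otherwise unbalance classes without
any visible symptom.

Filtering is applied per trial, never per epoch, so no epoch ever contains
filter edge transients from an artificial boundary.

## Connectivity estimators

One C×C matrix per epoch and estimator; all four are exactly symmetric by
construction (computed on unordered pairs and mirrored).

- **PLV.** Instantaneous phase from the analytic signal (Hilbert
  transform). The transform is unreliable at the window edges, so 5% of
  samples on each side are excluded from the phase average. Diagonal 1.
- **PCC.** Centered inner product over the product of centered norms.
  Diagonal 1. Zero-variance channels are an error (undefined phase /
  correlation), not a silent NaN.
- **COH.** Welch cross- and auto-spectra with 0.5-s segments, 50% overlap,
  Hann window — with 1-s epochs this gives three segments, the shortest
  configuration that still averages at all. Magnitude-squared coherence is
  formed per frequency and then arithmetically averaged over 1–47 Hz to
  produce one scalar per pair. Small-sample note: with three segments the
  null coherence floor is ≈ 0.33, visible in the synthetic benchmarks.
  Diagonal 1.
- **MI.** Equal-width 2-D histogram, 16 bins per axis spanning each
  signal's observed range, log base 2 (bits); `0·log(0)` terms contribute
  zero. The diagonal stores the channel's self-information (entropy of the
  binned signal). Histogram MI on 200 samples is biased upward (null level
  ≈ 0.7 bits at these settings); thresholds therefore cannot be compared
  across MI estimators on an absolute scale — see below.

## Graph construction and SPD rectification

Thresholding keeps off-diagonal entries with `|value| ≥ t` as weighted
edges (their magnitudes) by default; a binary 0/1 mode exists. Weighted
adjacency is the default so the Laplacian spectrum carries coupling
strength, not just topology. Negative correlations are thresholded by
magnitude: a strong anticorrelation is as informative an edge as a strong
correlation, and threshold grids for correlation features are conventionally
positive. The connectivity diagonal is ignored (no self-loops).

The combinatorial Laplacian `L = D − A` is symmetric PSD with the constant
vector in its null space, so it is never strictly positive definite.
Eigenvalue rectification `U max(εI, Σ) Uᵀ` with ε = 1e-4 (configurable)
clamps the spectrum from below, producing a genuinely SPD matrix. ε trades
conditioning against distortion: large enough that downstream
eigendecompositions are well-conditioned, small enough (four orders below
typical Laplacian eigenvalues) that it does not perturb informative
spectrum.

**Per-feature default thresholds** are PLV 0.6, PCC 0.7, MI 0.35, COH 0.4,
the sweep optima on the reference protocol. MI's threshold is interpreted
as a quantile level rather than an absolute value, because histogram MI has
no estimator-independent scale: a nominal threshold `t` on a 0–0.65
reference scale maps to the `t/0.65` quantile of the matrix's off-diagonal
distribution. PLV/PCC/COH thresholds are absolute (their estimators are
normalized to [0,1] / [−1,1]).

## SPD geometry

The affine-invariant constructions on the SPD manifold:

- tangent (logarithmic) map `Log_S(S_i) = S^{1/2} logm(S^{-1/2} S_i S^{-1/2}) S^{1/2}`,
- exponential map `Exp_S(T_i) = S^{1/2} expm(S^{-1/2} T_i S^{-1/2}) S^{1/2}`,
- geodesic distance `δ(S1,S2) = ||log Σ(S1^{-1}S2)||_F`, computed from the
  generalized eigenvalues of the pencil (S2, S1).

All spectral functions use the eigendecomposition pattern `U f(V) Uᵀ` on
symmetrized double-precision input. Eigenvalues below 1e-12 raise a domain
error: clamping is the graph stage's explicit job, and silent repair in the
geometry layer would mask construction bugs. The test suite cross-checks
the tangent maps against a Cholesky-whitening construction and scipy's
Schur-based `logm`/`expm` — different algorithms for the same object.

## SPD network

Architecture: (BiMap → ReEig) × K, LogEig, flatten, dropout, dense softmax
head. Defaults: for 62-channel input, K = 4 with dimension chain
62→31→20→16→12 (so the flattened feature is 144-dimensional); for other
input sizes the default is a two-block chain (3d/4, d/2), suited to the
8-channel benchmarks. Reference hyperparameters: learning rate 0.001,
batch size 64, max 200 epochs, weight decay 1e-4, dropout 0.2.

Implementation choices (the network is plain numpy with hand-derived
gradients):

- **Spectral-layer backprop** uses the Daleckii–Krein divided-difference
  form: for `f(S) = U g(V) Uᵀ` the input gradient is
  `U (G ∘ (Uᵀ dOut U)) Uᵀ` with `G_ij = (g(v_i) − g(v_j))/(v_i − v_j)` and
  `G_ii = g'(v_i)`; denominators are guarded at 1e-12. A finite-difference
  check on a 4-channel toy network agrees to better than 1e-4 relative
  error (observed ≈ 1e-9).
- **Degenerate spectra.** Batches whose eigen-gap falls below 1e-6 during
  training receive a deterministic graded diagonal perturbation of 1e-9,
  which breaks exact ties (e.g. the all-εI matrices produced by an empty
  graph) without measurably moving the loss.
- **Stiefel constraint.** BiMap weights keep orthonormal rows. Euclidean
  gradients are projected to the tangent space
  (`G − sym(W Gᵀ) W`) and each SGD step is retracted by a sign-fixed QR
  decomposition of `Wᵀ`. Initialization draws a seeded random orthonormal
  frame. Weight decay applies only to the dense head; the manifold
  constraint already bounds the BiMap weights.
- **Loss** is softmax cross-entropy; dropout acts on the flattened LogEig
  features. Ties in the fused argmax resolve to the lowest class index.
- **Determinism.** With a fixed config seed on one thread, initialization,
  batching, dropout and therefore final parameters are bit-reproducible.

Fusion averages softmax probabilities (not logits): probability averaging
keeps every model's calibration visible in the fused vector and makes the
single-feature case a trivial identity.

## Synthetic benchmark: what it emulates and what it does not

The generator plants class-conditional coupling: each class is assigned one
perfect matching of channel pairs from the round-robin one-factorization of
the complete graph, so matchings of different classes are edge-disjoint and
every channel joins at most one pair per class. A coupled pair shares a
source (narrow-band oscillator at a per-pair frequency in 6–30 Hz plus
band-limited broadband noise) mixed at weight `a` (coupling_strength) with
a private source of the same construction, then white noise of standard
deviation `noise_sd` is added. A configurable fraction of pairs (default
0.25) passes the shared source through `tanh(2·)` on one endpoint, giving
the histogram-MI estimator nonlinear structure that the linear estimators
under-report. Channel variances are class-independent by construction —
class identity lives only in which pairs couple.

Defaults mirror the reference protocol (62 channels, 200 Hz, 1-s epochs,
3 classes, 5 trials per class of 120 epochs); benchmarks and tests use the
scaled-down 8-channel, 40-epochs-per-trial variant with coupling 0.9 and
noise 0.1 so the full four-feature pipeline runs in minutes on one CPU.
Trials are laid out in interleaved class order so the "first 9 trials"
split stays balanced.

What passing on this data shows: the estimators detect the kinds of
dependence they are built for, thresholding recovers planted topology, the
SPD construction and network train stably and use connectivity (destroying
edges collapses accuracy to chance). What it does not show: performance on
real EEG — no volume conduction, no 1/f background, no artifacts, no
inter-subject variability, and far stronger coupling contrast than
biological recordings.

## Known limitations

- Training is CPU-only, plain SGD; no momentum or batch-norm-on-manifold.
- The histogram MI estimator is biased at T = 200; quantile thresholding
  sidesteps scale but not variance.
- The EDF reader is a thin optional wrapper; only the HDF5/synthetic path
  is exercised by tests.
- Per-subject aggregation is left to the caller: `ExperimentResult` holds
  one accuracy per run, and multi-session averaging conventions vary.
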