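# Methods

This note documents the model, its parameters and defaults, the
numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Feature pipeline

**Centering.** Each frame's J×3 coordinate matrix has its per-column
(x, y, z) mean over joints removed. This makes all downstream features
exactly invariant to global translation of camera or body — and, as a
consequence, deliberately blind to global locomotion. The method is
therefore suited to in-place activities (gesturing, drinking,
writing), not to activities distinguished mainly by whole-body
displacement.

**Sub-volume sampling.** The centered 3 × J × T volume is sampled only
along the time axis: every window keeps the full spatial extent
(all three coordinates, all J joints), and windows of `r3` frames
start at every frame (stride 1). `r3` sets the temporal scale of the
learned primitives: too small and a window holds only a pose fragment,
too large and it spans whole activities. Defaults by capture rate:
11 frames at ~30 Hz, 13 at ~16 Hz, 21 for slower daily-activity
footage; `r3` is the one parameter worth adapting per corpus.

**Vectorization order.** Each window is flattened with the frame index
varying fastest, then joint, then coordinate, so that every run of
`r3` consecutive entries is one coordinate of one joint over the
window. Any fixed order would work for learning; what matters is that
training and prediction agree, so the layout tag is serialized inside
the model archive and checked on load.

## Dictionary learning

**Whitening.** One PCA whitener (mean removal, rotation to principal
axes, scaling by 1/√(λᵢ + ε), ε = 1e-5, full rank retained) is fitted
on the pooled training samples of *all* classes and stored with the
model. The same transform is applied before per-class learning and
before projection at coding time — a single stored transform is the
only self-consistent choice, and it keeps the projection step a pure
matrix-vector product.

**RICA objective.** Per class, W ∈ ℝ^{K×p} minimizes

    f(W) = (1/N) Σᵢ ‖WᵀW xᵢ − xᵢ‖² + (λ/N) Σᵢ Σₖ g(wₖ·xᵢ),

with g(u) = log cosh(u), a smooth L1-like penalty (evaluated stably as
|u| + log1p(e^{−2|u|}) − log 2). λ balances reconstruction against
sparsity of the responses; default λ = 0.5. Both terms are averaged
over samples so λ keeps its meaning as N varies. The analytic gradient

    ∇f = (2/N) (W X Rᵀ + W R Xᵀ) + (λ/N) tanh(W X) Xᵀ,  R = WᵀW X − X,

is unit-tested against central finite differences.

**Solver.** L-BFGS-B, gradient tolerance 1e-6, at most 200 iterations,
from a seeded init (Gaussian rows scaled by 1/√p, row-normalized). The
per-iterate objective trace is recorded and must be non-increasing
(line-search tolerance 1e-8). A non-finite objective aborts with a
diagnostic rather than returning garbage.

**Codebook.** Class dictionaries are stacked in sorted-label order;
each class's row range is stored so histogram blocks can be attributed
to classes. With full-scale settings (K = 400 words per class) the
codebook is over-complete (K·A > p); the reduced test preset
(K = 32) is not, which is expected and only warned about.

**k-means baseline.** Seeded k-means centroids (scikit-learn,
`n_init=10`) on the same whitened samples are a drop-in replacement
for the RICA words, isolating how much the learned sparse codes
contribute beyond a generic vocabulary.

## Sparse coding and histograms

Exact L1 sparse coding per sub-volume would be far too slow at dense
sampling rates; instead each whitened sample is projected onto the
codebook in one matrix-vector product and only the L
largest-magnitude coefficients are kept. Ties at the L-th magnitude
keep the lower index (stable, deterministic across runs); kept
coefficients that are exactly zero are pruned — a zero coefficient is
not an occurrence of a word. Per video, occurrences are counted per
word and L1-normalized (sum 1) so videos of different lengths are
comparable and the χ² kernel applies; normalization can be disabled.
The sparsity degree — the fraction of nonzero bins — is reported as a
diagnostic of how selective the encoding is.

## Classification

**χ² kernel map.** The additive χ² kernel k(x,y) = 2xy/(x+y) per bin
is approximated by a finite feature map so linear SVMs can be used.
The map is the standard homogeneous-kernel form: bin x ↦
(√(w₀x), √(w₁x)·cos(ω log x), √(w₁x)·sin(ω log x)) at order 1
(3 output dimensions per bin; x = 0 maps to zeros, matching
k(0,·) = 0). The classic coefficient rule samples the kernel spectrum
sech(πω) on a frequency grid, but with a single harmonic that rule
cannot get below ≈22% worst-case relative error on component ratios up
to 20, at any sampling period. The default coefficients are instead a
minimax relative-error fit of w₀ + w₁·cos(ωτ) to the kernel signature
sech(τ/2) on |τ| ≤ log 20 (w₀ = 0.6792841, w₁ = 0.3132581,
ω = 0.8331449), giving 0.75% worst-case error on that range. Outside
the calibrated ratio range the approximation degrades (as does the
spectrum-sampled map); order and period remain configurable, and
`KernelMapConfig.chi2_spectrum` provides the classic coefficients.

**SVMs.** One binary hinge-loss linear classifier per class
(one-vs-rest), objective reg·‖w‖²/2 + mean hinge with reg = 0.01,
solved by liblinear (C = 1/(reg·n), tol 1e-7, fixed random state for
determinism). Prediction is the arg-max of decision values; ties break
toward the earlier class in sorted order.

**Metrics.** Leave-one-subject-out ("new person") folds: train on all
subjects but one, test on the held-out subject. Per fold: confusion
matrix (rows = true class), accuracy = trace/total, macro precision =
mean over classes of TP/(TP+FP) (0 for never-predicted classes), macro
recall analogous. Reported numbers are unweighted means over folds.

## Handedness mirroring

To pool left- and right-handed subjects, a sequence can be reflected
across a body-symmetry plane: per frame, a total-least-squares plane
P1 is fitted through four role joints (left/right arm, left/right
hip — TLS via the smallest right singular vector of the centered
4-point matrix), and the mirror plane P2 contains the arm-midpoint to
hip-midpoint line with normal n₂ = normalize(n₁ × (m_h − m_a)).
Reflection q ↦ q − 2((q − m_a)·n₂)n₂ is an isometry and involution
(tested to 1e-10). Planes are fitted per frame rather than once per
video — a per-frame fit follows a subject who turns, and reduces to
the global fit when the subject is still. Degenerate geometry
(collinear role joints, coincident midpoints) raises an error rather
than producing an arbitrary plane.

## Synthetic data generator

Each class's motif is a sum of two sinusoids per joint per coordinate
(frequencies uniform in 0.5–3 Hz — the range of human gesture and limb
motion; phases uniform; amplitudes ~0.25 m), drawn once per class so
all subjects share the class signature. Subjects differ by a global
placement offset (σ = 0.5 m; removed by centering), an amplitude
jitter (±10%), and per-repetition iid Gaussian coordinate noise
(σ = 1 cm, typical consumer depth-sensor jitter). Optionally the last
subject is mirrored to emulate one left-handed participant. Draw order
is fixed (class motifs, then subject parameters, then per-repetition
noise) so a seed pins the dataset bit-exactly.

What this emulates: smooth, class-distinctive, quasi-periodic joint
trajectories with subject-level nuisance variation — the structure the
leave-one-subject-out protocol must generalize across. What it does
not: skeletal kinematic constraints (bone lengths are not preserved),
tracker dropout and gross joint-swap artifacts, aperiodic or
compositional activities, and within-class style variation beyond
amplitude scaling. Perfect synthetic recovery therefore validates the
pipeline's mechanics and separability behavior, not real-world
recognition rates.

The planted-dictionary generator produces samples that are sparse
non-negative combinations (coefficients uniform in [0.5, 1.5]) of
random orthonormal atoms plus Gaussian noise, with the atoms returned
as ground truth; recovery is scored by Hungarian-matched absolute
cosines between learned words and atoms.

## Problem sizes and determinism

The shipped experiments use the reduced preset K = L = 32 with the
default corpus (6 classes × 4 subjects × 2 reps, T = 120, J = 15,
r3 = 11 → p = 495, 110 windows per video), chosen so the full
leave-one-subject-out study runs in about a minute on one core; the
full-scale preset (K = L = 400) is the package default for real
corpora. All randomness (generator, dictionary init, k-means, SVM
solver) flows from explicit integer seeds; retraining with identical
inputs and seeds produces a byte-identical model archive, which is how
determinism is tested.

## Model archive

A single `.npz` of named arrays (codebook, whitener mean/transform,
SVM weights/biases) plus one JSON metadata block (format version,
class labels and row ranges, vectorization layout tag, kernel-map and
full pipeline config). Loading refuses a mismatched format version.

## Known limitations

- Centering discards global translation; activities distinguished by
  locomotion need different features.
- The RICA objective is non-convex; different seeds can reach
  different local minima (the descent property and recovery behavior
  are tested, global optimality is not claimed).
- The kernel-map calibration targets bin ratios up to 20; histograms
  with more extreme nonzero-bin ratios see larger approximation error.
- Dialect readers implement one documented layout per dataset family;
  exports that deviate (extra columns, different units) need the
  canonical CSV route.
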