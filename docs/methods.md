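# Methods

`kernelfuse` implements kernel-level fusion of two patient-matched data
views — a small mixed-type clinical record and a high-dimensional expression
profile — for binary outcome prediction, together with the surrounding
protocol: preprocessing, hyperparameter selection by leave-one-out AUC, and
a repeated stratified-holdout benchmark.

## Models

### LS-SVM baseline

A least-squares SVM replaces the hinge loss of the classical SVM with a
squared-error term, so training reduces to one linear solve.  With labels
y_i ∈ {−1,+1} and kernel K, the dual solution (b, β) satisfies the bordered
system

    [ 0   yᵀ        ] [ b ]   [ 0  ]
    [ y   Ω + I/γ   ] [ β ] = [ 1_N ],     Ω_ij = y_i y_j K(x_i, x_j),

and a point x is scored by f(x) = Σ_i β_i y_i K(x, x_i) + b.  γ > 0 trades
training error against smoothness.  The solver is a direct symmetric
factorization (`scipy.linalg.solve(assume_a="sym")`); with N up to a few
hundred there is no reason to iterate.  A residual check raises on
numerically singular systems instead of returning garbage.

### Weighted LS-SVM (the fusion classifier)

The fusion model treats the labels as regression targets of a function in
the clinical view's feature space, but weights the residual vector e by the
inverse covariance of the *expression* view's centered feature map:

    min_{v,e,b}  (γ/2) eᵀ (Φ₂cᵀ Φ₂c)⁻¹ e + (1/2) vᵀv
    s.t.         y = Φ₁cᵀ v + b·1_N + e.

Directions of high expression-view variance are cheap to leave unexplained;
directions in which the cohort's expression profiles barely vary are
penalized hard.  Eliminating v and e gives a dual system on the two
*centered* Gram matrices only:

    [ 0     1ᵀ                  ] [ b ]   [ 0 ]
    [ 1_N   Ω₁c + γ⁻¹ Ω₂c       ] [ α ] = [ y ],

scored as f(x) = Σ_i α_i [K₁(x,x_i) + γ⁻¹ K₂(x,x_i)] + b.  Two details are
deliberate and worth stating:

* the kernel block is **not** label-weighted (unlike the baseline's Ω); the
  labels appear as the right-hand side;
* the bias sits outside the α-weighted sum.  Writing it inside, as a naive
  reading of the dual classifier formula would have it, annihilates b
  because the first block row forces Σα_i = 0; the placement used here is
  the one consistent with the bias row of the linear system.

Evaluated on the training points the two-kernel score interpolates the
targets exactly (it reproduces the system rows); the clinical-kernel part
alone equals y − e with e = γ⁻¹Ω₂c α, which is the stationarity condition
and is what the test suite checks.  Generalization therefore rests entirely
on the out-of-sample kernel evaluations, and γ controls how much of the fit
is routed through the expression kernel (γ → ∞ recovers a clinical-only
interpolant; Ω₂ = I recovers bias-augmented kernel ridge at penalty 1/γ).

### Kernel GEVD and the score pipelines

Dropping the labels and maximizing the weighted projected variance instead
yields a generalized eigenproblem on the same pair of centered Gram
matrices:

    Ω₁c α = λ Ω₂c α.

The package solves the pencil (Ω₁c, Ω₂c + jitter·I) by the symmetric
reduction S₂^{-1/2} S₁ S₂^{-1/2} (jitter defaults to 1e-8·trace/N and is
always reported).  Patient scores are the products (centered clinical
kernel) × (dual eigenvectors): the training kernel gives training scores,
the centered test-vs-train kernel gives test scores.  "Projecting the data
onto the generalized eigenvectors" is ambiguous once feature maps are
implicit; the kernel-times-eigenvector reading is the one that produces
per-patient scores for both training and unseen samples and reduces to the
explicit linear projection for linear kernels, which is how the tests pin
it.  A linear-kernel LS-SVM on the scores completes the classifier (the
scores already carry the learned nonlinear structure; an RBF-on-scores
variant exists behind a flag).  With linear kernels on both views the same
code path *is* the classical GEVD pipeline.  Retained components default to
all eigenvalues above 1e-8 of the largest.

The underlying linear algebra (`linalg`) follows the inverse-square-root
construction: (BᵀB)^{-1/2} from an eigendecomposition with a pseudo-inverse
cutoff, the GSVD as the SVD of A(BᵀB)^{-1/2} with cosine–sine
normalization σ_a² + σ_b² = 1, and generalized eigenvalues (σ_a/σ_b)².
Exact simultaneous reconstruction of both factors requires BᵀB to be
invertible; the rank-deficient case errors unless explicitly allowed, in
which case identities hold on range(B) only.

## Kernels

* RBF: K(x,z) = exp(−‖x−z‖²/(2σ²)); σ is the bandwidth, per view (σ₁
  clinical, σ₂ expression — view 1 is always the clinical/weighted view,
  view 2 the expression/weighting view).
* Linear: plain inner products.
* Clinical (mixed-type): the per-variable average of range-normalized
  agreement (continuous and ordinal, using the *training* range) and exact
  match (nominal, with categories unseen in training scoring 0).  Ordinal
  variables use their level codes in the continuous formula — ordering is
  respected, level gaps are approximated as equal.  Zero-range variables are
  excluded with a warning.  PSD-ness of this kernel is checked per instance
  and repaired with a minimal diagonal jitter if violated (logged).

Centering is the feature-space map φ(x) → φ(x) − μ̂ with μ̂ the training
mean: Kc = K − rowmean − colmean + grandmean on the training block, and the
same transformation with training column means and training grand mean on
test-vs-train cross kernels — the only choice consistent with out-of-sample
prediction.  Square kernels are symmetrized as (K+Kᵀ)/2 after computation
to kill round-off asymmetry.

## Preprocessing

* Patients with any missing clinical value are excluded from all views and
  the labels (no imputation).
* Genes are filtered by training variance: variances below the 10th
  linear-interpolation percentile are removed; ties at the threshold are
  kept.  The filter runs on the raw training values *before*
  standardization — after z-scoring every gene has unit variance and the
  filter would select on round-off noise.
* Each remaining gene is z-scored with training mean and sd; test columns
  use the training statistics.  Numerically constant training columns are
  dropped with a warning.
* The clinical matrix is z-scored when fed to RBF or linear kernels; it is
  *not* z-scored for the mixed-type clinical kernel, which normalizes by
  training ranges itself.

All of these are recomputed inside every cross-validation fold and every
benchmark repetition from that fold's training part alone.  A sentinel test
asserts that perturbing a held-out sample changes nothing about the fold
model that scores it.

## Hyperparameter selection

A grid over (σ₁, σ₂, γ) is scored by the AUC of pooled leave-one-out
held-out decision values on the training set (stratified p-fold is available
when LOO is too slow).  Defaults: γ ∈ {2⁻¹⁰, 2⁻⁸, …, 2¹⁰}; bandwidths at
{0.25, 0.5, 1, 2, 4} × the median pairwise distance of the preprocessed
training view.  Ties are broken deterministically toward the smallest γ,
then the largest σ₁, then σ₂ — preferring smoother, more regularized
models.  Single-view models search (σ, γ); the GEVD pipeline searches only
the downstream γ; the kernel-GEVD pipeline searches (σ₁, σ₂, γ_downstream)
jointly, since no separate criterion for its bandwidths is available.
Fold-level Gram matrices are cached (they do not depend on the grid point),
which keeps a full-grid LOO at N ≈ 80 under a second per method.

## Benchmark protocol

Per repetition: a stratified split assigns round(2/3 · n_class) of each
class to training (the rounding rule is the documented convention);
the identical split is shared by all methods; each method tunes on the
training part only, refits at its selected parameters, and is scored by test
AUC on continuous decision values (never on sign outputs).  Repetition seeds
default to 1…100 and are recorded for exact reruns.  Methods are compared
with a two-sided paired Wilcoxon signed-rank test against the weighted
LS-SVM.  Zero differences are dropped; for ≤ 25 pairs the exact null
distribution is computed by convolution over doubled midranks (equivalent to
enumerating all 2ⁿ sign assignments, including under ties); beyond that the
normal approximation with tie correction is used.  AUC is the Mann–Whitney
statistic with midrank tie handling.  Hyperparameters are re-tuned in every
repetition (the leakage-safe reading; a tune-once mode would be cheaper but
lets one training set inform the others' models).

## Synthetic cohorts

The generator emulates mid-sized breast-cancer prognosis cohorts: defaults
are 150 patients (study runs use 120), 2000 genes, 7 clinical variables
(2 continuous, 2 ordinal, 3 nominal), a 30% positive class, 40 informative
genes at a standardized shift of 0.7, 4 informative clinical variables at
strength 0.9, unit noise.  Ordinal variables discretize shifted latent
Gaussians at equal-probability cutpoints (preserving order, matching the
clinical kernel's semantics); nominal variables draw from class-tilted
category weights; missing entries, when requested, are masked uniformly in
the clinical view only.  Positive-class count is round(fraction·n), exactly.
One integer seed spawns deterministic sub-streams per concern, so datasets
are bitwise reproducible.

What the generator does **not** emulate: microarray platform artifacts
(probe effects, intensity-dependent noise), gene–gene correlation structure,
informative missingness, or calibrated clinical effect sizes.  Passing
benchmarks on these cohorts therefore demonstrates correctness of the
machinery and the qualitative value of fusion when complementary signal
exists — not expected AUC levels on any real cohort.

## Study-scale runs and problem sizes

The shipped study configuration (tests and `scripts/acceptance.py`) uses
n = 120 with the generator defaults above, 100 benchmark repetitions for the
fusion-vs-single-view comparison, 25 permuted-label repetitions for null
calibration, and a reduced tuning grid (bandwidth multipliers {0.5, 1, 2},
γ ∈ {0.01, 1, 100}).  These sizes give stable Monte-Carlo estimates (the
standard error of a mean AUC over 100 repetitions is ≈ 0.005 here) while
keeping a full five-method run in the minutes range on one core.

## Numerical choices and edge cases

* Bordered systems: direct symmetric solve, relative-residual guard of
  1e-6 (raises with a condition estimate rather than returning a bad fit).
* GEVD jitter: 1e-8·trace(S₂)/N by default, always reported; eigenvector
  signs fixed by making each vector's largest-magnitude component positive.
* sign(0) maps to +1 in label predictions (documented convention).
* Degenerate folds (a training part losing an entire class) are skipped
  with a warning; the CV AUC is computed over the scored samples.
* A benchmark method failing on more than 10% of repetitions aborts the run
  with a diagnostic rather than silently reporting a biased mean.

## Known limitations

* The clinical kernel lacks a general PSD proof; the per-instance check +
  jitter repair is pragmatic, not elegant.
* The GSVD does not implement the full rectangular-diagonal factorization
  for rank-deficient weight matrices — only the invertible-weight path the
  fusion method actually needs, plus a range-restricted pseudo-inverse
  fallback.
* LOO is done by honest refitting (O(N) solves per grid point); closed-form
  LOO shortcuts exist for LS-SVMs but are deliberately out of scope —
  correctness first, and the full refit is what the leakage sentinel can
  vouch for.
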