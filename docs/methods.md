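# Methods

## Observer model

A yes/no psychophysics trial is modeled as the sign of a noisy linear
comparison between the presented stimulus and a latent template. Stimuli
are binary noise images: each of the m pixels is drawn i.i.d. Bernoulli(0.5)
in {0, 1}. The template x is a grayscale image with intensities in [0, 1].
The decision variable on trial i is

    z_i = (φ_i − φ̄) · (x − x̄),

where φ̄ = 0.5 per pixel is the stimulus-ensemble mean and x̄ the template
mean, and the response is y_i = sign(z_i + ε_i) ∈ {−1, +1}, with
sign(0) = +1 as a fixed tie-break.

**Why center.** With raw {0,1} stimuli and a nonnegative template the raw
inner product φ_i · x is strictly positive for any non-degenerate template,
so an uncentered sign rule answers "yes" on every trial and carries no
information. Centering both factors makes the noiseless decision variable
symmetric around zero (empirically ~50% "yes"), which is the regime the
yes/no paradigm operates in. A regression test asserts both facts.

**Response coding.** Internally responses are always −1/+1; the
conventional 1 (yes) / 0 (no) coding is accepted at I/O boundaries and
mapped on load. Sign coding is what makes the estimators below literal
difference-of-sums, and the 1-bit sparse estimator presumes it.

## Noise mechanisms

`NoiseSpec(sigma, mechanism)` supports three observer-noise models:

- **flip** (default): each noiseless response is independently negated
  with probability σ/100 — σ is exactly the expected percentage of
  incorrect responses. σ = 50 is an uninformative (random) responder and
  σ = 100 a perfectly contrarian one. Flip counts are Binomial(l, σ/100).
- **additive_gaussian**: ε_i ~ N(0, σ) with σ read as the noise
  *variance* on the decision-variable scale. The induced error rate
  depends on the template through the scale of z (std ≈ ½‖x − x̄‖); for
  the canonical 50×50 letters it is ≈ 12% incorrect at σ = 25 and ≈ 17%
  at σ = 50. This is the mechanism the noisy simulation studies use: it
  produces observers that are moderately and heavily degraded yet still
  informative, which is the regime in which comparing estimators under
  noise is meaningful.
- **calibrated_gaussian**: additive Gaussian noise whose scale is solved
  (by bracketed root finding on the exact flip-rate expression) so that
  the induced sign-flip rate equals σ percent. Additive symmetric noise
  cannot flip more than half the responses, so this mechanism requires
  σ < 50.

The three are kept separate because "percent incorrect" and "additive
decision noise" are different physical statements that coincide only
approximately: any additive mechanism saturates at a 50% error rate, so a
percent-scale σ of 50 cannot be represented additively, while a variance-
scale σ has no fixed percent interpretation across templates.

## Estimators

### Reverse correlation

The classification image is the mean centered stimulus on "yes" trials
minus the mean on "no" trials. Two variants are exposed: Φ_cᵀy normalized
by the trial count (proportional to the mean difference for balanced
responses; the scalar is irrelevant because every metric used — r² and
sign prediction — is invariant to positive rescaling), and the full
generalized-inverse regression (Φ_cᵀΦ_c)⁺Φ_cᵀy for small problems. If all
responses share one sign the mean difference is undefined; the estimator
warns and falls back to the Φᵀy form.

### 1-bit compressive sensing (closed form)

With Ψ the orthonormal 2D DCT-II basis (row-major pixel flattening;
basis columns ordered by (row frequency, column frequency) row-major) and
Θ = Φ_cΨ the sensing matrix on centered stimuli, the estimator is

    v = m⁻¹ Θᵀ y,   ŝ = P(v) / ‖P(v)‖₂,   x̂ = Ψ ŝ.

v is computed through the fast DCT of Φ_cᵀy — Θ is never materialized, and
Φ_cᵀy itself is computed as Φᵀy − 0.5·Σy so the centered float matrix is
never formed either. The fast path agrees with the dense-matrix path to
1e−8 (tested). ŝ always has unit norm and at most γ nonzeros.

**Thresholding operator P.** Two modes, both keeping the γ
largest-magnitude entries of v (ties at the threshold go to the lower
index):

- *soft* (default): survivors are shrunk toward zero by λ, set to the
  (γ+1)-th largest magnitude (λ = 0 when γ ≥ m). This is the analytic
  minimizer of −m⁻¹sᵀΘᵀy + λ‖s‖₁ over the unit ball with λ derived from γ,
  so the solution is exactly γ-sparse; λ is never set directly.
- *hard*: survivors keep their values (pure top-γ selection).

The choice matters more than it looks. Soft shrinkage by the (γ+1)-th
magnitude is a denoiser: at large γ the threshold sits at the noise floor
of v, so performance degrades only slowly past the optimum and small-
sample reconstructions are markedly better (at n = 1,000 on the 50×50 "S",
soft r² ≈ 0.70 vs hard ≈ 0.49). Hard selection is more aggressive and
makes held-out prediction accuracy peak at smaller γ (γ ≈ 64 vs ≈ 512 for
the shipped template at n = 10,000). Soft is the default because it is the
exact penalized-objective solution and dominates on reconstruction
quality; hard is retained both as the cleaner structural reduction
(γ = m in hard mode reproduces the reverse-correlation direction exactly —
tested to cosine similarity 1 ± 1e−8) and because selection-only
thresholding is what some published implementations of this estimator
appear to have used, visible in where their γ optimum lands.

### Sparse GLM comparator

L1-penalized logistic regression of the sign-coded responses on the
DCT-transformed centered stimuli: minimize Σ log(1 + exp(−y_i(Θs)_i)) +
λ‖s‖₁. Solved by monotone FISTA (accelerated proximal gradient with
backtracking line search and momentum restart on overshoot), applying Θ
and Θᵀ through the fast DCT. Convergence: relative objective change below
1e−6 (default), max 5,000 iterations; hitting the cap flags
`converged=False` without raising. The image-domain reconstruction is
reported unit-normalized for comparability. λ is chosen by the same
held-out prediction-accuracy search used for γ, over a log-spaced grid
spanning 1e−2–1e2 times √n (the gradient scale at s = 0).

Auxiliary nuisance-regressor terms that appear in one published sparse-GLM
implementation are interface artifacts of that package, not part of the
model, and are omitted.

**A deliberate deviation from published comparator behavior.** Published
results obtained with an iterative fixed-point sparse-GLM solver report
that the GLM's advantage over reverse correlation collapses under response
noise. Our cleanly converged proximal-gradient fit of the same penalized
likelihood does not reproduce that collapse — its advantage persists or
grows under noise (measured: +0.21 r² advantage noiseless, +0.27 at heavy
noise, 20×20 template, n = 2,000). The plausible reading — consistent with
the original authors' own speculation — is that the published fragility
was a property of that specific optimizer, not of the penalized-likelihood
model. The test suite therefore asserts the defensible directions (noise
degrades every estimator; the GLM matches or exceeds the closed form at
large noiseless n) and does not assert the collapse.

## Sparsity-level selection

- **Held-out protocol (simulation):** fit the sparse estimator once per γ
  on a training session of n trials (v does not depend on γ, so one data
  pass serves the whole grid), then simulate n_heldout_sets fresh sessions
  from the same observer and score each γ's reconstruction by balanced
  prediction accuracy; select the γ with the best mean. Defaults: grid
  {2, 4, …, 2048}, 8 held-out sets of n trials each.
- **Nested protocol (measured data):** partition trials into k seeded
  random slices; per outer fold, train on k−2 slices, select γ on one
  validation slice, score the winner once on the withheld test slice;
  rotate so every slice serves as the test slice once; the final γ is the
  mode of per-fold winners. The selection path never sees test-slice
  responses (enforced by construction and asserted through an
  instrumentation hook in tests). Default grid {2, …, 1024}, k = 10.

All ties — per-γ accuracy ties and modal ties — break toward smaller γ
(the more parsimonious model). γ values whose fit degenerates (thresholded
vector identically zero) are excluded from the argmax rather than scored
zero.

## Evaluation

- **Template r²:** squared Pearson correlation over vectorized pixels,
  defined only in simulation. Sign-blind (an anti-correlated estimate also
  scores 1); the signed correlation is exposed separately. Invariant to
  affine rescaling of the estimate. Errors on constant images.
- **Response prediction:** a reconstruction predicts held-out responses
  through the noiseless sign rule (ε = 0). Predicting with noise would
  deflate all methods equally while adding variance, so determinism is
  preferred.
- **Balanced accuracy:** mean of true-positive and true-negative rates
  (delegated to scikit-learn behind the package surface, with an explicit
  error naming the missing class on single-class inputs).
- **k-fold CV:** per fold, fit on k−1 folds, predict the held-out fold;
  predictions pooled over all folds are scored once (pooling, rather than
  averaging per-fold scores, matches how such protocols are usually
  described and is stabler for small folds). Folds are seeded random
  partitions by default with a contiguous-block option. Single-class folds
  are flagged but still contribute to the pooled score.

A thin paired-t-test wrapper (scipy) is provided for cross-subject
accuracy comparisons; it is bookkeeping, not part of the method.

## Synthetic-data generator

The generator emulates the canonical letter-detection experiment: a 50×50
grayscale letter template, binary equiprobable noise stimuli, and the
centered-sign observer above. The canonical "S" and "K" templates ship as
fixed plain-text rasters (antialiased, horizontally stretched lowercase
DejaVu Sans glyphs scaled into [0, 1]) so that results never depend on the
host's fonts; other letters and sizes are rasterized at run time by the
same recipe. Dot/disc templates support impulse-like representations.

What the generator does **not** emulate: real observers drift, lapse, and
use criteria that shift over a session; real templates are not literally a
letter raster, and their sparsity in the DCT basis is an assumption, not a
given; stimulus ensembles in real studies are sometimes filtered or
windowed rather than i.i.d. binary. Passing tests therefore demonstrate
correctness and the claimed relative behavior of the estimators under the
stated model — not that any particular human study will show the same
effect sizes.

One consequence deserves emphasis: the location of the optimal γ is a
property of the template raster's DCT spectrum interacting with the trial
count. The shipped "S" concentrates 92% of its centered energy in its top
64 coefficients but has a heavy enough tail that, at n = 10,000 noiseless
trials with the soft-thresholded estimator, held-out accuracy keeps
improving up to γ ≈ 512. A smoother raster, a smaller n, heavier response
noise, or hard-mode selection all pull the optimum down toward tens of
coefficients. The γ grid-search machinery is agnostic to all of this; it
reports whatever the data say.

## Numerical and design choices

- Vectorization is row-major everywhere; the DCT is the orthonormal
  type-II variant in each dimension, so ΨᵀΨ = I to machine precision.
- sign(0) = +1; threshold ties to lower index; γ ties to smaller γ.
- Every stochastic artifact takes one integer seed; replicate r of a
  battery uses a deterministic child seed derived via NumPy's SeedSequence
  (kept below 2³¹). Identical config + seed ⇒ bit-identical results
  (tested on the experiment driver).
- The stimulus matrix is stored as int8 with a lazily cached float64 copy
  so repeated matrix–vector products stay on the BLAS fast path; products
  against centered stimuli use the algebraic identity
  Φ_cᵀr = Φᵀr − 0.5·Σr instead of materializing a centered copy.
- Experiment drivers score prediction accuracy on a fresh simulated test
  set of 2,000 trials per cell (the protocol only requires "a novel data
  set"; 2,000 gives ±0.011 s.e. on an accuracy near 0.85, small relative
  to between-replicate spread).
- Confidence intervals over replicates are Student-t.
- Reduced problem sizes in the test suite (12×12–20×20 templates, hundreds
  to a few thousand trials) were chosen as the smallest scales at which
  each qualitative property is stable across seeds; the canonical 50×50 /
  n = 10,000 configuration is exercised by the acceptance checks and the
  examples.

## Known limitations

- The closed-form estimator returns a direction (unit norm); absolute
  template contrast is unidentifiable from signs alone.
- The DCT-sparsity prior biases reconstructions toward smooth, compressible
  images; genuinely non-sparse templates will be over-smoothed.
- The GLM solver is first-order; at very small λ on large problems it can
  need thousands of iterations (it flags rather than fails).
- Balanced accuracy on heavily imbalanced sessions has high variance in
  small folds; pooling mitigates but does not remove this.
- The generalized-inverse reverse-correlation form materializes the
  centered stimulus matrix and is intended for small problems only.
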