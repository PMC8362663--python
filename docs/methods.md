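# Methods

`nirscgan` implements a complete fNIRS ternary motor-task classification
pipeline with conditional-GAN data augmentation: synthetic recording
generation, hemodynamic signal conditioning, Gramian-angular-field image
encoding, adversarial synthesis of class-labeled images, CNN
classification, and an augmentation-fraction evaluation protocol.  This
note records the model choices, the numerical conventions, and what the
synthetic benchmark does and does not establish.

## Synthetic recordings

The generator emulates a finger/foot-tapping block design measured by a
20-channel continuous-wave fNIRS montage (channels 0–9 tagged left
hemisphere, 10–19 right; optode geometry is out of scope — only
laterality matters downstream).  Trials are balanced across the three
classes (RHT/LHT/FT), presented in seeded random order with a 30 s mean
inter-trial interval jittered uniformly by ±5 s.

**Evoked responses.** Hand taps drive the canonical double-gamma
hemodynamic response function (peak 6 s, undershoot ratio 1/6, maximum
normalized to 1) on contralateral ΔHbO with gain `effect_amplitude`
(default 1.0 µM-scaled units) and a 5% ipsilateral spillover; ΔHbR is
−0.35 of the ΔHbO response.  Foot taps produce a bilateral ΔHbO decrease
(gain −0.8) with a ΔHbR increase, using a *slower* kernel (peak 8 s).
The slower kernel reflects that the medial foot representation reaches
lateral optodes diluted and temporally smeared; it also matters
mathematically: the GASF encoding is invariant under a global sign flip
of the series (see below), so an exactly mirrored foot response would be
indistinguishable from a hand response in image space — a degeneracy real
data does not have.

**Noise.** Per channel: cardiac (default 1.2 Hz, amplitude 0.2),
respiratory (0.3 Hz, 0.3), Mayer waves (0.1 Hz, 0.3) with random phases,
a DC offset plus ~0.005 Hz wander (scale 0.5), and white noise (0.1).
Defaults put the evoked response at 10× the white-noise amplitude — a
clean, separable benchmark, deliberately easier than multi-subject real
data.  Sampling rate defaults to 10 Hz (satisfies Nyquist for cardiac
noise; 300 samples per 30 s epoch).  `generate_recording` is a pure
function of its config, seed included.

## Preprocessing

* Zero-phase band-pass: 3rd-order Butterworth, 0.01–0.1 Hz, applied
  forward–backward (`sosfiltfilt`).  The double pass squares the
  magnitude response (≥ 40 dB at DC and at cardiac frequencies) and
  cancels phase, preserving epoch timing.  Note the Mayer band sits at
  the upper band edge, where a 3rd-order design only attenuates ~6 dB;
  this is a property of the standard 0.01–0.1 Hz passband, not a defect.
* Epochs span [−2 s, +28 s) around each onset, half-open at the end, so
  10 Hz gives exactly 300 samples.  Events without full margins are
  skipped and logged.
* Baseline correction subtracts the per-channel mean over [−1 s, 0 s).
* Window-mean features: mean ΔHbO and ΔHbR per channel over 0–5, 5–10
  and 10–15 s (channel-major, HbO-before-HbR, window-minor ordering);
  20 channels give 120 features.
* Standardization uses the population (divide-by-n) SD, floored at 1e-8,
  and is fitted on training rows only.
* Kernel PCA (scikit-learn's centered-kernel eigendecomposition; default
  RBF, γ = 1/n_features, 20 components) with a deterministic sign
  convention: each component's largest-magnitude training loading is
  made positive.
* Channel selection scores each channel by the one-way ANOVA F statistic
  of its ΔHbO window means across the three classes, summed over
  windows; ties break to the lowest index.  A model-free statistic was
  chosen over classifier-specific feature importances because the latter
  depend on an arbitrary baseline model.

All sample windows are half-open `[start, end)` so the 0–5/5–10/10–15
seams never double-count a sample.

## GASF encoding

The post-onset 0–28 s segment of the selected channel (default ΔHbO; the
first kernel-PCA component series is available via `encode.source:
kpca1`) is compressed to 28 points by piecewise aggregate approximation
*before* the field is computed — compressing the series rather than the
image avoids resampling artifacts in the Gram structure.  The series is
affinely rescaled to [−1, 1] (a constant series maps to zero, logged),
lifted by φ = arccos(x̃), and G_ij = cos(φ_i + φ_j) = x̃_i x̃_j −
√(1−x̃_i²)√(1−x̃_j²); pixels are (G+1)/2.  Known property: G(−x̃) = G(x̃),
so the encoding discards one global sign — consumers of single-channel
GASF images should not expect polarity information.

## Conditional GAN

Generator: z ∈ R¹⁰⁰ ~ N(0, I) through a dense layer reshaped to
7×7×128 (batch-normalized, ReLU), concatenated with a 7×7 channel from a
label embedding (3 → 50 → 49), then three 4×4 transposed convolutions —
stride 2 (7→14), stride 2 (14→28), stride 1 refinement — with batch
normalization and ReLU except for the tanh output.  Discriminator: the
image plus a 28×28 label-embedding channel through two stride-2 4×4
convolutions (LeakyReLU 0.2) and a dense layer to a single logit.
Training alternates one discriminator step (real batch target 1,
generated batch target 0) with one non-saturating generator step, Adam
(lr 2e-4, β₁ = 0.5) for both, batch 32, default 600 steps.  The recorded
`d_loss` is exactly −V̂(G, D), the negated empirical value function.

Networks are built on the package's own numpy layer toolkit
(`nirscgan.nn`): im2col/col2im convolution lowering, transposed
convolutions implemented as the exact adjoint of the strided convolution
with explicit output cropping (which lets 4×4 kernels hit 28×28 at
stride 1), analytic backward passes verified against finite differences,
float32 working precision.  Training is bit-reproducible per seed.

Synthesis allocates `round(fraction × n_real)` images equally across
classes, remainder round-robin by class code; generated pixels map from
tanh range to [0, 1] and carry `provenance="generated"` permanently.  A
mean pairwise MS-SSIM above 0.98 within any generated class raises a
mode-collapse warning (never an error).

At desk scale (hundreds of CPU steps) the image discriminator does not
reach the Nash region — it still separates real from generated reliably.
The generated images are nonetheless class-informative (a
nearest-centroid oracle recovers the requested class well above chance),
which is the property augmentation actually needs.  The "D → 1/2 at
equilibrium" prediction is verified where it provably holds: a
discriminator trained on matched distributions (p_g = p_r) in the 1-D
toy harness, which also confirms D*(x) = p_r/(p_r + p_g) to MAE < 0.05.

## CNN classifier

Eighteen counted units: input; 4 × (3×3 convolution, batch norm, ReLU,
2×2 max pool) with 16/32/64/128 filters (28→14→7→3→1); flatten; two
dense layers (128, 64) each with dropout; 3-way softmax.  Categorical
cross-entropy plus an l2 kernel penalty (λ·Σw² on convolution and dense
kernels only), RMSprop (lr 1e-3), batch 4.  The learning rate halves
after 5 epochs without validation improvement; training stops after 10
(best weights restored).  Filter counts and dense widths were chosen so
four pooling halvings fit a 28×28 input; all are configurable, and a
seeded uniform random search over dropout/optimizer/kernel-size/widths
is provided.

Validation and test sets are structurally protected: any dataset
containing `provenance="generated"` images is rejected at every
evaluation entry point.

## Augmentation sweep

The CGAN is trained once on the real training images.  For each fraction
f ∈ {0, 0.1, …, 1.1} the sweep synthesizes round(f × 90) class-balanced
images, trains the classifier on real ∪ generated, and evaluates on the
30 real test images (10 per class).  Regularization relaxes linearly
with f — l2 from 0.5 at f = 0 to 0.01 at f = 1.1, dropout 0.4 → 0.2 —
because the effective training set grows; the per-row (l2, dropout) pair
is logged in every report.  A failed step records a failure row and the
sweep continues.

## Problem sizes and determinism

The default desk protocol simulates 40 trials per class (120 epochs),
splits off a stratified 30-image test set, trains the CGAN for 600 steps
and each of the 12 classifier fits for up to 60 epochs with early
stopping; the whole sweep is a single-CPU, minutes-scale computation.
One global seed fans out to the simulator, the split, CGAN training,
synthesis and every classifier fit, so a run is reproducible
end-to-end, including artifact content hashes.

## What the benchmark shows — and does not

Passing the synthetic sweep demonstrates that the pipeline is wired
correctly: encoding preserves class structure, the CGAN emits
class-conditional, diverse images, the classifier learns them, and
augmentation does not corrupt evaluation.  It does *not* demonstrate
real-data effect sizes: the benchmark has a single simulated
"subject", no motion artifacts, no inter-subject variability, and a
10× evoked-to-noise ratio, so near-ceiling accuracies are expected and
the benefit of augmentation is correspondingly compressed.  Metric
recomputations from the reference confusion matrices (80.00%, 96.67%,
per-class precisions) are exact arithmetic and independent of the
synthetic conditions.

## Known limitations

* Single-channel encoding; no multi-channel image fusion.
* GASF discards the global sign of each epoch series.
* No motion-artifact correction, short-separation regression, or raw
  optical-density conversion — inputs are assumed to be ΔHbO/ΔHbR.
* MS-SSIM on 28×28 images truncates to 2 of the standard 5 scales
  (11×11 window), with exponents renormalized.
* The image-domain GAN is trained far from asymptopia; its diagnostics
  (discriminator accuracy, MS-SSIM diversity) should be read as health
  checks, not convergence certificates.
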