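# Methods

## The model

`tumorsig` implements an *implicit autoencoder* (IAE): a denoising
autoencoder whose reconstruction quality and latent distribution are both
constrained adversarially rather than through explicit likelihoods.

Four networks are trained jointly on normalized CT patches
`x ∈ [−1, 1]^{96×96}`:

* **Encoder** `E` — fully convolutional, five stride-2 blocks (96 → 48 →
  24 → 12 → 6 → 3), leaky-ReLU activations with instance normalization on
  the middle blocks, a linear final convolution. It maps a patch onto a
  spatial latent grid `z ∈ R^{3×3×C}` (default `C = 128`). The channel
  vector at one grid cell is the *digital signature* of the image region
  under that cell's receptive field (cell `(i, j)` ≈ the 32×32 block
  centered at `((i+½)·32, (j+½)·32)`).
* **Decoder** `G` — the mirrored transposed-convolution stack ending in
  `tanh`, so outputs stay in `[−1, 1]`.
* **Data discriminator** `D` — four stride-2 convolutions plus two fully
  connected layers, judging real patches against decoder outputs.
* **Latent regularizer** `R` — three fully connected layers judging
  encoder outputs against i.i.d. `N(0, 1)` samples, pulling the aggregate
  latent posterior toward a standard normal prior.

Per batch, three updates run in order with non-saturating binary-logistic
objectives (verdicts clamped to `[1e−7, 1 − 1e−7]`):

1. discriminator: `−E[log D(x)] − E[log(1 − D(G(E(x̃))))]`,
2. regularizer: `−E[log R(z_prior)] − E[log(1 − R(E(x̃)))]`,
3. one joint encoder+decoder step on
   `λ·E|x − G(E(x̃))| − E[log D(G(E(x̃)))] − E[log R(E(x̃))]`,

where `x̃ = x + ε`, `ε ~ N(0, σ²)` with `σ² = 0.1` (denoising input; never
applied at inference) and `λ = 500`. With these defaults the weighted L1
term accounts for the large majority of the decoder objective, which is
what keeps reconstructions anchored to the input while the adversarial
terms sharpen texture. Augmentation during training is a uniform rotation
from {0°, 90°, 180°, 270°} plus independent up–down/left–right flips with
probability ½ each; arbitrary-angle rotations are deliberately excluded
because they interpolate pixels and alter the intensity statistics.

Optimization is Adam (β₁ = 0.9, β₂ = 0.999) for 400 epochs at learning
rate 2·10⁻⁴, dropped to 2·10⁻⁵ after epoch 200, batch size 32. The update
order (critics first, then one joint generator step against the updated
critics) and the unconditional discriminator are implementation choices;
`ModelConfig.critic_lr_scale` (default 1 — critics and generator share a
rate) exposes two-time-scale training if a critic needs to learn faster.

Everything is implemented in NumPy (module `tumorsig.nn`): im2col-based
strided convolution and its adjoint transposed convolution, instance
normalization, dense layers, and Adam, all with hand-derived backward
passes that are verified against central finite differences in the test
suite. Networks compute in float32; float64 is used in the gradient
checks.

## Latent editing

`latent_ops` implements the signature edits. A `CellEdit` names a target
cell, a source cell and a blend weight `α ∈ [0, 1]`; editing replaces the
target's channel vector by `(1 − α)·target + α·source`. A pure swap is
`α = 1`. Decoding an edited latent yields a *synthetic* patch — a lesion
is inserted by swapping a lesion signature into a normal patch's cell and
removed by the reverse swap; sweeping `α` grades the lesion in and out.
Because receptive fields of neighboring cells overlap (kernel 4,
padding 1), an edit mainly affects the corresponding 32×32 region but
blends smoothly into its surround; `kernel_size = 2` (no padding) builds
an encoder with exactly non-overlapping receptive fields, used in tests
as a locality probe.

## The phantom generator

The phantom emulates portal-venous liver CT at the level the pipeline
needs: per-patch parenchyma texture `N(110, 10²)` HU spatially smoothed
to a ~6 px correlation length, additive white acquisition noise
`N(0, 8²)` HU, and — in lesion patches — one filled disc of hypodense
tissue `N(45, 10²)` HU with radius uniform in [8, 20] px, a 1 px feathered
rim, placed uniformly over positions where the disc fits inside the
patch. Both tissues sit inside the display window `[−110, 190]` HU and
the 65 HU contrast is well above the 40 HU validation floor. Volumes use
the same tissue model with a cylindrical elliptical liver (semi-axes 0.32
and 0.38 of the slice extent) and spherical lesions, background at
−30 HU. All randomness flows through one counter-based Philox stream per
call, so outputs are bit-reproducible from `(spec, seed)`.

These intensity defaults are artifact conventions: no intensity
statistics of real lesions were estimated, and the phantom has no
vessels, no multi-phase kinetics, no irregular lesion margins and no
inter-patient variability. Passing phantom tests therefore demonstrates
that the machinery works (encoding separates the two tissue classes,
edits move decoded intensities the right way), not that clinical-grade
realism is achieved on real scans.

## Preprocessing

Axial slices are cut by a sliding 96×96 window on a 48 px stride
(top-left anchored, 0-based, windows that do not fit are dropped).
A window is kept if ≥ 25% of its pixels are liver — "contains liver
tissue" needs a quantitative floor, and a quarter patch keeps content
meaningful — and labeled lesion if it covers ≥ 10 lesion-mask pixels
(a single noisy mask pixel should not flip a label). Intensities are
clipped to `[−110, 190]` HU and mapped affinely onto `[−1, 1]`; no
resampling and no further normalization. Both thresholds are exposed in
`PatchExtractionConfig`.

## Signature classification

Flattened latents (row-major cells, then channels; 3·3·128 = 1152
features at full scale) feed four out-of-the-box scikit-learn
classifiers: `LinearSVC`, `RandomForestClassifier(n_estimators=1000,
max_depth=10)`, `MLPClassifier` and `GaussianNB`, all other parameters at
library defaults. Evaluation is stratified 10-fold cross-validation
(stratification prevents single-class folds on small data); each fold
reports accuracy, sensitivity (lesion = positive), specificity and ROC
AUC, aggregated as mean ± 2 standard deviations across folds. Decision
thresholds are each classifier's native label rule; AUC uses the margin
(`decision_function`) where available and the posterior otherwise. PCA
for visualization is mean-centered only — the latent space is already
pulled toward `N(0, 1)`, so per-feature scaling is unnecessary.

## Reader-study statistics

A rater's score over `n` two-alternative items is Binomial(n, p) with
chance at `p = 0.5`. The exact two-sided p-value doubles the smaller tail
probability and caps at 1; at `p₀ = 0.5` this coincides with the
equal-tailed exact test. The *chance interval* at level α collects the
accuracies whose counts are not rejected: the upper endpoint is the
largest `k/n` with all p-values from `n/2` up to `k` at least α, the
lower endpoint its mirror `1 − k/n`; bounds are inclusive. For `n = 40`,
α = 0.05 this gives `[0.35, 0.65]` (27/40 = 0.675 has p ≈ 0.038 < 0.05;
26/40 = 0.65 has p ≈ 0.081). An ensemble rater is the per-item majority
vote (odd rater counts cannot tie; even counts require an explicit tie
rule). Inter-rater agreement is Fleiss' kappa on the item × category
count table (undefined and reported as NaN when every rating falls in a
single category). Decision times are compared with Welch's two-sided
t-test (a pooled-variance flag exists); no multiple-comparison correction
is applied, matching the study design. The tail-doubling p-value is
implemented directly on scipy's binomial distribution because scipy's
`binomtest` uses the minimum-likelihood two-sided method, which defines a
different interval.

## Desk-scale experiments

Full-scale training (hundreds of thousands of real patches, 400 epochs)
is a GPU workload. `pipeline.desk_scale_config` fixes a CPU-scale variant
used by the test suite and the worked examples: 2,000 phantom patches
(1,000 per class), latent 3×3×16, base width 8, batch 32, 12 epochs with
the learning-rate drop at the halfway point, rates 10⁻³ → 10⁻⁴ (5× the
full-scale rates — the far smaller network tolerates it, compensating for
the ~30× shorter schedule). On one CPU a run takes a few minutes and
reproduces the qualitative full-scale behavior: reconstruction error well
below the mean-image baseline, cross-validated linear-SVM accuracy on
flattened latents above 0.9, center-cell lesion insertion/removal moving
the edited region's mean intensity in the expected direction in ≈100% of
phantom pairs, and monotone interpolation sweeps.

Under this short schedule the latent prior is only partially matched: the
pooled latent mean is near zero and most per-dimension variances fall in
[0.3, 3], but individual dimension means still carry biases of order
±0.5–1 that shrink slowly with further epochs. This is a known limitation
of the truncated schedule, not of the objective; the full-scale schedule
runs ~30× longer.

## Numerical choices and degenerate inputs

* Verdict clamp 1e−7 keeps adversarial logs finite; gradients flow
  through the sigmoid's pre-activation, so saturated critics still pass
  signal.
* `clip_and_scale` rejects non-finite input; `inverse_scale` tolerates
  1e−6 out-of-range before rejecting.
* Zero-variance/equal-mean time samples return `(t, p) = (0, 1)` rather
  than NaN.
* `sample_balanced` and fold splitting are deterministic under a single
  integer seed; model training derives all its randomness (init, shuffle,
  noise, augmentation, priors) from `ModelConfig.seed`.
* Checkpoints (`.npz` with parameters, config and history) round-trip
  bit-identically.

## Known limitations

* The phantom is a geometric proxy; none of the reported phantom numbers
  estimate performance on real CT data.
* The exact layer widths/depths of the reference IAE are not public;
  the stacks above are a faithful re-creation of the described topology
  (fully convolutional codec, conv+FC discriminator, 3-layer FC
  regularizer), not a weight-level reproduction.
* Single 2-D tissue type and modality; no 3-D patches.
* CPU-only: full-scale (3×3×128, 400 epochs, ~500k patches) training is
  out of reach in reasonable time; the code supports the configuration,
  but it has only been exercised at desk scale.
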