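# Methods

## Problem and scope

`metaceeg` studies regularized adversarial generation of stimulus-locked EEG
epochs.  Plain GAN training on small EEG datasets tends to fail in two
characteristic ways: mode collapse (few repeated waveforms, poor diversity)
and spectrally wrong outputs (poor similarity).  The package implements a
trio of generator-side regularizers that monitor the generation process in
three complementary domains, the reduced-scale trainers that consume them,
the metrics used to judge generated data, and a synthetic oddball generator
so every stage is testable without any recorded EEG.

## The regularizers

Let `x` be a real epoch, `G(z)` a generated one, and `lam ∈ (0,1)` a single
trade-off weight.  The generator objective is

```
L_G_final = L_G + lam · L_SR + (1 − lam) · (½ L_FR + ½ L_TR)
```

where `L_G` is the adversarial term of the underlying variant (Wasserstein
critic score here).

**Time-domain term (TR).**  For each interior sample a parametric quadratic
`x(t) = a1 + a2 t + a3 t², y(t) = b1 + b2 t + b3 t²` is fitted through the
three consecutive samples at `t ∈ {−1, 0, 1}`.  With the abscissa equal to
the (uniform) sample index, `a2 = dx`, `a3 = 0`, `b2 = (y3 − y1)/2`,
`b3 = (y3 − 2y2 + y1)/2`, and the curvature at the middle point is

```
k = |2(a3 b2 − a2 b3)| / (a2² + b2²)^{3/2} = 2·dx·|b3| / (dx² + b2²)^{3/2}.
```

The absolute value is applied throughout — curvature is a magnitude, and the
loss below needs nonnegative arguments.  TR scores the generated curvature
against the real one with binary cross entropy, averaged over epochs,
channels, and interior samples.

**Frequency-domain term (FR).**  The DFT amplitude spectrum
`F[k] = |Σ_n x[n] e^{−j2πkn/N}|` of each trace is normalized to sum 1; the
generated spectra are scored by BCE against the mean normalized spectrum of
the real mini-batch.  The real average is recomputed per mini-batch (a
whole-training-set average is available by precomputing the target, but the
per-batch default keeps the term stationary under data refreshes).

**Domain mapping for the BCE terms.**  Raw curvature is unbounded above and
a raw amplitude spectrum is not a probability, so the cross entropies above
are undefined on them.  The package maps curvature through the monotone
squash `k̂ = k/(1+k)` and normalizes spectra to sum 1, then clips both to
`[1e−7, 1 − 1e−7]`.  This is the package's own, deliberately minimal
mapping: it preserves the ordering of curvatures, fixes `k = 1 ↦ 0.5`, and
makes both losses finite and bounded below exactly when generated
statistics match real ones (verified numerically in the tests).

**Latent-space term (SR).**  For latent pairs `(z1, z2)` drawn as disjoint
halves of the mini-batch,

```
ratio = (1 − cos(G(z1), G(z2))) / (1 − cos(z1, z2)),
```

which for unit-normalized vectors equals
`‖ĝ1 − ĝ2‖² / ‖ẑ1 − ẑ2‖²`.  A small ratio means nearby latents collapse to
the same output — the signature of mode collapse.  The default loss is the
*reciprocal* mode `mean 1/(ratio + 1e−8)`: minimizing it pushes the ratio up
and therefore rewards diversity.  Two alternatives are kept for
experimentation: `negative` (`−mean ratio`, same direction, different
curvature) and `literal` (`+mean ratio`, which *penalizes* diversity; kept
only so the formulation that writes the ratio directly into the combined
loss with a plus sign can be reproduced and compared).  Degenerate pairs
(`z1 ≈ z2` after normalization) raise and are resampled by the trainer.

**Gradient bound.**  Along the chord `γ(t) = t z1 + (1 − t) z2` the gradient
theorem gives, for the raw generator map,

```
‖G(z1) − G(z2)‖² / ‖z1 − z2‖² ≤ ( ∫₀¹ ‖∇_z G(γ(t))‖ dt )².
```

`sr_bound_check` verifies this numerically: spectral norms of the Jacobian
at `n_quad` trapezoid nodes, squared path integral, violation counted beyond
`1e−3 ·` bound.  The cosine-form ratio coincides with the left-hand side
exactly when generator outputs are unit-normalized; the check uses the raw
map, for which the inequality is exact (an identity generator attains
equality).  This bound is why pushing the ratio up is meaningful: it forces
the generator's latent-space gradient norm up, countering the flat-generator
regime of mode collapse.

## Trainers

Three variants share one loop (5 critic updates per generator update by
default, Adam `lr 1e−4, β = (0.5, 0.9)`, gradient-penalty coefficient 10):

* `wgan_gp` — MLP generator/critic, Wasserstein loss with gradient penalty;
* `cwgan_gp` — the same with a learned label embedding concatenated to the
  latent and to the critic input;
* `wavegan_lite` — 1-D convolutional pair: the generator is a dense seed
  followed by four (nearest-neighbour upsample ×2 → stride-1 conv →
  LeakyReLU) blocks and a tanh conv head; the critic mirrors it with
  average-pool downsampling.  Upsample+conv is used instead of transposed
  convolution: it plays the same role, avoids checkerboard artifacts, and
  keeps every operation in a family closed under the double differentiation
  that the gradient penalty requires.

No deep-learning framework is part of the dependency set; the package ships
a ~300-line reverse-mode autodiff engine over numpy (`metaceeg.autodiff`)
whose vector-Jacobian products are themselves engine ops, so the
second-order gradients needed by `(‖∇_x D(x̂)‖ − 1)²` come out of the same
machinery.  All networks are deliberately small (desk-scale, single CPU);
the point is the regularizers' behaviour, not photorealistic EEG.

Determinism: a single schedule seed drives initialization and a PCG64
stream whose state is checkpointed, so save → resume reproduces an
uninterrupted run bit for bit.  A real mini-batch is drawn for the
generator step whether or not any regularizer is active, so disabling all
three terms consumes the same random stream as a build with no regulation
module at all — the two loss histories agree exactly, which the tests
assert.

## Evaluation

* **Mode Score** (diversity, higher better):
  `MS = exp( E_fake KL(p(y|x) ‖ p*) − KL(p̄ ‖ p*) )` with `p*` the real
  label marginal and `p̄` the mean prediction on generated data, computed
  with a compact convolutional classifier trained on real epochs only and
  frozen.  `MS = 1` for an uninformative classifier and `= C` for one-hot
  predictions with matched uniform marginals.  Because the classifier is
  part of the metric, its data hash and seed are recorded; MS values are
  comparable only within one classifier.
* **Sliced Wasserstein distance** (similarity, lower better): flatten
  epochs, project on 128 seeded random unit directions, average the exact
  sorted-sample 1-D W1 distances.  The larger set is subsampled (seeded) to
  match counts.
* **Welch PSD**: 1-s windows, 50 % overlap, Hann taper, averaged across
  epochs, reported on 0.01–40 Hz.
* **ERP diagnostics**: per-label epoch average, min–max normalized per
  channel, with an order-15 least-squares polynomial trend on a [−1, 1]
  abscissa to highlight the P300 deflection.
* **Classification metrics**: Acc/Pre/Rec/F1 from confusion counts and AUC
  as the pairwise positive–negative statistic with ties counted 0.5
  (equal to the Mann–Whitney form); multiclass values are macro one-vs-rest
  averages.

## Trade-off weight selection and the augmentation experiment

For a grid of candidate weights, MS and SWD columns are z-normalized
*jointly with the unregularized baseline row* (the deltas subtract the
baseline, so both must share a scale), then
`ΔMS = MS_λ − MS_0`, `ΔSWD = SWD_0 − SWD_λ`; only grid points with both
deltas positive are feasible and the feasible argmax of `ΔMS + ΔSWD` wins.
An empty feasible set raises, signalling the caller to widen the grid.  The
recommended default from this procedure is `lam = 0.6`.

The augmentation experiment mixes generated epochs into classifier training
at ratios `r = 0…5` (generated = r × real): stratified 8:2 train/test split,
5-fold CV inside the 80 %, label-matched generated epochs added *only* to
each fold's training portion — validation folds and the test split stay
real-only, which the tests verify with sentinel-tagged generated data.
Whether mixed or real-only validation is the right protocol is genuinely
open; real-only is the conservative choice and is what the numbers mean
here.  Accuracy vs ratio is then fitted with the saturating power law
`y = a x^γ + b` by least squares — closed-form `(a, b)` per `γ`, and a
400-point grid over `γ ∈ (0, 3]` refined by golden section.  Degenerate
constant-`y` input returns `(a, γ, b) = (0, 1, ȳ)`.

## Synthetic data

`generate_oddball` emulates parietal oddball recordings: per-channel 1/f
background (white noise shaped by `f^(−α/2)` in amplitude, DC removed, unit
SD, scaled by `noise_sd`), plus, for target classes, a positive Gaussian
bump of configurable amplitude/width whose latency is drawn per epoch from
`N(μ, σ²)` (clamped to the window with a warning), spread across channels by
a fixed parietal weight vector (1.0 on the Pz-like channel, 0.6 on
neighbours).  Defaults follow the emulated recordings: 256 Hz, 1 s
post-stimulus epochs (`time0 = 0`), 5 parietal channels, 2 classes with 200
epochs each, 5 µV target amplitude at 400 ± 30 ms with 80 ms width, 2.5 µV
pink noise (α = 1) — roughly a realistic single-trial P300 SNR.  Each epoch
has its own RNG stream keyed by (seed, class, epoch index), so epoch `i` is
invariant to how many epochs are requested.

What the generator does *not* model: volume conduction (the weight vector is
a caricature of a topography), eye-blink/movement artifacts,
non-stationarity across a session, and real P300 morphology (the bump is
Gaussian, not an empirical template).  Consequently, passing tests show that
the losses, trainers, and metrics behave as designed on signals with the
right gross structure — they do not certify performance on recorded EEG.

## Numerical choices

* Preprocessing band 0.01–40 Hz: a literal 0.01 Hz FIR high-pass needs a
  filter longer than a 1-s epoch, so when the low edge spans < 1 cycle per
  epoch it is realized as per-epoch mean removal followed by the FIR
  low-pass (Hamming, 129 taps at 256 Hz, scaled with fs); filtering is
  forward–backward (zero-phase) to preserve ERP latencies.
* MaxAbs scaling is per epoch per channel (keeps each training example in
  [−1, 1] for the tanh generator heads); the scope is exposed because
  per-recording scaling is equally defensible.
* BCE clips at `1e−7`; SR adds `1e−8` to the ratio before the reciprocal;
  the bound check tolerates `1e−3` relative quadrature error.
* Flat channels: min–max normalization of an all-constant average returns
  zeros; MaxAbs leaves all-zero traces untouched.
* Saturation-fit `γ` bracket `(0, 3]` comfortably contains both the
  sub-linear saturation regime and the linear edge case.

## Problem sizes

Everything in the test-suite and the acceptance script is sized for a
single CPU: 1-channel 256-sample epochs, 400-epoch datasets, networks with
8 conv channels or 64-unit hidden layers, and runs of a few hundred
generator steps.  The ablation smoke experiment (3 seeds × {baseline,
SR-only, FR+TR-only} at 300 generator steps with 3 critic updates each)
verifies the *direction* of each regularizer's effect — SR raises Mode
Score, FR+TR lowers SWD — and makes no numeric claim beyond that; GPU-scale
training on recorded datasets is explicitly out of scope.

## Known limitations

* The autodiff engine is minimal by design: stride-1 convs only, no GPU, no
  graph reuse; training beyond a few thousand steps is slow.
* Mode Score depends on the evaluation classifier; values across different
  classifiers are not comparable (hence the recorded provenance).
* The `literal` SR mode exists for comparison only; with it the combined
  loss *discourages* diversity.
* The conditional variant uses a simple embedding concatenation; no
  projection discriminator or auxiliary classifier.
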