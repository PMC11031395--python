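# Methods

`fairgen` is a desk-scale implementation of generative fairness augmentation
for diagnostic imaging: a conditional denoising-diffusion model is trained on
labeled and unlabeled images, synthetic images are sampled from it under a
fair attribute policy, and downstream diagnostic classifiers are trained on
mixtures of real and synthetic data and audited with subgroup-fairness and
distribution-shift statistics.  Everything runs on one CPU in minutes; the
clinical-scale setting this emulates (hundreds of thousands of images, large
pretrained backbones) is out of scope by design.

## The model and the fair objective

Let x be an image, y its diagnostic label, a a sensitive attribute (sex, age
band, skin tone, or an acquisition variable such as hospital), and d the
acquisition domain.  The data-generating process factorises as
p(x | a, y) p(a | y) p(y).  Training data is drawn from a *skewed* joint
p_train(y, a) — some (label, attribute) cells are scarce — while the quantity
of interest is the risk under a *fair* joint p_f(y, a) in which the attribute
is uniform and independent of the label:

    p_f(a, y) = Uniform(a) x p(y).

The method trains a generative model p̂(x | y, a) on all available images
(labeled and unlabeled) and builds the classifier's training distribution as
a Bernoulli(α) mixture: with probability α an example is drawn from the real
labeled set, otherwise (a, y) are drawn from the fair joint and x from
p̂(x | y, a).  With a perfect generator and α = 0 this *is* the fair
distribution, so empirical risk minimisation on the mixture targets the fair
risk directly.  The package contains a closed-form testbed for exactly this
property (`TwoGaussianToy`): 2-D features, class signal on one axis,
attribute signal on the orthogonal axis, so the Bayes-optimal fair accuracy
is Φ(class_sep / 2σ) and the effect of training on skewed versus fair data
is measurable against that bound.

## Diffusion model

Standard DDPM machinery: a variance schedule β_1..β_T (linear or cosine;
cosine default, T = 100 in the experiment pipeline), the closed-form forward
marginal x_t = sqrt(ᾱ_t) x_0 + sqrt(1 − ᾱ_t) ε, and ancestral sampling using
the posterior mean with the predicted clean image clipped to [−1, 1] at each
step.  Conditioning is blockwise: a label block (one-hot or soft) and an
optional property block, concatenated; an all-zero block means "unknown".
Unlabeled examples therefore train with a zero label block, and the
unconditional branch of classifier-free guidance is the fully zeroed vector.
Sampling combines the two branches as ε̂ = (1 + w) ε(x, t, c) − w ε(x, t, 0).

The denoiser is a fully-connected network over the flattened image, a
32-dimensional sinusoidal timestep embedding and the conditioning vector
(hidden widths 256/256 by default).  Two implementation choices matter:

* **Zero-initialised conditioning columns.**  The first-layer weight columns
  receiving the conditioning vector start at zero.  A block that is
  identically zero throughout training receives zero gradient there, so its
  columns stay zero and the trained model is *exactly* invariant to whatever
  is fed into that block at sampling time — the "unknown means unused"
  contract holds structurally, not approximately.
* **Clean-image parameterisation.**  The network regresses x_0 rather than ε
  (the sampler converts via ε̂ = (x_t − sqrt(ᾱ_t) x̂_0)/sqrt(1 − ᾱ_t)).  With
  ε-regression the clean-image component of the target carries weight
  sqrt(ᾱ_t), which vanishes at high noise — precisely where the sampler
  decides which mode (label) to commit to — and at this model scale the
  conditioning pathway never trained (samples collapsed to an attribute- and
  label-averaged blob).  x_0-regression weights all timesteps equally and
  restores sharp conditional control.  `predict_type="eps"` keeps the plain
  noise-regression objective available.

The cascaded upsampler follows the printed degradation recipe for its
conditioning image: bilinear upsampling with probabilistic anti-aliasing
(p = 0.5), Gaussian pixel noise (p = 0.2, σ = 4 on the 0–255 scale), Gaussian
blur with a 7×7 kernel and σ = |N(0, 0.2)| (the absolute value, since a
negative width is meaningless), quantisation to 256 levels, and normalisation
to (−1, 1).  The upsampler shares the base model's conditioning vector,
concatenated with the degraded image.

## Synthetic cohorts

The generator emulates the statistical structure of multi-site medical
imaging without any clinical data.  Each 16×16 RGB image is composed of a
smooth background texture, a centred blob whose radius deterministically
encodes the label (radius fraction 0.18–0.42 of the image side, linear in
the label index), one corner hue marker per attribute whose opacity is
`spurious_strength`, an additive per-domain RGB cast, and i.i.d. pixel noise.
Because each factor enters through an independent mechanism, prevalence
shift, demographic skew and acquisition shift can be ablated separately.
The Bayes rule is known (`planted_rule`), implemented as correlation against
zero-mean disk templates so that additive casts cancel exactly; with zero
noise it scores accuracy 1 and its accuracy decays monotonically with
`noise_sd`.

Defaults for the end-to-end experiment were chosen once to mimic the
qualitative regime of the clinical settings: a minority attribute value
(p(a=1|y=0)=0.1, p(a=1|y=1)=0.5, giving an overall ~30% minority correlated
with the label), `spurious_strength` 0.9 (the shortcut cue is easy),
`noise_sd` 0.1–0.15 (the diagnostic feature is noisy), domain casts of
magnitude 0.12 (stain-like shifts that degrade colour features OOD), a
held-out OOD domain, 30% of in-distribution examples unlabeled
(histopathology-style: domain known, diagnosis not), and minority capping at
100 labeled examples.  In this regime the baseline classifier leans on the
attribute cue and its accuracy splits across subgroups out of distribution.

What the toy cohort does **not** model: real lesion/tissue morphology,
intra-class appearance variability, label noise, attribute-conditional
image structure beyond a single cue, and domain shifts beyond an additive
cast.  Passing tests therefore demonstrate that the machinery behaves as the
theory predicts under controlled shifts — not that the method attains any
particular effect size on clinical data.

## Fair sampling and classifier arms

`draw_conditioning` draws labels i.i.d. from the empirical labeled p(y) and
attribute values i.i.d. uniform, independently (the factorised fair joint).
`build_mixture_stream` draws each of n stream items from the real pool with
probability α, else from the synthetic pool, uniformly with replacement
within each pool.  Modality-style defaults for α follow the ratios used at
clinical scale: 0.5 (histopathology), 0.0 (radiology), 0.25 (dermatology);
the pipeline default is α = 0.5 at this scale since fully synthetic training
(α=0) compounds generator error on a small model.

The downstream classifier is a two-hidden-layer fully-connected net
(128/64) trained by Adam on minibatches of 32 for 600 steps; the last hidden
activation is the penultimate feature map used by the shift diagnostics.
Heads are multiclass softmax or independent per-condition sigmoids.  The
comparison arms mirror the standard baselines: per-modality heuristic
augmentation chains with the printed jitter parameters (geometric sizes
rescaled proportionally to the toy resolution), attribute-even oversampling
with replacement, and focal loss −(1 − p_t)^γ log p_t with γ = 2 by default
(γ = 0 reduces exactly to cross-entropy; probabilities are clamped at 1e-7
inside gradients and 1e-12 in the loss value).  A reduced random-op policy
(two random jitter ops per image) stands in for a learned augmentation
search space; it is a configurable heuristic, not a reimplementation of one.

In the experiment pipeline the synthetic pool is sampled with guidance
weight w = 1.5.  At this model scale unguided (w = 0) pools are faithful on
average but carry subtly subgroup-dependent artefacts — the generator sees
only ~100 capped minority examples — and a classifier trained on them can
acquire a *new* subgroup gap.  Guidance pushes samples toward canonical
exemplars of the conditioned (label, attribute) cell and reduces the effect.
The guidance weight of the plain library sampler defaults to 0 (guidance
off) and is always explicit in the experiment configuration.

Canonical synthetic images cut the other way too: the sampler returns
posterior means, so samples are nearly noise-free while real images carry
pixel noise and domain casts, and a classifier trained on a raw mixture can
key on that appearance difference and mis-threshold real out-of-distribution
positives.  Combining the mixture with the standard colour-jitter
augmentation (the `synthetic_augment` arm) bridges the gap and is the
configuration the end-to-end directional test uses — mirroring the
clinical-scale finding that synthetic data and standard augmentations are
complementary.

## Metrics

* AUC via the rank statistic (ties counted 1/2) — identical to the
  probability that a random positive outscores a random negative; undefined
  inputs (one class) raise `UndefinedMetricError` rather than returning 0.
* AUC parity: |AUC_g1 − AUC_g0| for a binary attribute.
* Best–worst gap: max − min of any per-group metric map.
* High-risk sensitivity: pooled (micro) top-1 recall over a designated
  high-risk label set.
* Balanced and top-k accuracy; classes absent from the reference are
  excluded from the balanced mean and logged.
* Beta-posterior spread: independent Beta(1 + s, 1 + f) posteriors per group
  under a uniform prior, 100,000 paired difference draws, standard deviation
  reported.  This reads as the uncertainty of the group-vs-outgroup
  performance difference; tiny subgroups give wide spreads.

## Shift diagnostics

Unbiased squared MMD with the cubic polynomial kernel
K(u, z) = (u·z/d + 1)^3 — degree fixed to capture up to third-order moment
mismatches with no bandwidth to tune; the 1/d scaling and +1 offset keep
kernel values O(1) and are configurable.  Within-set sums exclude i = j (the
reading under which the 1/(N(N−1)) coefficient is the unbiased estimator);
`include_diagonal=True` provides the biased variant for sensitivity checks.
The replicate protocol draws S = 30 subsamples of n = 300 rows per domain
without replacement and compares augmentation strategies with a two-sided
Mann–Whitney U-test (exact null for small untied samples, normal
approximation with tie correction otherwise; all-identical inputs
short-circuit to p = 1).  PCA compression reports the smallest number of
covariance eigen-directions retaining a given variance fraction.
Consistently-misclassified individuals are the evaluation examples all five
seed replicates of a training setup get wrong; the summary counts them per
subgroup and lists the set differences between setups.

## Numerical and design choices

* Rater aggregation ranks by *descending confidence*, not list position
  (only this reading reproduces the canonical worked example; list-position
  ranking yields a different vector).  Confidence ties break by list order,
  configurable to average ranks.  Confidences influence ranking only; the
  weight is 1/rank.
* `skew_dataset` removes uniformly at random within each capped subgroup;
  the majority value and all unlabeled examples are untouched.
* `strip_labels` uses a seeded permutation split, so the unlabeled count is
  exactly round(fraction·n).
* Age-style bucket edges default to (18, 40, 65); half-open buckets
  [e_i, e_{i+1}), below-first → 0, at-or-above-last → last.
* All generators and trainers are pure functions of (config, seed); seeds
  are derived from a master seed via `numpy.random.SeedSequence` and kept
  below 2^31.
* The experiment pipeline holds out whole domains for OOD evaluation and an
  in-distribution evaluation split; training streams and evaluation sets are
  disjoint by id (asserted at run time).

## Problem sizes

The shipped experiment configuration uses 2,000 generated examples
(≈560 labeled after stripping and capping), a 100-timestep cosine schedule,
3,000 denoiser training steps, a synthetic pool equal in size to the labeled
set, and five classifier seeds per arm — chosen so the full pipeline and the
test suite complete in minutes on a single CPU while leaving the qualitative
structure of the clinical-scale experiment intact.

## Known limitations

* The fully-connected denoiser and classifier do not model spatial
  invariances; results at larger image sizes would need convolutional
  backbones.
* The generator's planted rule is linear-ish in pixel space by construction;
  it cannot probe representation-learning effects.
* The directional end-to-end result (the synthetic-augmented arm does not
  widen, and typically narrows, the OOD subgroup gap relative to the plain
  baseline) is a property of the emulated regime; effect sizes do not
  transfer to clinical data.  In this toy regime the colour-jitter policy
  alone is also highly effective against the additive-cast shift, so the
  end-to-end comparison demonstrates compatibility of synthetic mixtures
  with strong generalisation, not superiority over heuristic augmentation;
  the *unique* value of the fair generative mixture is isolated by the
  closed-form two-Gaussian property test, where no augmentation is involved.
* Adding held-out-domain unlabeled images to the diffusion pool
  (`ood_unlabeled_fraction`) helps at clinical scale but degraded sample
  quality under the flat MLP denoiser here; it defaults to off.
* Guidance weights well above ~3 visibly oversaturate samples at this scale.
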