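# Methods

## The scoring problem

A PD-L1 tumor proportion score is a proportion: TPS = 100 ×
positive tumor cells / viable tumor cells, scorable only with ≥ 100
viable tumor cells. Slides are stratified at the clinical cutoffs into
no expression (< 1%), low (1–49%) and high (≥ 50%) subgroups; the 49–50%
boundary, which the subgroup definitions leave open, is resolved as high
iff TPS ≥ 50, consistent with the 50%-cutoff kappa analysis and clinical
convention.

The scorer is weakly supervised: the only training signal is one TPS
label per slide, quantized to a fixed set of 12 values
{0, 0.01, 0.05, 0.1, 0.2, …, 0.9}. The set is denser near zero because
the 1% cutoff is the clinically critical boundary; it is configurable.

## Pipeline

**Tissue detection.** Otsu threshold on luminance; tissue is the
*darker* side (stained tissue vs. glass). The polarity is fixed — an
inverted scan would fail loudly in the tissue-fraction checks rather
than silently. A 5×5 morphological closing fills nuclear holes. A
constant-intensity image (Otsu undefined) yields an empty mask plus a
warning, not an exception.

**Tiling.** Non-overlapping 256×256 windows on the aligned grid,
top-left origin, half-open coordinates; a patch is kept when ≥ 50% of
its window is tissue (threshold configurable; the keep rule is not
prescribed anywhere authoritative, 0.5 is this package's choice).
Right/bottom remainder strips are discarded.

**Tumor-patch classifier.** A compact CNN (two conv-ReLU-maxpool stages
over the patch block-mean-pooled to 32×32, then a dense layer to 2
logits) trained with inverse-frequency-weighted cross-entropy. The
fine-tuned ImageNet MobileNet-V2 mode remains in the configuration enum
for real-slide work but requires a deep-learning framework with
pretrained weights and is not trainable in this package.

**MIL model.** Per tumor patch, the extractor CNN (same compact
architecture, `num_features`=32 outputs) produces a feature vector
squashed through a sigmoid into [0,1] — required so the pooling bins
are well defined; the feature range is otherwise a free choice. A
gated-attention network (tanh and sigmoid gates, attention dim 16)
scores each patch; scores are softmax-normalized across the bag.
Distribution pooling forms, for every feature dimension j,

    h[j, b] ∝ Σ_i w_i · exp(−(c_b − f_ij)² / (2σ²)),

over `n_bins`=21 equally spaced bin centres c_b on [0,1], each row
renormalized to sum to one. σ = 0.05 (≈ one bin width) keeps the
smoothed histogram differentiable without washing it out; both are
configurable. The attention weights enter the pooling kernel sum
directly — one of several defensible wirings of attention into
distribution pooling; it preserves permutation invariance and
weight-mass invariance (splitting an instance's weight over duplicates
changes nothing), both asserted in tests. The bag head is a fully
connected network (hidden 64) from the flattened `num_features × n_bins`
representation to 12 logits; softmax gives label probabilities and the
bag prediction is the expected TPS under them. The head consumes the
representation scaled by `n_bins` (bin densities rather than
probabilities) purely for optimization conditioning.

**Slide prediction.** Inference bags are drawn with replacement with a
full-cover guarantee (every patch appears at least once; remaining
slots uniform), 100 bags of 200 patches by default; heatmap bagging
defaults to 100 patches per bag to keep maps local. TPS-AI = mean of
bag predictions × 100. A slide with zero tumor patches returns an
explicit no-tumor result, never a number.

**Heatmap.** Each patch's value is the average prediction of the bags
containing it (its recalculation count is its multiplicity across
bags). The count-weighted mean of patch values equals the mean bag
prediction exactly; tests enforce the identity. Overlays colour patches
with value ≥ threshold; colormap and blending alpha are recorded in a
sidecar JSON so renders are reproducible.

## Training

Slides (never bags) are split 3/1/1 into train/validation/test. Each
epoch, every training slide's patches are re-partitioned into fresh
random bags (random permutation, round-robin), each bag inheriting the
slide's quantized label — re-bagging every epoch is a variance-reduction
choice, not a mandate. RandomCrop to 224 plus horizontal/vertical flips
are applied at training time only; a small pool of eight precomputed
augmentation variants per patch is sampled per epoch so the network
pass, not the augmentation, dominates step cost.

Two losses are available: cross-entropy over the 12 labels (default)
and mean-squared error on the expected-value readout. Optimization is
Adam with global gradient-norm clipping at 5 and gradients
**accumulated over all bags of an epoch before each step**. The
accumulation is load-bearing: each bag carries a single label, so
per-bag Adam steps chase one label at a time — Adam's per-coordinate
normalization turns small noisy gradients into full-size steps, the
squashed features saturate, and the model collapses to predicting the
label marginal. The head's final layer is zero-initialized for the same
reason (training starts from the uniform output with no random
transient). An optional mean-pooling warm start
(`pretrain_epochs` > 0) fits slide TPS as the mean over patches of a
sigmoid scalar readout — the natural first-order reading of a
proportion label — before the full objective; with gradient
accumulation it is not required and is off by default. Early stopping
tracks validation loss (patience 50 epochs) and restores the best
parameters.

## Synthetic slides

The generator renders caricature IHC slides with truth exact by
construction: white glass; eosin-pink tissue as a union of random
ellipses; a tumor region assembled from a blob subset greedily matched
to the requested tumor-area fraction; tumor cells as 4.5–6.5 px
elliptical hematoxylin nuclei, the positive ones ringed by a 2 px brown
annulus (membranous staining); and smaller (2–3 px) distractor immune
cells, 30% of them brown by default — the pipeline must ignore them,
since TPS counts tumor cells only. The realized positive count is a
binomial draw clamped within ±2 percentage points of the target (counts
are integers; the realized value, not the target, is the label used
everywhere downstream). A 256×256 patch is labelled tumor iff ≥ 5 tumor
centroids fall in it. Identical spec + seed gives bit-identical images.

Default conditions: 1024×1024 px slides, 6 tissue blobs, tumor area
fraction 0.6, 400 tumor cells, immune density 2×10⁻⁴ per tissue pixel,
additive stain noise SD 3 (0–255 scale) — sizes at which a 60-slide
cohort generates, trains and evaluates in minutes on one CPU while
still yielding ~10–16 patches per slide. The generator does **not**
emulate stain gradients, nuclear texture, focus artefacts, pen marks,
tissue folds, or cell-type morphology beyond size/colour; passing the
recovery benchmark therefore shows the pipeline's machinery is correct
and recovers proportions from weak labels under these idealized optics,
not that it transfers to scanner images.

## Evaluation statistics

ICC is the two-way random-effects, absolute-agreement, single-measure
form ICC(2,1), computed from the two-way ANOVA mean squares, with the
McGraw–Wong F-based 95% CI — the standard form for method-vs-reference
agreement; the consistency form ICC(3,1) would not penalize a constant
offset and is deliberately not used. Cohen's kappa uses
marginal-product expected agreement with the conventional bands (≤0.2
slight, ≤0.4 fair, ≤0.6 moderate, ≤0.8 substantial, ≤1.0 almost
perfect); when both raters are constant and equal, kappa is reported as
1.0 with a warning. Bland–Altman limits are mean ± 1.96 × sample SD of
prediction-minus-truth differences. Cohort contingency tables use the
Pearson chi-square without continuity correction — the variant that
reproduces all five published cohort-comparison statistics exactly.
Percentages are floats 0–100 in reports and fractions 0–1 internally.

## Benchmark problem sizes

The desk-scale benchmark (`milt.pipeline.desk_config`) runs 60 slides
(36/12/12 split), 2 training bags per slide, 20 inference bags of 16,
600 training epochs with the expected-value MSE loss, and a 12-epoch
classifier. At these sizes the cross-entropy loss also recovers the
TPS ranking but calibrates less tightly at the scale extremes, so the
benchmark configuration selects the MSE readout; cross-entropy remains
the module default. The classifier benchmark trains on 600 balanced
patches and scores 400 held-out ones from independently seeded slides
with tumor-area fraction 0.35 (so non-tumor tissue patches are not
rare).

## Known limitations

- The desk backbone sees patches block-mean-pooled to 32×32; individual
  membrane rings survive only as colour statistics. This is sufficient
  for the synthetic optics but is not a claim about 20× scanner data.
- Slide-level TPS is the unweighted mean of bag predictions; very small
  slides are handled by replacement sampling, but a slide with a single
  tumor patch gets an effectively patch-level prediction.
- Bag size at inference is reported as 200 in one place and 10×10 in
  another by the method's description; both are exposed in
  configuration, neither asserted canonical.
- The agreement suite covers two raters only; multi-rater designs,
  weighted kappa and bootstrap CIs are out of scope.
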