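# Methods

`histomine` implements a weakly-supervised pipeline for classifying
whole-slide images (WSIs) of H&E-stained colorectal biopsies as
containing poorly differentiated adenocarcinoma or not. Only a
slide-level diagnosis is available as a label; on positive slides,
free-hand polygon annotations around tumour regions restrict where
positive training tiles may come from. This note records the model, the
choices behind every tunable, what the synthetic data does and does not
emulate, and the numerical conventions.

## The classification model

A WSI is far too large for a CNN, so the unit of computation is a square
tile. A convolutional backbone with global average pooling and a
single-logit sigmoid head maps each RGB tile to a probability that it
shows poorly differentiated tumour. At inference the model slides over
every tissue tile of the slide (tile 512 px, stride 256 px at full
scale) and the slide score is the **maximum** tile probability: one
confident tile flags the slide, which matches the clinical question —
is tumour present anywhere in the biopsy. An ensemble averages member
tile probabilities before the maximum (averaging per-member slide maxima
is also available; it is a different statistic and is exposed as an
explicit option).

Two backbones share this contract:

- `efficientnet_b1` — the canonical EfficientNet-B1 layout: 3×3 stem
  conv (32 channels), seven MBConv stages with depths [2,3,3,4,4,5,2]
  and output channels [16,24,40,80,112,192,320] (B1's depth coefficient
  1.1 applied to the base repeats, widths unchanged), squeeze-excitation
  bottlenecks sized from each block's unexpanded input, and a 1×1 top
  conv to 1280 features. Being fully convolutional with global pooling
  it accepts tiles at native size; a configured `input_size` mean-pools
  or resizes tiles first.
- `tiny_cnn` — three stride-2 3×3 conv/batch-norm/ReLU stages
  (3→8→16→32 channels) plus the same pooled single-logit head; 6,121
  parameters. It exists so the full two-phase training loop runs at
  desk scale in seconds, not to compete with the large backbone.

### Partial fine-tuning

Transfer learning here freezes the entire backbone except the
batch-normalisation affine parameters (per-channel scale γ and offset
β) and the final classification layer. On EfficientNet-B1 that leaves
62,048 BN parameters plus 1,281 head parameters (1280 weights + 1 bias)
= **63,329 trainable scalars** out of ~6.5 M. BN running mean/variance
still update in training mode — they are buffers, not trainable
parameters, and are never counted. The single-logit head is the only
head size consistent with that arithmetic: a two-way softmax head would
contribute 2,562 parameters and no enumeration of BN pairs could make
up the difference.

### The layer library

No deep-learning framework is part of the dependency set; the package
carries its own numpy layer library (`_nn.py`) with hand-written
backward passes for grouped/depthwise convolution, batch
normalisation, dense layers, squeeze-excitation, swish/ReLU/sigmoid and
global average pooling, plus Adam. Every backward pass is verified
against central-difference numerical gradients in the test suite.
Frozen parameters still propagate activation gradients (trainable BN
parameters sit deep inside a frozen backbone) but the optimizer never
touches them, so frozen values are bit-identical across a whole run.
Convolution padding is symmetric (`k//2`); exact TF-style asymmetric
"same" padding would shift some feature maps by one pixel but has no
effect on parameter counts or on any quantity the tests assert.

## Training procedure

**Phase 1 — random balanced sampling.** Slides enter a shuffled queue
that strictly alternates positive and negative; an exhausted label pool
is reshuffled and reused, so the minority label is oversampled rather
than letting batches go unbalanced. Each batch takes one positive and
one negative slide and samples `batch_size / num_labels` = 16 tiles
from each, with replacement (a small annotation may admit a single
candidate tile, which could never fill a 16-tile demand otherwise).
Annotated slides sample only tiles placed by the annotation rules;
unannotated slides sample uniformly from tissue tiles. One epoch makes
`max(n_pos, n_neg)` such pairs, so every slide is visited at least once
per epoch. The loss is tile-level binary cross-entropy with tiles
inheriting their slide's label, optimised by Adam (β₁ 0.9, β₂ 0.999),
learning rate 0.001 decayed by 0.95 every 2 epochs.

**Phase 2 — hard mining.** Once the validation loss fails to improve
for `switch_patience` (2) epochs, training alternates inference and
training: slides are drawn from the same balanced queue, all candidate
tiles of each slide are scored by a sliding window, and the k=16
hardest tiles are kept — highest-probability tiles of negative slides
(false-positive candidates), lowest of positive slides. Ties resolve to
grid (row-major) order so mining is deterministic. Tiles accumulate
into a subset truncated at exactly N=256, which is then trained through
once in batches of 32. One mining round plus that pass is an epoch.
Training stops after `stop_patience` epochs without validation
improvement ("improvement" = beating the running minimum by more than
1e-6), and the weights of the best validation epoch are kept.

**Validation signal.** Both phases evaluate the same quantity: BCE on a
fixed, seeded sample of up to 64 tiles per validation slide
(annotation-restricted for annotated positives), drawn once before
training and cached, so phase switching and early stopping respond to
the model, not to sampling noise.

**Annotation-driven tile placement.** An annotation whose bounding box
fits inside a tile (max dimension ≤ tile size, with boundary equality
going to this branch) yields one tile centred on the bbox centroid,
clamped into the slide. A larger annotation is covered by an
overlapping grid over its bbox — stride tile/2 by default, matching the
inference stride — with the final row/column clamped to end at the bbox
edge, keeping tiles that intersect the polygon (intersecting rather
than fully-contained tiles retain edge context and more training
signal). Annotated slides are also *mined* only within these
candidates: selecting the lowest-scoring tiles of a positive slide from
its whole tissue would label non-tumour tissue positive.

**Determinism.** All randomness — queue shuffles, tile draws,
validation sampling, weight init — derives from the config seed via
named `SeedSequence` substreams. Two runs with one seed produce
identical histories, checkpoints and predictions.

## Tissue detection

The slide's full-resolution grayscale histogram (ITU-R 709 luminosity
weights, rounded to 8 bits) is thresholded by Otsu's method: the level
L maximising between-class variance of the split {gray < L} / {gray ≥
L}, ties broken toward the lowest level. A mask pixel (one per 32×32
base-pixel block by default; memory/precision trade-off, configurable)
is tissue when its block-mean gray falls strictly below L — tissue is
darker than glass. A blank slide yields an all-false mask and a warning
rather than an error. Tiles count as tissue when ≥ 10% of their mask
footprint is tissue (`min_tissue_fraction`; excludes glass-only tiles
without discarding fragment edges).

## Evaluation

- **ROC AUC**: all-pairs concordance with half-credit ties
  (Mann–Whitney), via scikit-learn.
- **Log loss**: mean BCE with probabilities clipped to [1e-7, 1-1e-7].
- **Bootstrap CIs**: percentile 2.5/97.5 over 1000 seeded resamples,
  stratified within each class so every resample contains both classes
  and AUC is always defined.
- **Confusion matrix** at threshold 0.5, with score = threshold counted
  positive.
- **Specificity at 100% sensitivity**: threshold = minimum positive
  score; specificity = fraction of negatives strictly below it.

Slides with no tissue tiles get an undefined score, are excluded from
metrics, and trigger a warning.

## Synthetic data

Real WSIs from the source hospitals are private, so the generator
emulates exactly the statistical structure the pipeline assumes: bright
glass background (245 ± 8 gray), 3–7 pink tissue fragments (~155 gray)
built from overlapping rotated ellipses with low-frequency mottling and
gland-like ring motifs, and — on positive slides only — elliptical
regions (10–40% of tissue) packed with small dark blue-purple nuclei to
~70% coverage, giving a region mean of ~90 gray. Each region is
enclosed by a 32-vertex polygon annotation that covers the positive
texture by construction. The positive texture is detectable within a
single tile, and a mean-darkness straw-man classifier reaches WSI AUC
> 0.9 on a 20-slide set — certifying the task is solvable, so an
end-to-end training failure indicates a pipeline bug rather than
impossible data.

What the generator does **not** emulate: stain variation and scanner
artefacts, nuclear morphology and chromatin texture, gland architecture
beyond ring motifs, tissue folds/pen marks, or the heavy class
imbalance of real screening populations. Passing end-to-end tests
therefore demonstrates that the machinery (sampling, mining, freezing,
aggregation, evaluation) is correct — not that the tiny backbone would
classify real histopathology.

## Desk-scale study conditions

End-to-end tests run 2048-px slides with tile 128 / stride 64
(geometry scaled 4× down from the full-scale 512/256 defaults; all
geometry is parametric and both scales run identical code), the
`tiny_cnn` backbone fed 32-px mean-pooled tiles, k=16, N=256, batch 32,
and `stop_patience` 4 with at most 30 epochs — enough for both phases
to run and converge on the synthetic task, chosen as this package's
desk-scale configuration. Library defaults keep the full-scale values
(tile 512/256, stop patience 10).

## Known limitations

- Pyramidal slide containers are read at their base level via tifffile;
  true multi-resolution access (openslide) is not wired in, and slides
  are held fully in memory — appropriate for fixtures, not for 30K×15K
  clinical scans.
- ImageNet starting weights are not bundled; transfer learning starts
  from any user-supplied checkpoint of a compatible architecture.
- The numpy backbone is single-threaded; EfficientNet-B1 forward passes
  at clinical scale would be orders of magnitude slower than a GPU
  framework. The package's value at that scale is the sampling, mining
  and evaluation machinery, with the model behind a narrow interface.
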