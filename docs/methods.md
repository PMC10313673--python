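# Methods

## Problem and approach

`mosqid` identifies medically important mosquitoes (species × sex classes,
plus a non-mosquito control) from single-specimen photographs. Instead of a
conventional softmax classifier, it uses deep metric learning (DML) with
content-based image retrieval (CBIR): a network maps each image to a 64-d
embedding trained so that conspecific images cluster; a query is classified
by retrieving its k = 20 nearest training embeddings and letting them vote.
The retrieval formulation has two practical advantages for entomological
surveillance: it tolerates small, imbalanced classes, and the reference
gallery can be *extended* with newly labelled images — including classes or
capture sources never seen in training — without touching the model.

## Model

The network has three separately optimised parts:

1. **Backbone.** Either the 34 parameter-layer residual network (basic
   blocks [3, 4, 6, 3]; its 1000-wide output layer feeds the embedder,
   mirroring the original system, unusual as that choice is) or a
   ~130k-parameter `smallcnn` (four 3×3 conv + batch-norm + ReLU + 2×2
   max-pool blocks, channels 16/32/64/128, final 2×2×128 map flattened).
   `smallcnn` at 32×32 input is the default: residual-34 training is not
   practical on a single CPU, and 32×32 matches the resolution at which
   robustness queries are rescaled. The flattened (rather than
   globally pooled) final map keeps coarse spatial structure, which
   measurably speeds classifier-head convergence at this tiny input size.
2. **Embedder.** A linear map to 64 dimensions, L2-normalised. On the unit
   sphere, ascending Euclidean distance and descending cosine similarity
   give the same ranking, which reconciles the pipeline's two metrics (a
   cosine match threshold and Euclidean retrieval) into one coherent
   geometry.
3. **Classifier head.** Linear, 64 → 20 logits (width ≥ number of classes;
   20 leaves headroom). It exists to "support the trainer": its
   cross-entropy term stabilises early training and provides the
   validation-accuracy signal used to pick the best epoch. Inference is
   retrieval-based and does not use it.

The layers run on a small numpy reverse-mode autograd engine written for
this package (`mosqid.nn`): broadcast arithmetic, matmul, im2col
convolution, max-pooling, batch-norm, log-softmax, and Adam. Everything is
float64 and seeded, so training histories are bit-reproducible; every
layer's backward pass is verified against central differences in the test
suite.

## Loss, mining and batches

The metric objective is the triplet-margin hinge
`L = [d_ap − d_an + m]₊` with margin m = 0.1, averaged over tuples chosen
by one of five miners (selection rules follow the reference
metric-learning library semantics; the source text names the miners but
does not define them):

| miner | rule | default |
|---|---|---|
| triplet_margin | keep triplets with d_ap − d_an + m > 0 | m = 0.1 |
| multi_similarity | pairs within ε of the hardest opposing pair (cosine) | ε = 0.1 |
| pair_margin | positive pairs with d > pos_margin, negatives with d < neg_margin | 0.2 / 0.8 |
| angular | α = atan(d_ap / 2·d_nc) > threshold | 20° |
| distance_weighted | one negative per anchor, P ∝ 1/q(d), q(d) ∝ d^(D−2)(1 − d²/4)^((D−3)/2), d clamped to [0.5, 1.4] | seeded |

Pair-based miners feed the triplet loss by joining positive and negative
pairs that share an anchor. An optional subset-batch stage composes with
any tuple miner (identity by default). Empty mining output contributes an
exact zero loss.

Batches come from an M-per-class sampler: 16 images, 8 per class (so 2
classes per batch), classes smaller than 8 sampled with replacement. The
total loss is `1.0·cross-entropy + 1.0·triplet` — the two terms are
unweighted because no weighting is specified anywhere; both weights are
config fields.

Optimisation is Adam (β₁ = 0.9, β₂ = 0.999, weight decay 0.001,
ε = 1e-8) with per-part learning rates: backbone 1e-5, embedder and
classifier 1e-4. The nominal schedule is 200 epochs with the best epoch
(argmax validation accuracy, earliest on ties) retained. Validation is a
10% stratified carve-out of the train split; the test split never
influences training. A k-means pass (k = 20) over the training embeddings
is logged per epoch as a cluster-purity monitor only — it is not a loss
term; the source description is ambiguous on this point and monitoring is
the conservative reading.

## Inference

`embed → retrieve → match-filter → vote`:

* retrieval is exhaustive k-nearest (k = 20) by Euclidean distance,
  ascending — exact at gallery scales of a few thousand rows;
* the match filter removes neighbours with cosine similarity < 0.5; if
  none survive the query is reported as a distinct *no-match* outcome
  rather than forced into a class (the threshold implies rejectable
  queries). The filter is applied to the retrieved k before voting; the
  alternative sequencing is not stated in the source and this one is
  exposed as configuration;
* voting: score(c) = 100·count(c)/survivors; the top score wins, ties
  broken by smaller mean neighbour distance, then lexicographic class
  code (ties are never mentioned in the source; the rule is deterministic
  and distance-respecting).

Gallery extension appends `pseudo_train`-flagged embeddings of newly
labelled images to the index. The operation provably leaves existing rows
and model parameters bitwise unchanged (asserted in tests).

## Evaluation

One-vs-rest Tp/Tn/Fp/Fn per class from the confusion matrix, with
precision, sensitivity, specificity, accuracy and F1 in percent; 0/0
ratios are reported as absent, not zero. Both micro (pooled counts) and
macro (mean of per-class values) averages are computed and labelled:
arithmetic consistency with the published miner-comparison tables shows
their "Average" sensitivity/precision rows are micro-averages while the
specificity/accuracy columns are macro means, so the package reports both.
Rounding for display is half-up to 2 decimals, matching the tables.

ROC curves are one-vs-rest on the vote score with thresholds swept
0–100% in 5% increments (21 points; threshold 0 calls everything positive).
AUC is the trapezoid over the curve plus the implicit (0, 0) endpoint;
because vote scores with k = 20 live on the same 5% grid, this equals the
tie-corrected Mann–Whitney statistic (checked against that oracle).
Confidence intervals are percentile bootstrap over query resampling
(1000 resamples, 2.5/97.5 percentiles, seeded). UMAP provides the 2-D
embedding projection for report figures.

## Synthetic data

The specimen photographs behind the original study are available only on
request, so the package generates a parametric stand-in corpus
(`mosqid.synth`). Each class is an insect-like figure — body ellipse with
abdominal stripes, two translucent wings, a head — with per-class shape,
stripe-frequency and hue parameters, and per-image pose jitter (rotation
±20°, translation, scale ±8%). Capture sources reproduce the contrasts the
study describes: a stereomicroscope-like profile (grey background, mild
blur/noise) versus a phone-like profile (near-white background, stronger
blur, 0.85× zoom, more sensor noise, +8% illumination), plus an
"external" second-source profile (darker grey board, 1.6× zoom, heavier
noise) for the extension experiment. Rendering is supersampled 3× and
box-averaged down; every pixel is a pure function of (spec, seed) via
per-image `SeedSequence([seed, class, image])` streams, so corpora are
bit-reproducible.

What the generator does *not* emulate: real anatomical detail (scales,
wing venation), specimen damage, viewpoint diversity beyond in-plane pose,
and natural intra-class variation. Classes are separable by construction.
End-to-end results on this corpus therefore demonstrate that the pipeline
*mechanics* work — training converges, retrieval recovers held-out and
pseudo-training classes, noise degrades AUC — not that the published
real-data accuracy transfers.

## Scaled-down study conditions

Desk-scale experiments (tests and the acceptance script) use 5 balanced
classes × 40 images (64×64, two sources, 90/10 stratified split), the
`smallcnn` backbone at 32×32, 20 epochs, and 40 batches per epoch. The
original iteration counts per epoch are mutually inconsistent in the
source text and far beyond desk scale, so batches-per-epoch is a config
field; 40 gives the optimiser ~800 steps at the fixed learning rates,
enough for the classifier head to plateau on separable data. The
extension experiment renders a 6th class (60 images, external source,
90% pseudo-training / 10% queries). The noise sweep uses σ ∈ {0, 25, 75}
intensity units — clean, visibly degraded, and heavily degraded at 32×32.
The bootstrap calibration study uses 100 outer replications of
Bernoulli(0.8) correctness at n = 200 queries.

## Numerical choices and edge cases

* Boxes are 0-based half-open (x0, y0, x1, y1), origin top-left.
* Per-class test count in splits is `max(1, round_half_up(n·(1−f)))`, so
  every class is testable; membership is a hash of (seed, image_id).
* Resize is bilinear; noise is added in [0, 255] units then clipped, with
  half-even rounding to uint8.
* Distances of mined tuples get a 1e-12 floor inside the square root to
  keep gradients finite for coincident points; duplicate batch members
  are legal (replacement sampling).
* Degenerate angular triplets (anchor = positive location) are skipped;
  a negative at the anchor–positive midpoint counts as α = 90°.
* k-means with fewer distinct points than k warns and shrinks k.
* Retrieval distance ties break by gallery order (stable sort).

## Known limitations

* The numpy engine is single-threaded beyond BLAS matmul; residual-34 is
  buildable and correct (34-layer census, gradient-checked blocks) but
  slow to train — it exists for architectural fidelity, not desk use.
* No approximate nearest-neighbour index; retrieval is O(n·d) per query.
* The synthetic corpus cannot validate real-data performance claims; the
  printed real-data tables are reproduced only at the arithmetic level
  (confusion-matrix → metric identities).
* Object detection (cropping) is out of scope; the pipeline consumes
  ground-truth boxes or pre-cropped images.
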