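# Methods

## The labeling-transfer problem

A detector trained on one fruit species does not transfer to another:
fruit shape and scale are comparable across many orchard species, but
color statistics differ enough that a source-trained model scores
target fruit near zero. The pipeline closes this gap without manual
target labels by (i) repainting the labeled source imagery toward the
target appearance, (ii) bootstrapping pseudo labels on the real target
imagery with a confidence threshold θ, (iii) filtering pseudo-label
noise with the dataset-wide mean score, and (iv) iterating label
regeneration and detector fine-tuning.

The method's core assumptions, inherited by this implementation:

* source and target fruits differ mainly in appearance (color), not in
  shape or scale — the transform can keep the source boxes verbatim;
* detector confidence correlates with label correctness, so a score
  threshold and a mean-score filter remove noise preferentially;
* the fine-tuned detector's labels on the target set improve
  monotonically enough over rounds that cyclic re-labeling converges
  rather than drifting.

## Pseudo-label generation and filtering

Generation keeps detections with score ≥ θ, θ ∈ (0, 1). Filtering
computes `S_aver` as the arithmetic mean of **all** candidate scores
pooled over the dataset (a per-image variant exists behind a flag for
ablation only) and keeps boxes with score ≥ `S_aver`; ties survive, so
a non-empty batch always retains its maximum-scoring box. The
comparison carries an absolute tolerance of 1e-9 so float accumulation
in the mean can never delete a batch of identical scores. Filtering is
applied once per round, not iterated to a fixed point. Images left with
no surviving box stay in the fine-tuning set as background-only images
(`drop_empty_pseudo_images` excludes them).

The self-learning loop regenerates pseudo labels from the *current*
detector every round — labels are replaced, never accumulated — and
fine-tuning warm-starts from the current detector state. A round with
zero candidates aborts the loop with advice to lower θ, rather than
silently fine-tuning on nothing.

## Evaluation stack

Matching follows the VOC protocol: detections in descending score
order, each claiming the unmatched ground truth with highest IoU ≥ the
threshold (0.5 everywhere here); duplicate hits are false positives;
score ties break by larger IoU, then insertion order, making runs
deterministic. Precision, recall and F1 are computed at a single
operating point (the detector's own θ when reporting sweep tables);
0/0 is reported as 0 and logged. AP integrates the exact
(all-point) area under the monotone precision envelope of the pooled
precision-recall curve — no 11-point interpolation — and mAP averages
AP over classes, collapsing to AP in the single-class fruit setting.
AP with zero ground-truth boxes raises an explicit error instead of
returning 0.

## Synthetic scenes

Each frame (default 256×256) contains:

* a foliage background: green-hued pixel noise (H ≈ 0.30, S ≈ 0.25)
  with a smooth low-frequency brightness field and elliptical leaf
  blobs;
* 3–7 round fruits, radius ~N(20, 3) px so a typical box is ~40×40 px
  (the small-target regime), colored by a per-species HSV model with
  per-pixel jitter, a per-fruit hue offset (sd 0.015, ripeness
  variation), per-fruit brightness jitter (±15 %), and radial shading
  (25 % value falloff at the rim);
* occluding leaves drawn over each fruit with probability 0.5; a
  fruit's ground-truth box is the tight bounding box of its *visible*
  pixels, and fruits with < 25 % visible pixels are not annotated;
* 3–6 warm-hued distractor blobs (H ≈ 0.05, radius 4–8 px) — dry
  leaves, soil — that a color detector with a miscalibrated model
  confuses with fruit, but whose pixel mass is small enough that
  refitting on pseudo-label regions is dominated by true fruit pixels.

All randomness flows through `numpy.random.default_rng` on per-image
seeds derived from `(seed, split, index)`, so generation is
bit-reproducible and adding images never perturbs existing ones.

The packaged default scenario uses an orange-hued source (H 0.08) and a
red-hued target (H 0.975, circular distance ≈ 0.10, several times the
within-species spread) with 16 training and 8 test frames per domain —
sizes chosen so a full threshold sweep runs in well under a minute while
every per-round quantity remains estimable. What the generator does
**not** emulate: real fruit texture and specular highlights, shape and
scale differences between species, perspective and depth-of-field,
correlated lighting across a field session. Passing tests therefore
demonstrate the correctness and the qualitative dynamics of the
labeling-transfer machinery (species gap, improvement from
self-learning, supervised ceiling), not photometric performance on real
orchard imagery.

## Domain transform stand-in

The packaged `HueShiftTransform` is a parametric, gated HSV remap, not
a learned translator: pixels that look like source fruit (hue within
0.06 of H 0.08, S ≥ 0.4, V ≥ 0.3) get their hue rotated and their
saturation/value scaled; all other pixels pass through. Its default
parameters deliberately land ~0.035 in hue away from the true target
model — a learned image-translation network is never perfect, and that
residual miscalibration is precisely what the self-learning loop is
there to absorb. The `DomainTransform` contract (transform preserving
image shape; boxes copied verbatim) is the seat where a real CycleGAN
generator plugs in.

## Reference detector

`ColorLikelihoodDetector` models fruit appearance as an independent
per-channel Gaussian in HSV (hue treated circularly) and scores each
pixel `exp(-z̄²/2)` with `z̄²` the mean squared per-channel z-score.
Design choices that matter:

* **Robust fitting.** The color model is estimated from the pixels
  inside the ellipse inscribed in each training box (fruits are round;
  box corners are background) using median / scaled-MAD location and
  scale. Plain mean/sd over whole boxes lets occluder contamination
  inflate the hue spread until the model loses species specificity
  entirely. Scale floors at 0.01 avoid degenerate models.
* **Segmentation.** The score map is gated at `pixel_gate` (0.15),
  cleaned by morphological closing and hole filling, and split by a
  watershed on the smoothed distance transform (peak separation 12 px,
  peak strength ≥ 3) so touching fruits separate without shredding
  single fruits. Blobs under `min_area` (9 px) are dropped.
* **Confidence.** A box's confidence is the mean pixel likelihood over
  its blob — already a calibrated [0, 1] quantity, so it is used raw. A
  per-batch min-max rescaling was considered and rejected: it would pin
  the best score of every round at 1.0, making θ relative to the batch
  and incomparable across rounds.
* **Fine-tuning.** Each round re-estimates a model from the
  pseudo-label regions and blends it into the current one with weight
  λ = 0.5 (`blend_weight`), halving the parameter gap per refit — the
  color-model analogue of a few epochs of gradient fine-tuning.

The detector keeps the failure mode that motivates the whole pipeline:
fitted on raw source colors it scores the target split at mAP ≈ 0.08;
fitted on the repainted source it reaches ≈ 0.88 but confuses distractor
clutter with fruit; three self-learning rounds close the rest of the gap
to the supervised ceiling.

## Defaults and tunables

| Parameter | Default | Meaning |
|---|---|---|
| `theta` | 0.3–0.7 sweep | pseudo-label confidence threshold θ |
| `n_updates` | 3 | self-learning rounds N |
| `finetune_rounds_per_update` | 1 | detector refits per round |
| `blend_weight` | 0.5 | fine-tune blend λ toward new statistics |
| `pixel_gate` | 0.15 | per-pixel likelihood gate for segmentation |
| `min_area` | 9 px | smallest accepted blob |
| `iou_threshold` | 0.5 | match criterion for all metrics |
| `min_visible_fraction` | 0.25 | occlusion culling for ground truth |

θ trades pseudo-label quality against quantity: too low admits clutter,
too high starves the refit or locks onto the few highest-scoring blobs
(the sweep harness exposes both regimes, including aborted cells).
N beyond 3 gives diminishing returns at λ = 0.5 since the model gap
shrinks geometrically.

## Known limitations

* The mean-score filter assumes pseudo-label noise is a minority of the
  candidate mass; when the majority of high-confidence candidates are
  wrong (e.g. θ set so high that only clutter passes), the loop can
  converge to the wrong mode — visible in sweep cells at θ ≥ 0.5 on
  some seeds. This is a property of the method, reproduced faithfully.
* Greedy matching is not the optimal assignment; on rare crowded
  configurations it undercounts TP relative to the exhaustive optimum
  (the test suite quantifies the divergence rate).
* The reference detector is purely chromatic: it cannot separate
  touching fruits of identical color beyond what the watershed
  recovers, and it has no notion of texture or shape.
* VOC XML is written in the 1-based inclusive dialect and converted on
  read; tools using a 0-based VOC dialect will see one-pixel offsets.
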