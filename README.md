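# fruitlabel

Automatic annotation transfer for fruit detection across species.

Orchard phenotyping pipelines need bounding-box labels for every fruit
species they monitor, but detection models are species-specific: a
detector trained on labeled oranges fails on apples because the fruits'
color statistics differ (the *species gap*), and relabeling thousands of
images per species by hand is the bottleneck. `fruitlabel` implements a
pseudo-label self-training pipeline that turns a labeled source-species
dataset plus an unlabeled target-species dataset into a *labeled* target
dataset, with no manual target annotation:

1. **Domain transform.** A source→target appearance transform `M₁`
   repaints each source image `I_S` into a fake target image
   `I_F = M₁(w₁, I_S)` while fruit positions — hence boxes — stay fixed,
   producing a labeled fake-target training set `D_F`.
2. **Pseudo-label generation.** A detector `M₂` initialized on `D_F` is
   run over every unlabeled target image `I_T`; detections with
   confidence ≥ a threshold θ become pseudo-label candidates
   `l_T = M₂(w₂, I_T, θ)`.
3. **Mean-score noise filtering.** The dataset-wide mean confidence
   `S_aver = Σᵢⱼ score(l_Tⁱʲ) / Σᵢ Nᵢ` acts as an adaptive cutoff:
   candidates scoring below `S_aver` are discarded. Because the maximum
   of a score set never falls below its mean, a non-empty candidate set
   always keeps at least one box.
4. **Cyclic self-learning.** For N rounds: regenerate pseudo labels with
   the current detector, filter at `S_aver`, fine-tune the detector on
   the surviving labels (warm start, labels replaced each round). Labels
   and detector improve together.

Evaluation uses the standard single-operating-point detection metrics at
IoU 0.5 — `Precision = Tp/(Tp+Fp)`, `Recall = Tp/(Tp+Fn)`,
`F1 = 2PR/(P+R)` — plus threshold-free AP/mAP as the exact area under
the precision-recall curve with a monotone precision envelope.

The package ships a seeded synthetic orchard-scene generator (small
round fruits ~40 px across, foliage clutter, shading, occlusion,
warm-hued distractor blobs, and a configurable per-species color model),
a parametric gated hue-remap standing in for a learned image-translation
network, and a trainable color-likelihood blob detector, so the entire
pipeline runs end to end on one CPU in seconds. Both the transform and
the detector are contracts (`DomainTransform`, `Detector`): a CycleGAN
or a YOLO-family network can be plugged in without touching the loop.

## Worked example

```bash
fruitlabel pipeline --out demo --seed 0 --theta 0.3
```

runs synth → transform → fit → self-train (N = 3) → evaluate on the
packaged scenario (orange-hued source, red-hued target, 16 training and
8 held-out test frames) and prints

```json
{
 "baseline_mAP": 0.8791012321624568,
 "self_learned_mAP": 1.0
}
```

The baseline row is the detector fitted on the repainted source only:
its residual color miscalibration lets clutter outscore some fruit
(precision 0.60 at the θ = 0.3 operating point, mAP 0.879). Three
self-learning rounds re-estimate the color model from its own filtered
pseudo labels — the per-round trace in `demo/report.json` shows
`S_aver` rising 0.519 → 0.573 while the filter discards roughly half of
the candidate boxes each round — and the adapted detector reaches
precision 0.977 and mAP 1.0 on the held-out split. A detector fitted
directly on the raw source colors, for comparison, scores mAP ≈ 0.08 on
the same split: the species gap the pipeline exists to close.

Every subcommand (`synth`, `transform`, `fit`, `pseudo-label`,
`self-train`, `evaluate`, `sweep`, `pipeline`) writes a resolved-config
snapshot next to its outputs, and every run is bit-reproducible from
snapshot + seed.

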