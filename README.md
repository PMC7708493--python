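# kidneyvol

Automated parenchymal kidney volumetry for dual-station neck-to-knee body
MRI. Kidney tissue is typically split across two overlapping breath-hold
imaging stations of a water/fat (Dixon-type) acquisition; `kidneyvol`
segments each station slice-wise with a 2.5D encoder–decoder network, fuses
the stations onto a common voxel grid, measures left and right parenchymal
volume and inter-kidney distance, and applies rule-based algorithmic quality
control to flag likely failure cases in large cohorts — all exercisable end
to end on a bundled synthetic phantom generator, so no restricted cohort
data is needed to develop, test or validate the pipeline.

**Who it is for:** image-analysis researchers working on organ volumetry in
population-imaging MRI, and anyone who needs a fully testable reference
implementation of multi-station segmentation volumetry with algorithmic QC.

## The method

* **2.5D segmentation.** Each axial slice *i* of the water signal is stacked
  with its neighbours (*i*−1, *i*, *i*+1; periodic at station ends) into a
  3-channel sample, normalized per station after clipping the brightest 1 %
  of intensities, and symmetrically zero-padded so both in-plane dimensions
  divide the network's downsampling factor (224 × 174 → 224 × 192 for the
  factor-32 network). A U-Net-style encoder–decoder (VGG-like widths
  64–128–256–512–512, long skip concatenations, ResNet-style short skips)
  predicts per-pixel class scores for the central slice; training uses
  pixel-wise cross-entropy, batch size one, Adam at lr 10⁻⁴ dropped ×10 late
  in an 80 000-iteration schedule, and online elastic augmentation. The
  network is implemented in pure numpy with explicit forward/backward
  passes.
* **Station fusion.** Predicted foreground probabilities and intensities
  are blended across the overlap with a linear 0→1 ramp and thresholded at
  0.5, yielding one fused label volume per subject.
* **Measurement.** The two largest 6-connected components are taken as the
  kidneys (left = larger column-axis centre of mass); volume is voxel count
  × voxel volume (cm³), with the inter-kidney Euclidean distance (mm) and
  the *scrap fraction* — labelled voxels outside the two largest components.
* **Quality control.** Five per-subject costs (image fusion, segmentation
  fusion, location, smoothness, scrap) feed two flagging stages: the worst
  1 %/1 %/2 % tails of location/image-fusion/segmentation-fusion cost, then
  the worst 1 %/1 % of smoothness/scrap cost among the survivors.
* **Validation.** Dice and Jaccard on fused volumes; MAE, SMAPE
  (|Δ| ÷ mean(pred, ref) × 100 — a 25 cm³ difference at mean 250 cm³ is
  10 %), R², and Bland–Altman 95 % limits of agreement on d = reference −
  predicted; plus k-fold subject-level cross-validation with an optional
  training-only extra pool.

## Worked example

`examples/02_fuse_and_measure.py` feeds a phantom's ground-truth labels
through fusion and measurement (network bypassed):

```
fused grid: (64, 54, 24), overlap slices (8, 16)
left kidney:   124.17 cm^3   (truth 124.17)
right kidney:  165.97 cm^3   (truth 165.97)
combined:      290.14 cm^3
inter-kidney distance: 93.3 mm
components: 2, scrap fraction 0.0000
```

With aligned stations the fusion blend is exact, so the measured volumes
match the generator's voxel-count truth; the scrap fraction 0 says every
labelled voxel belongs to one of the two kidney components.

`examples/03_train_and_validate.py` trains a width-reduced network for
2000 iterations on 48 phantom slices (a few minutes on one CPU) and scores
five held-out phantoms through the full predict → fuse → measure path:

```
mean dice 0.981 | MAE 1.0 cm^3 | SMAPE 0.3% | LoA (-2.7, 1.9) cm^3
```

`examples/04_quality_control.py` rates a 50-phantom cohort with one
injected large-motion subject and flags the worst percentile tails — the
motion subject tops the fusion-cost tail and is excluded.

The same stages are available as a CLI over a single YAML config:

```bash
kidneyvol simulate --config config.yaml   # phantom cohort -> NIfTI + manifest
kidneyvol train    --config config.yaml
kidneyvol infer    --config config.yaml   # labels + measurements.csv
kidneyvol qc       --config config.yaml   # quality table with flags
kidneyvol validate --config config.yaml
kidneyvol report   --config config.yaml
```

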