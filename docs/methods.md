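# Methods

This note documents the models, parameter choices and numerical conventions
behind `kidneyvol`, and what the synthetic phantoms do and do not establish
about behaviour on real data.

## Coordinate and label conventions

All volumes are `data[row, column, slice]` with row = anterior–posterior,
column = left–right, slice = longitudinal (SI). The subject's **left** side
lies at increasing column index; left/right kidney assignment uses the
column-axis centre of mass of the two largest components, and the phantom
generator places kidneys under the same convention. Voxel indices are
0-based; `origin_mm` is the physical position of voxel (0, 0, 0) and is what
registers the two stations along the table axis. Label volumes may carry
hard 0/1 labels or foreground probabilities; every thresholding step uses
`p >= 0.5 → kidney`.

## Synthetic phantoms

Each subject is an analytic scene rendered on a whole-trunk grid and split
into two overlapping stations, so station content, per-station truth and
whole-volume truth are consistent by construction.

* **Geometry.** Default grid 224 × 174 × 64 voxels at (2.232, 2.232, 4.5) mm
  with stations of 44 slices; the station overlap (24 slices, so
  2·44 − 24 = 64) is a configurable package choice — overlap extent is not a
  published acquisition parameter. `PhantomConfig.desk_scale()` keeps all
  anatomy in physical mm but coarsens the grid to 64 × 54 × 24 voxels at
  (4.5, 4.5, 6.0) mm, stations of 16 slices overlapping by 8; this is the
  problem size used throughout the test suite and examples.
* **Kidneys.** Superellipsoids (exponent 2.5 — boxier than an ellipsoid,
  closer to a real kidney silhouette) with semi-axes sampled per subject
  (defaults ≈ (17–23, 26–33, 46–58) mm for AP/LR/SI, giving parenchymal
  volumes of roughly 100–170 cm³ per kidney), minus an interior ellipsoidal
  hilum on the medial side rendered as dark tissue. The hilum is a
  concavity, not an amputation: any sliver it would disconnect is reassigned
  to the dark class so an anomaly-free kidney is always one 6-connected
  body. Truth masks cover exactly the voxels whose noiseless water
  intensity is the parenchyma class.
* **Channels and noise.** Water: air 0.05, trunk tissue 0.35, parenchyma
  0.85, dark structures 0.12 (arbitrary units); fat channel inverts kidney
  contrast. Additive Gaussian noise (sd 0.03) clipped at zero, drawn
  independently per station. No Rician noise, coil bias or water–fat swaps:
  phantom realism targets the pipeline's *contracts* (geometry, contrast
  ordering, overlap consistency), not MRI physics.
* **Motion.** Breath-hold misalignment is a rigid shift of the station-2
  scene content. The cohort generator draws per-subject baseline offsets
  with sd (0.25, 0, 0.4) mm — deliberately sub-voxel: the fusion stage's
  volume-consistency contract (truth-through-fusion within 2 %) bounds how
  much misalignment an *anomaly-free* subject may carry, since the measured
  sensitivity is ≈1.2 % volume error per mm of longitudinal shift. Severe
  misalignment is modelled explicitly by the `large_motion` tag
  ((6, 0, 9) mm), which the quality-control stage must catch.
* **Anomalies.** `missing_left/right` (true volume 0 on the absent side),
  `cysts` (dark spheres carved out of truth — may fragment the parenchyma,
  as severe cystic disease does), `fused` (a bright isthmus joins the
  kidneys into one component), `border_truncation` (kidneys pushed onto the
  outer station edge, driving the location cost).

## Network and training

The segmentation network is a 2.5D U-Net-style encoder–decoder implemented
directly in numpy (im2col convolutions, 2× max-pooling, nearest-neighbour
upsampling, long skip concatenations, ResNet-style additive short skips
around each two-convolution block, 1×1-convolution head to two classes).
Full-scale widths (64, 128, 256, 512, 512) mirror an 11-layer VGG encoder;
five pooling stages give downsampling factor 32, which fixes the pad
multiple. Residual placement (identity addition around each block, 1×1
projection on channel change) is a package choice; no batch normalization
is used. Weights are He-initialized; an external encoder checkpoint can be
loaded through `load_encoder_weights` (no pretrained weights ship with the
package).

Training is iteration-based with batch size one, uniform slice sampling,
pixel-wise softmax cross-entropy and Adam. Full-scale defaults: 80 000
iterations at lr 10⁻⁴, dropped once ×10 at iteration 60 000. Online
augmentation warps each sample with a smooth random displacement field
(4 × 4 control grid, Gaussian-smoothed, default max amplitude 10 px; linear
interpolation for images, nearest-neighbour for labels so they stay
binary). The outermost `drop_ends = 2` slices of each station are excluded
from training as artefact-prone.

`TrainingConfig.desk_scale()` is the CPU-scale protocol used in tests and
examples: 2000 iterations at lr 3·10⁻⁴ dropped at 1500, elastic amplitude
3 px. The learning rate is raised because the schedule is 40× shorter; the
amplitude is scaled to the coarse desk voxels (10 px at 4.5 mm/px would be
a ~45 mm warp). With width multiplier 0.125 (~0.5 M parameters) this trains
in a few minutes on one CPU and reaches Dice ≈ 0.98 on held-out phantoms —
a statement about the pipeline's learnability on phantom contrast, not
about performance on real MRI.

## Fusion, measurement, quality control

* **Blend.** Across an L-slice overlap the station-b weight at overlap
  slice t is (t+1)/(L+1), so weights are strictly inside (0, 1), sum to 1
  and ramp toward each station's interior. Probabilities are blended, then
  thresholded — using the network's soft output reduces seam artifacts
  compared with majority-voting hard labels. Zero overlap degrades to
  concatenation with a warning.
* **Components.** 6-connectivity (face neighbours) resists single-voxel
  diagonal bridges between the kidney and nearby mislabels; ordering is by
  size with ties broken by smallest linear voxel index, making results
  deterministic. `scipy.ndimage.label` does the labelling; the test suite
  checks it against an independent breadth-first flood fill.
* **Quality costs.** The five cost definitions (mean absolute overlap
  intensity difference; 1 − Dice of the two stations' labels on the
  overlap; |z_COM − z_mid| ÷ (z_extent/2); mean |ΔA(z)| ÷ mean A(z) over
  the active slice range; scrap share) are the package's normative,
  prose-reconstructed definitions — the original exact formulas were never
  published. Degenerate inputs: empty overlap is an error (manual review),
  empty masks rate worst for location and zero for smoothness/scrap,
  single-slice masks rate zero smoothness with a warning.
* **Flagging.** Each percentile tail flags the strictly-worst
  max(1, ⌊f·n⌋) subjects per cost. The floor keeps stage-wise flag
  fractions within the union bound of the configured settings; the
  strictness rule means all-identical cohorts flag nobody; the max(1, ·)
  keeps "top f % of worst" meaningful on small cohorts. Stage 2 recomputes
  its tails over stage-1 survivors only. Re-inclusion of small subjects
  flagged only for border proximity is a manual override column, not
  automated.

## Validation metrics

Dice and Jaccard are computed only on fused subject volumes (per-station
scores would average in empty stations). Two empty masks score 1.0 by
default (perfect-agreement convention; configurable to 0). SMAPE divides
by the mean of prediction and reference — robust to which segmentation is
treated as truth, given known inter-operator variation. R² is the
regression-free form 1 − Σd²/Σ(ref − mean ref)², reported as absent for
constant references. Limits of agreement use d = reference − predicted
with the exact 1.96 multiplier and sample (ddof = 1) SD; systematic
oversegmentation therefore shifts the interval negative. Cross-validation
splits subjects (never slices) into k folds; an optional extra pool joins
every training set but never a validation fold.

## Known limitations

* Phantom contrast is far easier than real MRI: no organs that mimic
  kidney intensity (spleen/liver mislabels, a genuine failure mode of the
  approach, cannot arise), no bias fields, no water–fat swaps. Passing
  tests establish the pipeline's internal consistency and its behaviour
  under the injected failure modes, not cohort-level accuracy.
* The numpy network trains desk-scale models in minutes but is not suited
  to full-resolution 80 k-iteration training.
* No mosaicing/registration correction is applied before fusion; severe
  motion is flagged, not repaired.
* Two-largest-component volumetry misreports the rare case where
  fragmentation puts both major components on the same side; the scrap and
  smoothness costs are designed to flag such subjects for scrutiny.
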