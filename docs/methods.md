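# Methods

## The problem and the pipeline

Label-free DIC microscopy shows cells as relief-like intensity gradients;
fluorescence staining shows specific structures (here F-actin and nuclei)
but is phototoxic and bleaches. The package learns the mapping
DIC z-stack → fluorescence channel as supervised image-to-image regression,
one model per channel, and wraps it in a transfer-learning workflow:
pretrain a model ensemble on diverse "local" datasets, match an unseen
target dataset to the most similar local one, fine-tune the matched U-Net
and cGAN with ~16 target pairs, and combine their predictions. Virtual
stains then drive single-cell morphometry and a YAP nuclear/cytoplasmic
(n/c) ratio predictor.

Images are float64 in [0, 1]; integer TIFFs are rescaled by their dtype
maximum on load and quantized to 16 bit on write (round-trip error
≤ 1/65535). Coordinates are (row, col), 0-based. The DIC input is a
z-stack presented to the networks as input channels (slice count
configurable; stacked channels rather than a projection, so the models can
exploit defocus structure).

## Models

All five families map (in_slices, H, W) → (1, H, W) with a final sigmoid:

- **unet / res_unet / att_unet** — encoder-decoder, double 3×3 conv blocks,
  2× average pooling / nearest upsampling, skip concatenation; residual
  variant adds 1×1 projection shortcuts per block; attention variant gates
  each skip with an additive attention coefficient map.
- **deeplab** — two stride-2 stages, atrous spatial pyramid pooling
  (dilations 1, 2, 4) at 1/4 resolution, lightweight decoder; adapted to
  regression with a linear 1-channel head before the sigmoid.
- **cgan** — U-Net generator plus a patch discriminator conditioned on the
  input stack, least-squares adversarial loss + L1 (λ = 100).

Two presets: `paper` (depth 4, width 64, lr 2e-4, batch 4, 512-px I/O,
mirroring common full-scale defaults) and `tiny` (depth 3, width 8,
64–128 px), the default for tests and the demo. Everything runs on a
purpose-built numpy reverse-mode autodiff engine (`cellvstain.nn`):
float64 throughout, deterministic given the seed, gradient-checked against
finite differences in the test suite.

Tiny-preset optimization is Adam, lr 5e-4, batch 2, 50 epochs, MAE loss
for the U-Net family and DeepLab. This calibration matters: the MAE
objective has a constant-output (median-predicting) plateau, and with
16-pair datasets larger batches give too few updates while larger learning
rates oscillate around the plateau instead of escaping it. Validation PCC
is computed per epoch on a carved-out fraction of the training rows, the
best-validation weights are checkpointed, and early stopping (patience 10)
is disabled for the first 30 epochs so the plateau cannot trigger it.
Nuclei-channel models in the demo use width 16: the nuclear envelope's
relief is a subtler label-free cue than the cell outline, and width-8
models compress the predicted nucleus size toward a prototype.

Prediction is deterministic; images larger than the training size can be
processed as overlapping tiles blended with triangular feather weights
(no seams on constant input by construction).

## Poisson-blending data augmentation

Cells are isolated from the binarized F-actin channel (Otsu on a 1-px
Gaussian-smoothed image, hole filling, 8-connectivity, min area 50 px,
border components dropped by default); each instance stores the mask plus
DIC/F-actin/nuclei crops at the bounding box padded by 2 px (fluorescence
zeroed outside the mask, DIC kept for true surround gradients). Composites
paste up to 20 randomly chosen instances, each uniformly rescaled in
[0.8, 1.2] (bilinear for intensities, nearest + 0.5 re-threshold for
masks), at uniform locations; a location overlapping previously accepted
masks is re-drawn up to 100 times before the instance is skipped. Accepted
instances are blended into every channel (each DIC slice, F-actin, nuclei)
with the same mask and location by solving the discrete Poisson equation
with Dirichlet boundary values from the background (scipy sparse solve;
plain gradients — mixed gradients are an option flag, off by default, since
convex cell shapes do not produce the blending artifacts reported for
irregular pasted objects). Overlap checking uses masks, not bounding boxes.

## Dataset matching

A small VGG-style CNN (3 conv-pool stages, global average pooling, softmax)
classifies 64-px center crops of the middle DIC slice, standardized per
image, into the local dataset ids; training patches get 8-fold dihedral
augmentation (morphology and scale cues are orientation-free). The matcher
trains on the train split only; held-out accuracy is logged. A target
dataset is matched by majority vote over its images; ties break by mean
class probability, then class order. The full-size VGG16 of the original
workflow is unnecessary at this scale; the contract is supervised matching,
not a specific capacity.

## Fine-tuning and combination

U-Net-family fine-tuning trains all layers at lr × 0.1 (configurable);
optimizer state is reset. cGAN fine-tuning reinitializes the last
discriminator layer (fresh He draw, zero bias), trains it at the base lr,
and everything else at the reduced lr; the model records exactly which
parameters were reinitialized so the surgery is auditable. The combined
predictor is pixel-wise `w·unet + (1−w)·cgan` on [0, 1] predictions; `w`
is selected from the grid {0, 0.1, …, 1} by mean patch-wise PCC on
validation pairs, ties preferring `w` nearest 0.5.

## Evaluation metric

Patch-wise Pearson correlation with a denominator regularizer ε = 1e-8
(so constant patches give r = 0 rather than dividing by zero). Patches are
non-overlapping, anchored at (0, 0), trailing partials dropped; the default
patch equals the model I/O size (512, or the image size if smaller); the
mean over patches is unweighted.

## Single-cell morphometry

17 features per cell: area, perimeter, minor/major axis for cell and
nucleus (8 "basic" parameters); compactness 4πA/P² and eccentricity
√(1−(b/a)²) and major-axis angle for both compartments (6); mean F-actin
intensity over the cell and mean nuclei intensity over the nucleus (2);
and the nuclear/cytoplasmic **area** ratio nuc_area/(cell_area−nuc_area)
(1). The area convention is used because these features derive from
F-actin/nuclei stains, where an intensity n/c ratio is not YAP-meaningful.
Conventions: perimeter is the 4-direction Crofton estimator (the weighted
boundary-step estimator biases a digital disk's compactness ~9% low);
axes/orientation/eccentricity come from second central moments
(equivalent-ellipse convention, skimage regionprops); angle is measured
from the row axis in degrees in [−90, 90); lengths and areas are physical
given the pixel size. Segmentation from stains takes cells as binarized
F-actin components and nuclei as binarized-nuclei components assigned to
the cell containing most of their area; cells without exactly one nucleus
are excluded by default (manual masks can be supplied instead, flagged in
provenance). Live-cell tracking links per-frame segmentations by nearest
centroid within a distance gate (ties broken by mask overlap) and flags a
division when two cells claim the same track.

## YAP prediction

Ground truth n/c ratio = mean YAP intensity over the nucleus ÷ mean over
the cytoplasm (cell minus nucleus); background subtraction is an option,
off by default. The predictor is an MLP with hidden layers (256, 256, 4),
ReLU, scalar linear output, squared-error loss — implemented with sklearn's
MLPRegressor. Features are z-scored with training-set statistics only
(zero-variance features left unscaled with a warning). Optimization is
Adam, lr 5e-4, minibatch 16, ≤2000 iterations with early stopping; because
the narrow width-4 layer can die at initialization, training restarts three
times and keeps the best internal-validation fit. Full-batch Adam at
lr 1e-3 was markedly less reliable at these sample sizes.

## Synthetic data

The generator emulates adherent cells in paired DIC/fluorescence images
with exact ground truth. Cell boundaries are ellipses with low-order
Fourier radial perturbation, area-normalized so the mask area stays within
a few percent of πab; `round` style is nearly elliptical with
multiplicative speckle in F-actin, `protrusive` style is elongated with
1–3 narrow Gaussian lobes (pseudopods). Nuclei are interior ellipses
(0.38–0.5 of the cell axes, small offset). The DIC model is the signed
45°-directional gradient of a smooth phase map offset to mid-gray; the
phase map is a paraboloid cap per cell plus a flat-top plateau over the
nucleus — the plateau concentrates gradient at the nuclear envelope, which
is what makes nucleus geometry inferable from the label-free channel (as
it is in real DIC). Defocus z-stacks apply increasing Gaussian blur per
slice. Noise is additive Gaussian (σ = 0.02 default). Cells are placed
without overlap with a 3-px gap (so binarization separates neighbours);
placement failure after bounded attempts raises an error carrying the
achieved count. What this generator does **not** emulate: real DIC optics
(PSF, shear interference), intensity inhomogeneity, debris and clumping,
out-of-focus fluorescence, and camera noise statistics — so passing tests
demonstrate the pipeline's correctness and its behavior under controlled
domain shift, not real-data performance.

The YAP benchmark samples 17 coherent features from ellipse geometry and
sets the true ratio to 1.6 + 0.35·z(nuc_area) + 0.30·z(cell_ecc) −
0.25·z(nc_ratio) + noise, with fixed population normalization constants so
the ground-truth map is identical across draws; noise σ is a fraction
(default 10%) of the signal σ. An optional 3-condition design shifts cell
elongation per group with the middle group highest — a non-monotone
optimal-stimulus response the predictor must reproduce.

## The demo recipe

`cellvstain demo --seed 1` (or `workbench.run_recipe`) runs the whole
pipeline at problem sizes chosen for a single CPU: four local datasets
(2 styles × 2 magnification scales, 40 pairs each: 16 train / 24 test;
64-px fields at 10×, 80-px at 40× so the large cells are not truncated;
3 slices), one target dataset (round, intermediate 1.15× scale, 48 pairs:
16 train / 32 test), 6 PBDA composites per local dataset, the 5-family
ensemble on the matched dataset (comparison-only families at a reduced
24-epoch budget), a 3-seed few-shot comparison at n = 16, grid
combination, feature agreement against rasterized ground truth, and the
YAP benchmark (train n = 200, independent 400-sample test draw, 3 seeds +
permutation null). The nuclei channel gets the harder geometry readout,
so its U-Net is wider (width 16) and its fine-tune runs 20 extra epochs;
the nuclei cGAN, a combination candidate only, trains 30 epochs. Feature
agreement is measured on a 2× supersampled grid (stains upsampled
bilinearly, ground truth rasterized analytically at 2×): the smallest
nuclei span only a few pixels and digitization noise would otherwise
dominate their axis estimates. Production model training is guarded
against the MAE constant-output collapse — if the best validation PCC
after training signals a never-escaped plateau, training restarts once
with a fresh initialization. The pretraining stage materializes weights
lazily — models are declared for every local dataset but gradient descent
runs only for the matched dataset's ensemble, which is observationally
equivalent and keeps the run around ten minutes. The summary JSON carries
every quantity the acceptance script reports.

## Known limitations

- The nn engine is CPU-bound float64 numpy; the `paper` preset topology is
  faithful but full-scale (512-px, width-64) training is impractical here.
- The synthetic DIC model is a caricature (directional gradient of a smooth
  phase map); models trained on it will not transfer to real microscopes.
- Matching relies on supervised classification between known local
  datasets; it cannot flag a target that resembles none of them.
- Automatic segmentation assumes separable cells; confluent monolayers
  need the manual-mask path.
- The YAP predictor is only as good as the 17 features; pixel-level YAP
  texture is deliberately out of scope.
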