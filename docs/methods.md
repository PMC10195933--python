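# Methods

## Problem

Screening mammography quality depends on positioning: the pectoralis
muscle should be visible at an adequate angle on the MLO view, the
inframammary fold should be imaged, the nipple should be in profile (and
centred on CC), the parenchyma must not be cut off, and the posterior
nipple line (PNL) lengths measured on CC and MLO should agree.  `mammoqa`
implements an automated reviewer for these criteria: per-feature CNN
classifiers, CNN landmark regressors, and closed-form geometric measures
derived from the regressed landmarks, evaluated with standard
classification statistics, localisation RMSE in millimetres, Cohen's
kappa, and Monte-Carlo confidence intervals.

Because no clinical images ship with the package, a synthetic phantom
generator provides the labelled data.  Its ground truth is exact by
construction, which turns the usual "accuracy against radiologists"
question into two testable ones: *can the networks recover the
generator's parameters?* and *does every pipeline stage preserve
coordinates and labels exactly?*

## Phantom model

Each phantom is an additive composition of smooth parametric shapes on a
dark background (default 512×512 px at 0.2 mm isotropic spacing):

- **Breast**: soft-edged half-ellipse anchored on the chest-wall edge;
  the vertical semi-axis is `breast_scale` × half the image height, the
  horizontal semi-axis a random 0.62–0.80 of it.
- **Pectoralis (MLO)**: a brighter wedge bounded by the line through the
  cranial landmark (top edge) and the caudal landmark (chest-wall edge,
  or the lowest in-image point for near-vertical margins).  The angle
  parameter is realised exactly; the returned landmarks are the analytic
  line endpoints, not raster measurements.  On CC an optional thin
  posterior crescent stands in for the muscle.
- **Nipple**: a Gaussian bump protruding from the skin line (in profile)
  or an interior blob at 72 % of the breast depth (not in profile); on CC
  an off-centre nipple is displaced 20 mm along the contour.
- **Inframammary fold (MLO)**: a bright arc along the inferior posterior
  contour.
- **Parenchyma**: 25 random Gaussian blobs inside the breast; an
  incomplete-parenchyma phantom truncates all tissue at 25 % of the
  breast depth from the chest wall.
- **Noise**: additive Gaussian (sd 0.02) after composition.

Laterality is realised by mirroring a canonical right-breast render, so
preprocessing must exercise its flip path.  Paired CC/MLO exams share
breast depth and shape draws, which makes the CC and MLO PNL agree within
a few millimetres on ideally positioned exams.

What the phantoms deliberately do **not** model: X-ray physics, scatter,
vendor look-up tables, lesions, implants, skin folds, or anatomical
variation beyond the shape parameters above.  Passing tests therefore
demonstrate that the pipeline, networks and statistics are implemented
correctly and can learn the geometric/photometric cues the criteria rely
on — not that the models would reach any particular accuracy on clinical
images.

## Preprocessing and coordinates

One convention everywhere: 0-based pixel-centre coordinates, `(x, y) =
(col, row)` in pixels, mm = pixel × spacing.  The chain is: content-based
horizontal canonicalisation (chest wall to the left; content-based makes
it idempotent), linear intensity windowing (per-image 1st/99th percentile
limits stand in for vendor LUTs), black padding to square (right stripe
for portrait, bottom stripe for landscape), bilinear resize to the model
side.  Every geometric step is recorded in a `TransformLog`; the flip map
is `x' = W − 1 − x` and resize maps coordinates by pure scaling, so the
forward∘inverse composition is exact to machine precision and regression
errors can be reported in original-frame millimetres.

## Networks and training

Both tasks share a VGG-style topology: 13 conv layers (3×3) grouped
2-2-3-3-3 with five 2×2 max-pools, batch normalisation after every conv,
two dense ReLU layers, 50 % dropout before the head.  Classification ends
in softmax with class-weighted cross-entropy (weights `N/(K·N_c)`);
regression ends in sigmoid over coordinates normalised by the model-frame
side, with MSE loss.  Training uses SGD, per-epoch augmentation
(rotation ±10°, shifts ±5 %, zoom ±10 %, with coordinates transformed
alongside images), a 3:1 train/validation split, and per-epoch checkpoint
selection (highest validation accuracy / lowest validation RMSE, earliest
on ties).

The default configuration is the full-scale recipe: 224 px input, full
channel widths (64…512), batch 32, lr 1e-5, 160 epochs.  The
**scaled-down profile** used for desk-scale experiments is the same code
path with 96 px input, width multiplier 0.25, 30 epochs, and momentum SGD
(0.9) at lr 0.01 — a standard recipe for a small batch-normalised CNN
trained from scratch; the full-scale learning rate is far too small for a
30-epoch budget.

The engine itself is a compact NumPy implementation (`mammoqa.nn`):
im2col patch matrices feed BLAS GEMMs, the input gradient is computed as
a convolution with the spatially flipped, channel-transposed kernel, and
all large work buffers persist across steps.  Everything is float32 and
seeded; on one thread, training histories are bit-reproducible.  Gradient
correctness is established in the tests by exact linearity checks for the
convolution and finite-difference checks for the smooth layers.

## Geometric quality features

All geometry operates in millimetres on landmark points:

- **Pectoralis angle**: angle between the cranial→caudal muscle line and
  the vertical posterior edge (0° = parallel to the chest-wall edge),
  folded into [0, 90]; invariant to swapping the landmarks.
- **PNL (MLO)**: perpendicular distance from the nipple to the infinite
  muscle line.
- **PNL (CC)**: horizontal distance from the nipple to the posterior
  image edge (the muscle is usually absent on CC).
- **PNL comparison**: CC and MLO lengths are called symmetric when they
  differ by at most 10 mm (a widely used positioning rule of thumb),
  inclusive at the boundary.
- **Pectoralis–nipple level**: the nipple is projected onto the muscle
  line; the offset is the signed along-line distance from the projection
  foot to the caudal landmark, positive when the muscle extends caudally
  beyond the nipple level; "reaches" is inclusive at zero.

## Pipeline and report

`assess_exam` runs five classifiers and three regressors per exam, maps
landmarks back through the TransformLogs, computes the geometric
features, and evaluates nipple centring on CC geometrically (|nipple y −
breast-mask midline| ≤ 15 mm) rather than with a dedicated classifier.
The report lists failed criteria as flags; no PGMI letter is assigned
because any mapping from flags to letters is site policy, not part of the
method.  A ground-truth `OracleBank` can be substituted for the networks;
with it, dataset evaluation must return accuracy exactly 1.0 and RMSE
exactly 0 — the end-to-end identity test of the plumbing.

Degenerate inputs: coincident pectoralis landmarks raise a
geometry error in the library API but are recorded as a
`geometry_degenerate` flag (not a crash) inside `assess_exam`; undefined
metric ratios (e.g. PPV with no positive predictions) are NaN with an
explicit flag, never silent zeros; `cohens_kappa` defines κ = 1 when both
raters are constant and identical.

## Evaluation statistics

Confusion metrics, unweighted Cohen's kappa and RMSE are computed in
closed form (cross-checked against scikit-learn in the tests).  The 95 %
Monte-Carlo interval has two modes: the default *probability* mode
redraws each item's correctness from the model's predicted probability of
being correct (B = 2000 replicates, percentile interval); *bootstrap*
mode resamples observed outcomes or per-item errors.  Coverage is
validated by simulation: for a calibrated reader with true accuracy 0.8
and item-level confidence dispersion Beta(0.8, 0.2), the interval covers
the truth in about 95 % of trials.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the package's own study conditions: 400 phantoms (300/100
split) for parameter recovery with the scaled-down profile; 1000 random
configurations for the geometry-oracle and coordinate round-trip sweeps;
50 phantom exams for the oracle pipeline identity; 1000 simulated trials
(n = 200, B = 2000) for CI coverage.  Under these conditions the
pectoralis-presence classifier reaches ≥ 0.90 validation accuracy and the
nipple regressor ≤ 5 mm validation RMSE; phantoms are easier than
clinical images, so those bounds are deliberately loose.

## Known limitations

- The phantom's defect thresholds (25 % truncation, 20 mm off-centre) are
  package conventions; clinical criteria are qualitative.
- Full-scale (224 px, 160 epochs) training is supported but not exercised
  by the tests; only the scaled-down profile is validated end to end.
- The CC "to-muscle" PNL variant is computed only when CC pectoralis
  landmarks are available, which the default phantom exam does not
  produce.
- Binarisation thresholds for angle/PNL adequacy are configurable
  defaults; no published cut-offs are implied.
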