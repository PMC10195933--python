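# mammoqa — automated mammography positioning quality assurance

`mammoqa` is a self-contained implementation of an automated reviewer for
screening-mammogram positioning quality.  It targets the criteria a PGMI
(Perfect/Good/Moderate/Inadequate) reviewer checks on a two-view exam:

- depiction of the **pectoralis muscle** (and its angle on MLO),
- the **inframammary fold** on MLO,
- **nipple in profile**, and **nipple centred** on CC,
- **complete parenchyma** (no posterior cut-off),
- agreement of the **posterior nipple line** (PNL) between CC and MLO,
- whether the muscle **reaches the nipple level** on MLO.

The package combines per-feature CNN classifiers and CNN landmark
regressors (a 13-conv/5-pool VGG-style network with batch norm, class
weighting, augmentation and per-epoch checkpoint selection, implemented
directly on NumPy/BLAS) with closed-form geometry on the regressed
landmarks.  For the posterior nipple line on MLO, the length is the
perpendicular distance from the nipple N to the muscle line through the
cranial/caudal edge points C₁, C₂:

    PNL_MLO = |(N − C₁) × (C₂ − C₁)| / ‖C₂ − C₁‖
    angle   = atan2(|Δx|, |Δy|)            (0° ⇒ parallel to the chest wall)
    level   = ‖C₂ − C₁‖ − (N − C₁)·û       (≥ 0 ⇒ muscle reaches nipple level)

Since clinical images are proprietary, the package ships a **synthetic
phantom generator**: parametric breast silhouettes with controllable
defects and *exact* ground-truth labels and landmarks.  That makes the
whole pipeline testable — networks must recover generator parameters,
geometry must match brute-force oracles, and an oracle predictor pushed
through the pipeline must yield accuracy 1.0 / RMSE 0 exactly.

## Worked example

Generate a phantom examination with one injected defect (no inframammary
fold), assess it with the ground-truth oracle standing in for the
networks, and read the report:

```python
from mammoqa import phantom, pipeline

cc, cc_gt, mlo, mlo_gt = phantom.generate_exam(
    phantom.ExamParams(seed=4, imf_present=False))
rep = pipeline.assess_exam(cc, mlo, pipeline.OracleBank(),
                           cc_truth=cc_gt, mlo_truth=mlo_gt)
print(rep.overall_flags)
q = rep.quality
print(f"angle {q['pect_angle_deg']:.1f} deg, "
      f"PNL MLO {q['pnl_mlo_mm']:.1f} / CC {q['pnl_cc_mm']:.1f} mm")
```

prints

```
['imf_not_visible']
angle 18.0 deg, PNL MLO 28.9 / CC 31.2 mm
```

The report flags exactly the injected defect; the PNL lengths agree to
2.2 mm (well inside the 10 mm symmetry tolerance), the muscle extends
12.1 mm past the nipple level, and the nipple sits 3.8 mm from the CC
midline — an otherwise well-positioned exam.

Training the scaled-down networks (96 px input, width multiplier 0.25,
30 epochs) on 400 phantoms:

```python
import numpy as np
from mammoqa import phantom
from mammoqa.models import PositioningClassifier
from mammoqa.preprocess import preprocess_for_model

data, _ = phantom.generate_dataset(400, seed=11, view="MLO")
X = np.stack([preprocess_for_model(r, side_px=96)[0].pixels
              for r, _ in data]).astype(np.float32)
y = np.array([int(gt.pect_visible) for _, gt in data])
clf = PositioningClassifier(input_side_px=96, width_multiplier=0.25,
                            epochs=30, lr=0.01, momentum=0.9, seed=0).fit(X, y)
print(clf.val_accuracy_)
```

The
pectoralis-presence classifier reaches ≥ 0.90 validation accuracy and the
nipple regressor localises to within 5 mm — see `docs/methods.md` for the
study conditions and what they do and do not demonstrate.

A `mammoqa` CLI wraps the same functions
(`generate`, `preprocess`, `train`, `assess`, `evaluate`).

## Layout

| Path | Contents |
| --- | --- |
| `src/mammoqa/phantom.py` | synthetic phantoms and paired exams with exact ground truth |
| `src/mammoqa/preprocess.py` | orientation/window/pad/resize with invertible coordinate logs |
| `src/mammoqa/nn.py` | NumPy CNN engine (conv/BN/pool/dense, SGD) |
| `src/mammoqa/models.py` | network configs, training loop, sklearn-style estimators |
| `src/mammoqa/geometry.py` | pectoralis angle, PNL, level offset |
| `src/mammoqa/evaluation.py` | confusion metrics, kappa, RMSE, Monte-Carlo CIs |
| `src/mammoqa/pipeline.py` | per-exam QA report and dataset evaluation |
| `src/mammoqa/cli.py` | command-line interface |
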