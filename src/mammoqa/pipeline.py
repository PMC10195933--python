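"""Per-examination quality-assurance flow and dataset-level evaluation.

One screening examination consists of a CC and an MLO projection of the
same breast.  ``assess_exam`` standardises both images, runs the five
feature classifiers (parenchyma CC/MLO, inframammary fold, pectoralis on
CC, nipple-in-profile on nipple crops) and the three landmark regressors
(nipple, pectoralis cranial and caudal edge points), converts landmarks
back to original-frame millimetres, derives the geometric quality
features (pectoralis angle, posterior nipple lines, pectoralis–nipple
level), and emits a :class:`QualityReport` whose ``overall_flags`` list
the failed positioning criteria.

Model access goes through a small predictor-bank interface so that the
trained CNNs can be swapped for a ground-truth oracle — that substitution
is the basis of the end-to-end identity tests (oracle in, perfect metrics
out).  No PGMI letter grade is assigned: the report lists failed criteria
and leaves any letter aggregation to a user-supplied rule table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import geometry
from .evaluation import MetricsResult, evaluate_classification, evaluate_regression
from .models import TrainedModel, predict_class, predict_landmark
from .preprocess import TransformLog, crop_nipple_region, preprocess_for_model, resize_to_model, pad_to_square
from .records import GroundTruth, ImageRecord

CLASSIFIER_NAMES = ("parenchyma_cc", "parenchyma_mlo", "imf",
                    "pectoralis_cc", "nipple_profile")
REGRESSOR_NAMES = ("nipple", "pect_cranial", "pect_caudal")


class ConfigError(ValueError):
    """A model bank or threshold configuration is incomplete."""


@dataclass
class Thresholds:
    """Pass/fail thresholds for the geometric criteria.

    ``pnl_tol_mm`` — maximum CC-vs-MLO posterior-nipple-line difference;
    ``center_tol_mm`` — maximum vertical nipple offset from the breast
    midline on CC; ``prob`` — classifier decision threshold.
    """

    pnl_tol_mm: float = 10.0
    center_tol_mm: float = 15.0
    prob: float = 0.5

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class QualityReport:
    """Machine-readable QA outcome of one examination."""

    exam_id: str
    features: Dict[str, dict]          # name -> {present: bool, probability: float}
    nipple_centered_cc: Optional[bool]
    nipple_offset_mm: Optional[float]
    quality: Optional[dict]            # geometry.QualityFeatures.to_dict()
    landmarks_mm: Dict[str, Optional[Tuple[float, float]]]
    thresholds: dict
    overall_flags: List[str]
    geometry_error: Optional[str] = None
    schema_version: int = 1

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True, default=float)

    @classmethod
    def from_json(cls, s: str) -> "QualityReport":
        d = json.loads(s)
        d["landmarks_mm"] = {
            k: (None if v is None else tuple(v))
            for k, v in d["landmarks_mm"].items()
        }
        return cls(**d)


class PredictorBank:
    """Uniform access to the eight positioning models.

    ``classifiers`` maps the names in :data:`CLASSIFIER_NAMES` to trained
    classification models; ``regressors`` maps :data:`REGRESSOR_NAMES` to
    trained landmark regressors.
    """

    def __init__(self, classifiers: Dict[str, TrainedModel],
                 regressors: Dict[str, TrainedModel]):
        missing = [n for n in CLASSIFIER_NAMES if n not in classifiers]
        missing += [n for n in REGRESSOR_NAMES if n not in regressors]
        if missing:
            raise ConfigError(f"missing models: {missing}")
        self.classifiers = classifiers
        self.regressors = regressors
        self.input_side_px = next(iter(classifiers.values())).config.input_side_px

    def classify(self, name: str, img: np.ndarray, gt=None) -> Tuple[bool, float]:
        pred = predict_class(self.classifiers[name], img)
        p_pos = float(pred.probabilities[1])
        return bool(pred.predicted_class == 1), p_pos

    def locate(self, name: str, img: np.ndarray, log: TransformLog, gt=None):
        return predict_landmark(self.regressors[name], img, log)


class OracleBank:
    """Ground-truth-backed stand-in for a trained PredictorBank.

    Used to validate the pipeline plumbing: with the oracle substituted
    for the networks, every classification is correct with probability 1
    and every landmark is exact, so dataset metrics must come out at
    accuracy 1.0 / RMSE 0.
    """

    def __init__(self, input_side_px: int = 96):
        self.input_side_px = input_side_px

    @staticmethod
    def _truth(name: str, gt: GroundTruth) -> bool:
        if name in ("parenchyma_cc", "parenchyma_mlo"):
            return bool(gt.parenchyma_complete)
        if name == "imf":
            return bool(gt.imf_visible)
        if name == "pectoralis_cc":
            return bool(gt.pect_visible)
        if name == "nipple_profile":
            return bool(gt.nipple_in_profile)
        raise KeyError(name)

    def classify(self, name: str, img: np.ndarray, gt: GroundTruth = None):
        if gt is None:
            raise ConfigError("OracleBank needs the ground truth per call")
        present = self._truth(name, gt)
        return present, 1.0 if present else 0.0

    def locate(self, name: str, img, log, gt: GroundTruth = None):
        if gt is None:
            raise ConfigError("OracleBank needs the ground truth per call")
        pt = {"nipple": gt.nipple_xy_mm,
              "pect_cranial": gt.pect_cranial_xy_mm,
              "pect_caudal": gt.pect_caudal_xy_mm}[name]
        return None if pt is None else np.asarray(pt, dtype=float)


def _posterior_edge_x_mm(rec: ImageRecord, log: TransformLog) -> float:
    """x of the chest-wall edge in the original frame (0 or far edge)."""
    flipped = any(s["op"] == "hflip" for s in log.steps)
    if flipped:
        return (rec.shape[1] - 1) * rec.pixel_spacing_mm[1]
    return 0.0


def _breast_midline_y_mm(rec: ImageRecord, bg: float = 0.15,
                         min_cols: int = 5) -> float:
    """Vertical midline of the breast silhouette on a CC view (mm).

    A row counts as breast only when several of its pixels clear the
    background threshold, so isolated noise pixels cannot stretch the
    silhouette extent.
    """
    counts = (rec.pixels > bg).sum(axis=1)
    rows = np.where(counts >= min_cols)[0]
    if rows.size == 0:
        return (rec.shape[0] - 1) / 2 * rec.pixel_spacing_mm[0]
    return (rows.min() + rows.max()) / 2 * rec.pixel_spacing_mm[0]


def _nipple_crop_model_frame(rec: ImageRecord, nipple_mm, side: int) -> np.ndarray:
    crop = crop_nipple_region(rec, nipple_mm, fraction=0.10)
    crop, _ = pad_to_square(crop)
    crop, _ = resize_to_model(crop, side)
    return crop.pixels.astype(np.float32)


def assess_exam(
    cc: ImageRecord,
    mlo: ImageRecord,
    bank,
    thresholds: Thresholds = Thresholds(),
    exam_id: str = "",
    cc_truth: GroundTruth = None,
    mlo_truth: GroundTruth = None,
) -> QualityReport:
    """Run the full QA flow on one CC+MLO examination.

    ``bank`` is a :class:`PredictorBank` (trained CNNs) or
    :class:`OracleBank` (ground truth; requires ``cc_truth``/``mlo_truth``).
    Degenerate landmark geometry is recorded as a flagged failure, not an
    exception.
    """
    if cc.view != "CC" or mlo.view != "MLO":
        raise ValueError("assess_exam expects (CC, MLO) in that order")
    side = bank.input_side_px
    cc_img, cc_log = preprocess_for_model(cc, side_px=side)
    mlo_img, mlo_log = preprocess_for_model(mlo, side_px=side)
    ccp = cc_img.pixels.astype(np.float32)
    mlop = mlo_img.pixels.astype(np.float32)

    features: Dict[str, dict] = {}
    for name, img, gt in (
        ("parenchyma_cc", ccp, cc_truth),
        ("parenchyma_mlo", mlop, mlo_truth),
        ("imf", mlop, mlo_truth),
        ("pectoralis_cc", ccp, cc_truth),
    ):
        present, prob = bank.classify(name, img, gt=gt)
        features[name] = {"present": present, "probability": prob}

    # landmarks (original-frame mm)
    nip_cc = bank.locate("nipple", ccp, cc_log, gt=cc_truth)
    nip_mlo = bank.locate("nipple", mlop, mlo_log, gt=mlo_truth)
    cranial = bank.locate("pect_cranial", mlop, mlo_log, gt=mlo_truth)
    caudal = bank.locate("pect_caudal", mlop, mlo_log, gt=mlo_truth)

    # nipple-in-profile: one model applied to the nipple crop of each view
    probs = []
    for rec, nip, gt in ((cc, nip_cc, cc_truth), (mlo, nip_mlo, mlo_truth)):
        crop = _nipple_crop_model_frame(rec, nip, side)
        _, p = bank.classify("nipple_profile", crop, gt=gt)
        probs.append(p)
    p_profile = float(min(probs))
    features["nipple_profile"] = {
        "present": p_profile >= thresholds.prob, "probability": p_profile,
    }

    # nipple centred on CC (geometric criterion from the regressed nipple)
    midline = _breast_midline_y_mm(cc)
    offset = float(nip_cc[1] - midline)
    centered = abs(offset) <= thresholds.center_tol_mm

    quality = None
    geometry_error = None
    if cranial is not None and caudal is not None:
        try:
            lm = geometry.LandmarkSet(
                nipple_cc_mm=tuple(nip_cc),
                nipple_mlo_mm=tuple(nip_mlo),
                pect_cranial_mm=tuple(cranial),
                pect_caudal_mm=tuple(caudal),
                posterior_edge_x_mm=_posterior_edge_x_mm(cc, cc_log),
            )
            quality = geometry.compute_features(lm, tol=thresholds.pnl_tol_mm).to_dict()
        except (geometry.DegenerateGeometryError, ValueError) as exc:
            geometry_error = str(exc)

    flags: List[str] = []
    if not features["parenchyma_cc"]["present"]:
        flags.append("parenchyma_cc_incomplete")
    if not features["parenchyma_mlo"]["present"]:
        flags.append("parenchyma_mlo_incomplete")
    if not features["imf"]["present"]:
        flags.append("imf_not_visible")
    if not features["nipple_profile"]["present"]:
        flags.append("nipple_not_in_profile")
    if not centered:
        flags.append("nipple_not_centered_cc")
    if quality is not None:
        if not quality["pnl_symmetric"]:
            flags.append("pnl_asymmetric")
        if not quality["pect_reaches_pnl"]:
            flags.append("pect_below_nipple_level")
    elif geometry_error is not None:
        flags.append("geometry_degenerate")

    def pt(p):
        return None if p is None else (float(p[0]), float(p[1]))

    return QualityReport(
        exam_id=exam_id,
        features=features,
        nipple_centered_cc=bool(centered),
        nipple_offset_mm=offset,
        quality=quality,
        landmarks_mm={
            "nipple_cc": pt(nip_cc), "nipple_mlo": pt(nip_mlo),
            "pect_cranial": pt(cranial), "pect_caudal": pt(caudal),
        },
        thresholds=thresholds.to_dict(),
        overall_flags=flags,
        geometry_error=geometry_error,
    )


def evaluate_dataset(
    exams: Sequence[Tuple[ImageRecord, GroundTruth, ImageRecord, GroundTruth]],
    bank,
    thresholds: Thresholds = Thresholds(),
    seed: int = 0,
) -> Tuple[Dict[str, MetricsResult], pd.DataFrame, List[QualityReport]]:
    """Compare pipeline predictions against ground truth over many exams.

    ``exams`` are ``(cc_record, cc_truth, mlo_record, mlo_truth)`` tuples.
    Returns per-feature metrics (classification accuracy/TPR/TNR/PPV/kappa
    with CIs, regression RMSE in mm), a tidy metrics table, and the
    individual reports.  Exams with missing ground truth are skipped with
    a warning row.
    """
    y_true: Dict[str, list] = {n: [] for n in CLASSIFIER_NAMES}
    y_pred: Dict[str, list] = {n: [] for n in CLASSIFIER_NAMES}
    reg_pred: Dict[str, list] = {n: [] for n in REGRESSOR_NAMES}
    reg_true: Dict[str, list] = {n: [] for n in REGRESSOR_NAMES}
    reports: List[QualityReport] = []

    for i, (cc, cc_gt, mlo, mlo_gt) in enumerate(exams):
        if cc_gt is None or mlo_gt is None:
            import warnings
            warnings.warn(f"exam {i}: missing ground truth, skipped")
            continue
        rep = assess_exam(cc, mlo, bank, thresholds, exam_id=f"exam-{i:04d}",
                          cc_truth=cc_gt, mlo_truth=mlo_gt)
        reports.append(rep)
        truth_of = OracleBank._truth
        for name in CLASSIFIER_NAMES:
            gt = cc_gt if name in ("parenchyma_cc", "pectoralis_cc") else mlo_gt
            if name == "nipple_profile":
                t = bool(cc_gt.nipple_in_profile and mlo_gt.nipple_in_profile)
            else:
                t = truth_of(name, gt)
            y_true[name].append(int(t))
            y_pred[name].append(int(rep.features[name]["present"]))
        pairs = [("nipple", rep.landmarks_mm["nipple_cc"], cc_gt.nipple_xy_mm),
                 ("nipple", rep.landmarks_mm["nipple_mlo"], mlo_gt.nipple_xy_mm),
                 ("pect_cranial", rep.landmarks_mm["pect_cranial"], mlo_gt.pect_cranial_xy_mm),
                 ("pect_caudal", rep.landmarks_mm["pect_caudal"], mlo_gt.pect_caudal_xy_mm)]
        for name, pred, truth in pairs:
            if pred is not None and truth is not None:
                reg_pred[name].append(pred)
                reg_true[name].append(truth)

    metrics: Dict[str, MetricsResult] = {}
    rows = []
    for name in CLASSIFIER_NAMES:
        if not y_true[name]:
            continue
        m = evaluate_classification(y_true[name], y_pred[name], seed=seed)
        metrics[name] = m
        rows.append({"model": name, "type": "classification", **m.to_dict()})
    for name in REGRESSOR_NAMES:
        if not reg_true[name]:
            continue
        m = evaluate_regression(reg_pred[name], reg_true[name], seed=seed)
        metrics[name] = m
        rows.append({"model": name, "type": "regression", **m.to_dict()})
    table = pd.DataFrame(rows)
    return metrics, table, reports
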