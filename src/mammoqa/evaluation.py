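"""Evaluation statistics: confusion metrics, Cohen's kappa, RMSE in mm,
and Monte-Carlo 95% confidence intervals.

Binary classification quality is summarised by accuracy, sensitivity
(TPR), specificity (TNR), precision (PPV) and F1; ratios with a zero
denominator are reported as NaN with an explicit flag rather than being
silently zeroed.  Landmark localisation error is the root mean squared
Euclidean distance between predicted and reference points in
millimetres.  Agreement between the automatic reader and the reference
labels uses unweighted Cohen's kappa.

Confidence intervals follow a Monte-Carlo scheme: in *probability* mode
each replicate redraws every item's correctness from its predicted
probability of being correct; in *bootstrap* mode replicates resample the
observed per-item outcomes (or errors) with replacement.  The interval is
the percentile range of the replicate statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np


@dataclass
class MetricsResult:
    """Point estimates (optionally with CIs) for one model/dataset pair.

    Undefined ratios are NaN and listed in ``undefined``.
    """

    n: int
    accuracy: float = np.nan
    sensitivity_tpr: float = np.nan
    specificity_tnr: float = np.nan
    precision_ppv: float = np.nan
    f1: float = np.nan
    rmse_mm: float = np.nan
    kappa: float = np.nan
    ci_95: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    undefined: Tuple[str, ...] = ()

    @property
    def recall(self) -> float:
        """Recall of the positive class (identical to sensitivity)."""
        return self.sensitivity_tpr

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "accuracy": self.accuracy,
            "sensitivity_tpr": self.sensitivity_tpr,
            "specificity_tnr": self.specificity_tnr,
            "precision_ppv": self.precision_ppv,
            "f1": self.f1,
            "rmse_mm": self.rmse_mm,
            "kappa": self.kappa,
            "undefined": list(self.undefined),
        }
        d["ci_95"] = {k: [float(lo), float(hi)] for k, (lo, hi) in self.ci_95.items()}
        return d


def _ratio(num: float, den: float):
    return (num / den) if den > 0 else np.nan


def confusion_metrics(y_true: Sequence[int], y_pred: Sequence[int]) -> MetricsResult:
    """Binary confusion-matrix metrics (positive class = 1).

    Accuracy = (TP+TN)/n, TPR = TP/(TP+FN), TNR = TN/(TN+FP),
    PPV = TP/(TP+FP), F1 = 2·PPV·TPR/(PPV+TPR).
    """
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    if yt.size == 0:
        raise ValueError("need at least one prediction")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    n = yt.size
    tpr = _ratio(tp, tp + fn)
    tnr = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    if np.isnan(tpr) or np.isnan(ppv) or (ppv + tpr) == 0:
        f1 = np.nan
    else:
        f1 = 2 * ppv * tpr / (ppv + tpr)
    undefined = tuple(
        name for name, v in
        (("sensitivity_tpr", tpr), ("specificity_tnr", tnr),
         ("precision_ppv", ppv), ("f1", f1))
        if np.isnan(v)
    )
    return MetricsResult(
        n=n, accuracy=(tp + tn) / n, sensitivity_tpr=tpr,
        specificity_tnr=tnr, precision_ppv=ppv, f1=f1, undefined=undefined,
    )


def cohens_kappa(rater_a: Sequence, rater_b: Sequence) -> float:
    """Unweighted Cohen's kappa over a shared label alphabet.

    When both raters are constant and identical, chance agreement is 1
    and kappa is defined as 1 (perfect agreement).
    """
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("rater vectors must be 1-D, equal length, non-empty")
    labels = np.unique(np.concatenate([a, b]))
    n = a.size
    idx = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    p_o = np.trace(table) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0)) / n ** 2)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return float((p_o - p_e) / (1 - p_e))


def rmse_mm(pred: Sequence, truth: Sequence) -> float:
    """Root mean squared Euclidean distance between paired points (mm)."""
    p = np.atleast_2d(np.asarray(pred, dtype=float))
    t = np.atleast_2d(np.asarray(truth, dtype=float))
    if p.shape != t.shape or p.size == 0:
        raise ValueError("pred and truth must have identical non-empty shapes")
    d2 = ((p - t) ** 2).sum(axis=1)
    return float(np.sqrt(d2.mean()))


def mc_confidence_interval(
    per_item: Sequence[float],
    level: float = 0.95,
    B: int = 2000,
    seed: int = 0,
    mode: str = "probability",
    statistic: str = "accuracy",
) -> Tuple[float, float]:
    """Monte-Carlo confidence interval for accuracy or RMSE.

    ``mode="probability"`` (classification): ``per_item`` are each item's
    predicted probabilities of being correct; every replicate redraws
    item correctness from those probabilities and records the accuracy.
    ``mode="bootstrap"``: replicates resample ``per_item`` (outcomes for
    accuracy, per-item error distances for RMSE) with replacement.
    Returns the percentile interval at ``level``; deterministic under
    ``seed``.
    """
    x = np.asarray(per_item, dtype=float)
    if x.size == 0:
        raise ValueError("per_item must be non-empty")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    if mode == "probability":
        if x.min() < 0 or x.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        draws = rng.random((B, x.size)) < x
        stats = draws.mean(axis=1)
    elif mode == "bootstrap":
        idx = rng.integers(0, x.size, size=(B, x.size))
        samples = x[idx]
        if statistic == "accuracy":
            stats = samples.mean(axis=1)
        elif statistic == "rmse":
            stats = np.sqrt((samples ** 2).mean(axis=1))
        else:
            raise ValueError("statistic must be 'accuracy' or 'rmse'")
    else:
        raise ValueError("mode must be 'probability' or 'bootstrap'")
    alpha = (1 - level) / 2
    lo, hi = np.quantile(stats, [alpha, 1 - alpha])
    return float(lo), float(hi)


def evaluate_classification(
    y_true, y_pred, p_correct: Optional[Sequence[float]] = None,
    level: float = 0.95, B: int = 2000, seed: int = 0,
) -> MetricsResult:
    """Confusion metrics + kappa, with a Monte-Carlo CI on accuracy."""
    res = confusion_metrics(y_true, y_pred)
    res.kappa = cohens_kappa(y_true, y_pred)
    if p_correct is not None:
        res.ci_95["accuracy"] = mc_confidence_interval(
            p_correct, level=level, B=B, seed=seed, mode="probability")
    else:
        correct = (np.asarray(y_true) == np.asarray(y_pred)).astype(float)
        res.ci_95["accuracy"] = mc_confidence_interval(
            correct, level=level, B=B, seed=seed, mode="bootstrap")
    return res


def evaluate_regression(
    pred_mm, truth_mm, level: float = 0.95, B: int = 2000, seed: int = 0,
) -> MetricsResult:
    """Localisation RMSE (mm) with a bootstrap CI over per-item errors."""
    p = np.atleast_2d(np.asarray(pred_mm, dtype=float))
    t = np.atleast_2d(np.asarray(truth_mm, dtype=float))
    res = MetricsResult(n=len(p), rmse_mm=rmse_mm(p, t))
    errors = np.sqrt(((p - t) ** 2).sum(axis=1))
    res.ci_95["rmse_mm"] = mc_confidence_interval(
        errors, level=level, B=B, seed=seed, mode="bootstrap", statistic="rmse")
    return res
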