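"""Landmark-derived positioning quality features.

Given the nipple position and the two pectoralis edge landmarks (where the
anterior muscle margin crosses the cranial image edge and the chest-wall
edge of an MLO view), this module computes the standard geometric quality
measures used in PGMI-style mammography positioning review:

* the pectoralis angle — inclination of the muscle line relative to the
  vertical posterior image edge;
* the posterior nipple line (PNL) on MLO — perpendicular distance from the
  nipple to the muscle line;
* the PNL on CC — horizontal distance from the nipple to the posterior
  image edge;
* the CC/MLO PNL comparison (on a well-positioned exam the two lengths
  should agree within roughly 1 cm);
* the pectoralis–nipple level — whether the muscle extends caudally to or
  beyond the level of the nipple.

All functions operate in millimetre coordinates ``(x, y)`` with y
increasing downward (image convention); they are pure and unit-correct
(scaling all inputs by ``s`` scales distances by ``s`` and leaves angles
unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

#: Default CC-vs-MLO PNL symmetry tolerance (mm).  A ~1 cm rule of thumb
#: widely used in positioning review; inclusive at the boundary.
DEFAULT_PNL_TOL_MM = 10.0


class DegenerateGeometryError(ValueError):
    """Raised when landmarks do not define a line (coincident points)."""


def _as_xy(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,) or not np.all(np.isfinite(a)):
        raise ValueError(f"expected a finite (x, y) point, got {p!r}")
    return a


@dataclass
class LandmarkSet:
    """Landmarks of one two-view examination, in mm.

    ``posterior_edge_x_mm`` is the x-coordinate of the chest-wall edge in
    the CC frame (0.0 in the canonical orientation).
    """

    nipple_cc_mm: Tuple[float, float]
    nipple_mlo_mm: Tuple[float, float]
    pect_cranial_mm: Tuple[float, float]
    pect_caudal_mm: Tuple[float, float]
    posterior_edge_x_mm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("nipple_cc_mm", "nipple_mlo_mm", "pect_cranial_mm", "pect_caudal_mm"):
            _as_xy(getattr(self, name))
        if not _as_xy(self.pect_cranial_mm)[1] < _as_xy(self.pect_caudal_mm)[1]:
            raise ValueError("cranial landmark must have smaller y than caudal")


@dataclass
class QualityFeatures:
    """Geometric quality measures derived from one LandmarkSet."""

    pect_angle_deg: float
    pnl_mlo_mm: float
    pnl_cc_mm: float
    pnl_diff_mm: float
    pnl_symmetric: bool
    pect_level_offset_mm: float
    pect_reaches_pnl: bool

    def to_dict(self) -> dict:
        return {
            "pect_angle_deg": float(self.pect_angle_deg),
            "pnl_mlo_mm": float(self.pnl_mlo_mm),
            "pnl_cc_mm": float(self.pnl_cc_mm),
            "pnl_diff_mm": float(self.pnl_diff_mm),
            "pnl_symmetric": bool(self.pnl_symmetric),
            "pect_level_offset_mm": float(self.pect_level_offset_mm),
            "pect_reaches_pnl": bool(self.pect_reaches_pnl),
        }


def pectoralis_angle(cranial, caudal) -> float:
    """Angle (degrees) between the pectoralis line and the vertical edge.

    0 deg means the muscle margin is parallel to the posterior (chest-wall)
    image edge; the result lies in [0, 90] and is invariant to swapping
    the two landmarks.
    """
    c1, c2 = _as_xy(cranial), _as_xy(caudal)
    d = c2 - c1
    if np.hypot(*d) == 0.0:
        raise DegenerateGeometryError("pectoralis landmarks coincide")
    return float(np.degrees(np.arctan2(abs(d[0]), abs(d[1]))))


def pnl_mlo(nipple, cranial, caudal) -> float:
    """Posterior nipple line length on MLO (mm).

    Perpendicular distance from the nipple to the infinite line through
    the two pectoralis landmarks.
    """
    n, c1, c2 = _as_xy(nipple), _as_xy(cranial), _as_xy(caudal)
    d = c2 - c1
    norm = np.hypot(*d)
    if norm == 0.0:
        raise DegenerateGeometryError("pectoralis landmarks coincide")
    v = n - c1
    return float(abs(v[0] * d[1] - v[1] * d[0]) / norm)


def pnl_cc(nipple, posterior_edge_x: float) -> float:
    """Posterior nipple line length on CC (mm): |nipple.x - edge x|."""
    n = _as_xy(nipple)
    return float(abs(n[0] - float(posterior_edge_x)))


def pnl_compare(pnl_cc_mm: float, pnl_mlo_mm: float,
                tol: float = DEFAULT_PNL_TOL_MM) -> Tuple[float, bool]:
    """CC-vs-MLO PNL difference and the (inclusive) symmetry verdict."""
    if pnl_cc_mm < 0 or pnl_mlo_mm < 0:
        raise ValueError("PNL lengths must be non-negative")
    diff = float(abs(pnl_mlo_mm - pnl_cc_mm))
    return diff, bool(diff <= tol)


def pect_nipple_level(nipple, cranial, caudal) -> Tuple[float, bool]:
    """Signed pectoralis–nipple level offset (mm) and the reach verdict.

    The nipple is projected perpendicularly onto the pectoralis line; the
    offset is the signed distance along the line from that foot point to
    the caudal landmark (positive when the muscle extends caudally beyond
    the nipple level).  ``reaches`` is True when offset >= 0.
    """
    n, c1, c2 = _as_xy(nipple), _as_xy(cranial), _as_xy(caudal)
    d = c2 - c1
    norm = np.hypot(*d)
    if norm == 0.0:
        raise DegenerateGeometryError("pectoralis landmarks coincide")
    u = d / norm
    t_foot = float(np.dot(n - c1, u))
    offset = float(norm - t_foot)
    return offset, bool(offset >= 0.0)


def compute_features(lm: LandmarkSet, tol: float = DEFAULT_PNL_TOL_MM) -> QualityFeatures:
    """Compute the full quality-feature bundle from one landmark set."""
    angle = pectoralis_angle(lm.pect_cranial_mm, lm.pect_caudal_mm)
    p_mlo = pnl_mlo(lm.nipple_mlo_mm, lm.pect_cranial_mm, lm.pect_caudal_mm)
    p_cc = pnl_cc(lm.nipple_cc_mm, lm.posterior_edge_x_mm)
    diff, sym = pnl_compare(p_cc, p_mlo, tol)
    offset, reaches = pect_nipple_level(lm.nipple_mlo_mm, lm.pect_cranial_mm, lm.pect_caudal_mm)
    return QualityFeatures(
        pect_angle_deg=angle,
        pnl_mlo_mm=p_mlo,
        pnl_cc_mm=p_cc,
        pnl_diff_mm=diff,
        pnl_symmetric=sym,
        pect_level_offset_mm=offset,
        pect_reaches_pnl=reaches,
    )
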