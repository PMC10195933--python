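"""Synthetic mammography phantoms with exact ground truth.

The generator renders breast-silhouette projections (CC and MLO views)
from smooth parametric shapes — a half-ellipse breast against a dark
background, a linear-edged pectoralis wedge (MLO) or a thin posterior
crescent (CC), Gaussian-blob parenchymal texture, a nipple rendered either
as a contour bump (in profile) or an interior blob (not in profile), a
curved inframammary fold, plus additive Gaussian pixel noise.

Each positioning feature a quality reviewer would assess is a controllable
parameter, and the returned :class:`~mammoqa.records.GroundTruth` is exact
by construction: landmark coordinates are the analytic shape parameters,
not measurements of the rendered raster.  This makes the phantoms usable
both as supervised training data (images + labels/landmarks) and as an
oracle for end-to-end pipeline tests.

The defect conventions (documented thresholds; the binary labels are
unambiguous):

* ``parenchyma_complete=False`` truncates all tissue at 25% of the breast
  depth from the chest wall (anything >= 15% truncation counts as
  incomplete);
* ``nipple_centered=False`` (CC) displaces the nipple 20 mm along the
  breast contour from the vertical midline (the centred tolerance used by
  the pipeline is 15 mm);
* ``nipple_in_profile=False`` moves the nipple from the skin contour to an
  interior position at 72% of the breast depth.

The canonical render is a right-laterality image with the chest wall at
the left edge; left laterality is realised by horizontal mirroring, which
exercises the preprocessing flip path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .records import ImageRecord, GroundTruth

# Rendering intensities (arbitrary display units in [0, 1])
_BG = 0.03
_BREAST = 0.40
_PECT_EXTRA = 0.25
_NIPPLE = 0.85
_IMF = 0.70
_BLOB_AMP = 0.10

#: truncation fraction used to render an incomplete-parenchyma phantom
TRUNCATION_FRACTION = 0.25
#: displacement (mm) of an off-centre nipple on CC
OFFCENTER_SHIFT_MM = 20.0
#: interior depth fraction of a not-in-profile nipple
INTERIOR_NIPPLE_DEPTH = 0.72


@dataclass
class PhantomParams:
    """Parameters of one phantom projection image."""

    view: str = "MLO"
    laterality: str = "R"
    image_size_px: Tuple[int, int] = (512, 512)
    pixel_spacing_mm: Tuple[float, float] = (0.2, 0.2)
    breast_scale: float = 0.75
    pect_present: bool = True
    pect_angle_deg: float = 20.0
    imf_present: bool = True
    nipple_in_profile: bool = True
    nipple_centered: bool = True
    parenchyma_complete: bool = True
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.view not in ("CC", "MLO"):
            raise ValueError("view must be CC or MLO")
        if self.laterality not in ("L", "R"):
            raise ValueError("laterality must be L or R")
        r, c = self.image_size_px
        if r < 64 or c < 64:
            raise ValueError("image_size_px must both be >= 64")
        sr, sc = self.pixel_spacing_mm
        if sr <= 0 or sc <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if not 0.3 < self.breast_scale < 0.95:
            raise ValueError("breast_scale must lie in (0.3, 0.95)")
        if not 0.0 <= self.pect_angle_deg <= 60.0:
            raise ValueError("pect_angle_deg must lie in [0, 60]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _ellipse_alpha(X, Y, ax, ay, cy, edge=0.04):
    """Soft-edged half-ellipse membership in [0, 1] (chest wall at x=0)."""
    e = (X / ax) ** 2 + ((Y - cy) / ay) ** 2
    return np.clip((1.0 - e) / edge, 0.0, 1.0)


def _gaussian_bump(canvas, X, Y, cx, cy, sigma, amp):
    canvas += amp * np.exp(-(((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sigma**2)))


def generate_phantom(params: PhantomParams) -> Tuple[ImageRecord, GroundTruth]:
    """Render one phantom projection and its exact ground truth.

    Deterministic given ``params.seed``.  MLO-only parameters
    (``pect_angle_deg``, ``imf_present``) are ignored for CC, and the
    CC-only ``nipple_centered`` is ignored for MLO.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rows, cols = params.image_size_px
    sr, sc = params.pixel_spacing_mm
    H, W = rows * sr, cols * sc
    Y, X = np.meshgrid(np.arange(rows) * sr, np.arange(cols) * sc, indexing="ij")

    # breast geometry (canonical: right breast, chest wall at x = 0)
    ay = params.breast_scale * H / 2.0
    ax = ay * rng.uniform(0.62, 0.80)
    ax = min(ax, 0.80 * W)
    cy = H / 2.0 + rng.uniform(-0.03, 0.03) * H

    img = np.full((rows, cols), _BG)
    breast = _ellipse_alpha(X, Y, ax, ay, cy)

    # posterior truncation simulating clipped parenchyma
    trunc_x = TRUNCATION_FRACTION * ax if not params.parenchyma_complete else 0.0
    if trunc_x > 0:
        breast = breast * (X >= trunc_x)

    img += (_BREAST - _BG) * breast

    # parenchymal texture: Gaussian blobs inside the breast
    for _ in range(25):
        rad = rng.uniform(0.15, 0.75)
        phi = rng.uniform(-1.2, 1.2)
        bx, by = rad * ax * np.cos(phi), cy + rad * ay * np.sin(phi)
        tex = np.zeros_like(img)
        _gaussian_bump(tex, X, Y, bx, by, rng.uniform(2.0, 6.0),
                       rng.uniform(-_BLOB_AMP, _BLOB_AMP))
        img += tex * breast

    pect_cranial = pect_caudal = None
    if params.view == "MLO":
        if params.pect_present:
            pect_cranial, pect_caudal = _render_pect_mlo(
                img, X, Y, params.pect_angle_deg, ax, ay, cy, H, W, rng
            )
        if params.imf_present:
            _render_imf(img, X, Y, ax, ay, cy, breast)

    else:  # CC
        if params.pect_present:
            # thin posterior crescent at the chest wall
            crescent = np.clip(1.0 - X / 4.0, 0, 1) * (np.abs(Y - cy) < 0.45 * ay)
            img += _PECT_EXTRA * crescent
            y0, y1 = cy - 0.45 * ay, cy + 0.45 * ay
            pect_cranial, pect_caudal = (1.0, y0), (1.0, y1)

    nipple = _render_nipple(img, X, Y, params, ax, ay, cy, rng)

    img = np.clip(img, 0.0, 1.0)
    if params.noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, params.noise_sd, img.shape), 0.0, 1.0)

    # laterality: canonical render is R; mirror for L
    if params.laterality == "L":
        img = img[:, ::-1].copy()
        x_max = (cols - 1) * sc

        def mirror(p):
            return None if p is None else (x_max - p[0], p[1])

        nipple = mirror(nipple)
        pect_cranial = mirror(pect_cranial)
        pect_caudal = mirror(pect_caudal)

    rec = ImageRecord(
        pixels=img,
        pixel_spacing_mm=(sr, sc),
        view=params.view,
        laterality=params.laterality,
        source_id=f"phantom-{params.view}-{params.laterality}-{params.seed}",
    )
    gt = GroundTruth(
        parenchyma_complete=params.parenchyma_complete,
        pect_visible=params.pect_present,
        nipple_in_profile=params.nipple_in_profile,
        imf_visible=params.imf_present if params.view == "MLO" else None,
        nipple_centered=params.nipple_centered if params.view == "CC" else None,
        nipple_xy_mm=nipple,
        pect_cranial_xy_mm=pect_cranial,
        pect_caudal_xy_mm=pect_caudal,
    )
    return rec, gt


def _render_pect_mlo(img, X, Y, angle_deg, ax, ay, cy, H, W, rng):
    """Brighter wedge from the top-posterior corner; returns exact landmarks.

    The anterior margin is the line through the cranial landmark (top
    edge) and the caudal landmark (chest-wall edge, or the lowest in-image
    point for near-vertical margins).  The wedge fills everything
    posterior (left) of that line.
    """
    tan = np.tan(np.radians(angle_deg))
    # the additive term keeps the caudal end near or below mid-breast so
    # a well-positioned exam clears the nipple-level criterion with margin
    x_top = rng.uniform(0.30, 0.45) * ax + 0.58 * ay * tan
    x_top = min(x_top, 0.85 * W)
    cranial = (x_top, 0.0)
    y_limit = 0.93 * H
    if tan > 1e-9 and x_top / tan <= y_limit:
        caudal = (0.0, x_top / tan)
    else:
        caudal = (x_top - y_limit * tan, y_limit)
    margin_x = x_top - Y * tan
    wedge = np.clip((margin_x - X) / 2.0, 0.0, 1.0)  # 2-mm soft edge
    img += _PECT_EXTRA * wedge
    return cranial, caudal


def _render_imf(img, X, Y, ax, ay, cy, breast):
    """Curved bright fold along the inferior posterior breast contour."""
    e = np.sqrt((X / ax) ** 2 + ((Y - cy) / ay) ** 2)
    band = np.exp(-(((e - 1.0) / 0.035) ** 2))
    inferior = (Y > cy + 0.55 * ay) & (X < 0.65 * ax)
    img += _IMF * band * inferior


def _render_nipple(img, X, Y, params, ax, ay, cy, rng):
    """Draw the nipple and return its exact (x, y) in mm."""
    if params.view == "CC" and not params.nipple_centered:
        off = OFFCENTER_SHIFT_MM * rng.choice([-1.0, 1.0])
    else:
        off = rng.uniform(-4.0, 4.0)  # mild jitter along the contour
    off = np.clip(off, -0.85 * ay, 0.85 * ay)
    y_n = cy + off
    x_contour = ax * np.sqrt(max(0.0, 1.0 - (off / ay) ** 2))
    if params.nipple_in_profile:
        pos = (x_contour + 1.5, y_n)  # bump protruding from the skin line
    else:
        pos = (INTERIOR_NIPPLE_DEPTH * x_contour, y_n)
    _gaussian_bump(img, X, Y, pos[0], pos[1], 2.2, _NIPPLE - _BREAST)
    return (float(pos[0]), float(pos[1]))


# ----------------------------------------------------------------------
# datasets and exams
# ----------------------------------------------------------------------

DEFAULT_CLASS_MIX: Dict[str, float] = {
    "pect_present": 0.5,
    "imf_present": 0.7,
    "nipple_in_profile": 0.7,
    "nipple_centered": 0.7,
    "parenchyma_complete": 0.7,
}


def generate_dataset(
    n: int,
    class_mix: Optional[Dict[str, float]] = None,
    seed: int = 0,
    view: str = "MLO",
    image_size_px: Tuple[int, int] = (512, 512),
    pixel_spacing_mm: Tuple[float, float] = (0.2, 0.2),
) -> Tuple[List[Tuple[ImageRecord, GroundTruth]], pd.DataFrame]:
    """Generate ``n`` phantoms with controlled per-feature positive counts.

    For each feature in ``class_mix`` exactly ``round(fraction * n)``
    phantoms are positive (assignment randomised by ``seed``).  ``view``
    may be ``"CC"``, ``"MLO"`` or ``"both"`` (alternating).  Returns the
    image/ground-truth pairs and a manifest with one row per image (all
    coordinates in mm, original frame).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(DEFAULT_CLASS_MIX)
    mix.update(class_mix or {})
    for k, v in mix.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"class fraction {k}={v} outside [0, 1]")
    rng = np.random.default_rng(seed)

    flags = {}
    for feat, frac in mix.items():
        n_pos = int(round(frac * n))
        v = np.zeros(n, dtype=bool)
        v[rng.permutation(n)[:n_pos]] = True
        flags[feat] = v

    out, rows = [], []
    for i in range(n):
        v = view if view != "both" else ("CC" if i % 2 == 0 else "MLO")
        params = PhantomParams(
            view=v,
            laterality="L" if rng.random() < 0.5 else "R",
            image_size_px=image_size_px,
            pixel_spacing_mm=pixel_spacing_mm,
            breast_scale=float(rng.uniform(0.55, 0.9)),
            pect_present=bool(flags["pect_present"][i]),
            pect_angle_deg=float(rng.uniform(5.0, 45.0)),
            imf_present=bool(flags["imf_present"][i]),
            nipple_in_profile=bool(flags["nipple_in_profile"][i]),
            nipple_centered=bool(flags["nipple_centered"][i]),
            parenchyma_complete=bool(flags["parenchyma_complete"][i]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, gt = generate_phantom(params)
        rec = ImageRecord(
            pixels=rec.pixels,
            pixel_spacing_mm=rec.pixel_spacing_mm,
            view=rec.view,
            laterality=rec.laterality,
            source_id=f"phantom-{i:05d}",
        )
        out.append((rec, gt))
        row = {
            "source_id": rec.source_id,
            "view": rec.view,
            "laterality": rec.laterality,
            "rows_px": image_size_px[0],
            "cols_px": image_size_px[1],
            "row_spacing_mm": pixel_spacing_mm[0],
            "col_spacing_mm": pixel_spacing_mm[1],
        }
        row.update(gt.to_dict())
        d = row.pop("nipple_xy_mm")
        row["nipple_x_mm"], row["nipple_y_mm"] = d
        for key in ("pect_cranial_xy_mm", "pect_caudal_xy_mm"):
            p = row.pop(key)
            base = key.replace("_xy_mm", "")
            row[f"{base}_x_mm"] = None if p is None else p[0]
            row[f"{base}_y_mm"] = None if p is None else p[1]
        rows.append(row)
    manifest = pd.DataFrame(rows)
    return out, manifest


@dataclass
class ExamParams:
    """Parameters of a paired CC+MLO examination of one breast.

    Both views share the breast depth so that, for an ideally positioned
    exam, the CC and MLO posterior nipple lines agree.
    """

    laterality: str = "R"
    image_size_px: Tuple[int, int] = (512, 512)
    pixel_spacing_mm: Tuple[float, float] = (0.2, 0.2)
    breast_scale: float = 0.75
    pect_angle_deg: float = 18.0
    imf_present: bool = True
    nipple_in_profile: bool = True
    nipple_centered: bool = True
    parenchyma_complete: bool = True
    pect_present_cc: bool = False
    noise_sd: float = 0.02
    seed: int = 0


def generate_exam(params: ExamParams):
    """Generate one (CC, MLO) phantom pair with shared anatomy.

    Returns ``(cc_record, cc_truth, mlo_record, mlo_truth)``.
    """
    base = dict(
        laterality=params.laterality,
        image_size_px=params.image_size_px,
        pixel_spacing_mm=params.pixel_spacing_mm,
        breast_scale=params.breast_scale,
        nipple_in_profile=params.nipple_in_profile,
        parenchyma_complete=params.parenchyma_complete,
        noise_sd=params.noise_sd,
    )
    cc_rec, cc_gt = generate_phantom(PhantomParams(
        view="CC", pect_present=params.pect_present_cc,
        nipple_centered=params.nipple_centered, seed=params.seed * 2 + 1, **base,
    ))
    mlo_rec, mlo_gt = generate_phantom(PhantomParams(
        view="MLO", pect_present=True, pect_angle_deg=params.pect_angle_deg,
        imf_present=params.imf_present, seed=params.seed * 2 + 1, **base,
    ))
    return cc_rec, cc_gt, mlo_rec, mlo_gt
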