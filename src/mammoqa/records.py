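"""Core data containers shared across the package.

Conventions used everywhere:

* pixel coordinates are 0-based, pixel-center, ``(row, col)`` with row
  increasing downward;
* physical coordinates are millimetres, ``(x, y)`` with
  ``x = col * spacing_col`` and ``y = row * spacing_row``;
* image intensities are floats in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

VIEWS = ("CC", "MLO")
LATERALITIES = ("L", "R")


@dataclass
class ImageRecord:
    """One grayscale breast-projection image with physical metadata.

    Attributes
    ----------
    pixels : ndarray
        2-D float array, intensities in [0, 1].
    pixel_spacing_mm : (float, float)
        Physical size of one pixel, (row spacing, col spacing).
    view : str
        ``"CC"`` (craniocaudal) or ``"MLO"`` (mediolateral oblique).
    laterality : str
        ``"L"`` or ``"R"``.
    source_id : str
        Provenance identifier (file name, phantom seed, ...).
    """

    pixels: np.ndarray
    pixel_spacing_mm: Tuple[float, float]
    view: str
    laterality: str
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixel intensities must lie in [0, 1]")
        sr, sc = self.pixel_spacing_mm
        if sr <= 0 or sc <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, **kw) -> "ImageRecord":
        return replace(self, pixels=pixels, **kw)


@dataclass
class GroundTruth:
    """Per-image radiologist-label surrogate: feature presences and landmarks.

    Landmark coordinates are (x, y) in mm in the image's own (original,
    pre-preprocessing) frame.  Pectoralis landmarks are present iff the
    muscle is visible; ``None`` encodes n/a for fields that do not apply
    to the view (e.g. ``imf_visible`` on CC).
    """

    parenchyma_complete: bool
    pect_visible: bool
    nipple_in_profile: bool
    nipple_xy_mm: Tuple[float, float]
    imf_visible: Optional[bool] = None
    nipple_centered: Optional[bool] = None
    pect_cranial_xy_mm: Optional[Tuple[float, float]] = None
    pect_caudal_xy_mm: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.pect_visible != (self.pect_cranial_xy_mm is not None):
            raise ValueError("pect landmarks must be present iff pect_visible")
        if self.pect_visible != (self.pect_caudal_xy_mm is not None):
            raise ValueError("pect landmarks must be present iff pect_visible")
        if self.pect_visible:
            if not self.pect_cranial_xy_mm[1] < self.pect_caudal_xy_mm[1]:
                raise ValueError(
                    "cranial landmark must lie above (smaller y) the caudal one"
                )

    def to_dict(self) -> dict:
        def pt(p):
            return None if p is None else [float(p[0]), float(p[1])]

        return {
            "parenchyma_complete": self.parenchyma_complete,
            "pect_visible": self.pect_visible,
            "nipple_in_profile": self.nipple_in_profile,
            "imf_visible": self.imf_visible,
            "nipple_centered": self.nipple_centered,
            "nipple_xy_mm": pt(self.nipple_xy_mm),
            "pect_cranial_xy_mm": pt(self.pect_cranial_xy_mm),
            "pect_caudal_xy_mm": pt(self.pect_caudal_xy_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        def pt(p):
            return None if p is None else (float(p[0]), float(p[1]))

        return cls(
            parenchyma_complete=bool(d["parenchyma_complete"]),
            pect_visible=bool(d["pect_visible"]),
            nipple_in_profile=bool(d["nipple_in_profile"]),
            imf_visible=d.get("imf_visible"),
            nipple_centered=d.get("nipple_centered"),
            nipple_xy_mm=pt(d["nipple_xy_mm"]),
            pect_cranial_xy_mm=pt(d.get("pect_cranial_xy_mm")),
            pect_caudal_xy_mm=pt(d.get("pect_caudal_xy_mm")),
        )
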