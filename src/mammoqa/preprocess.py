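"""Image standardisation chain with invertible coordinate bookkeeping.

Every geometric step (horizontal flip, square padding, resize) is recorded
in a :class:`TransformLog` so that coordinates can be mapped exactly
between the original image frame and the model input frame — this is what
allows landmark-regression errors to be reported in millimetres of the
original image.

Pixel coordinates are 0-based ``(x, y) = (col, row)``.  The flip map uses
the pixel-center convention ``x' = W - 1 - x``; resize maps coordinates by
pure scaling ``x' = x * sx`` (the two conventions differ by less than half
a pixel at the scales used here, and the scaling form makes the
forward/inverse composition exact).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from skimage.transform import resize as _sk_resize

from .records import ImageRecord


class MetadataError(ValueError):
    """Missing or inconsistent image metadata."""


class CoordinateError(ValueError):
    """A coordinate lies outside the image it refers to."""


@dataclass
class TransformLog:
    """Ordered record of preprocessing steps applied to one image.

    Steps are dicts: ``{"op": "hflip", "width_px": W}``,
    ``{"op": "pad", "right_px": r, "bottom_px": b}``,
    ``{"op": "window", "lo": lo, "hi": hi}`` (identity on coordinates),
    ``{"op": "resize", "sy": sy, "sx": sx}``.
    """

    source_spacing_mm: Tuple[float, float]
    steps: List[dict] = field(default_factory=list)

    def append(self, step: dict) -> None:
        self.steps.append(step)

    # -- coordinate maps (pixel units, (x, y) = (col, row)) ---------------
    @staticmethod
    def _apply_step(pt: np.ndarray, step: dict, inverse: bool) -> np.ndarray:
        op = step["op"]
        x, y = pt
        if op == "hflip":
            x = step["width_px"] - 1.0 - x
        elif op in ("pad", "window"):
            pass
        elif op == "resize":
            sy, sx = step["sy"], step["sx"]
            if inverse:
                x, y = x / sx, y / sy
            else:
                x, y = x * sx, y * sy
        else:
            raise ValueError(f"unknown transform step {op!r}")
        return np.array([x, y], dtype=float)

    def forward_px(self, pt) -> np.ndarray:
        """Map an original-frame pixel point to the final (model) frame."""
        p = np.asarray(pt, dtype=float)
        for step in self.steps:
            p = self._apply_step(p, step, inverse=False)
        return p

    def inverse_px(self, pt) -> np.ndarray:
        """Map a model-frame pixel point back to the original frame."""
        p = np.asarray(pt, dtype=float)
        for step in reversed(self.steps):
            p = self._apply_step(p, step, inverse=True)
        return p

    # -- mm helpers (original frame) --------------------------------------
    def px_to_mm(self, pt_px) -> np.ndarray:
        sr, sc = self.source_spacing_mm
        x, y = np.asarray(pt_px, dtype=float)
        return np.array([x * sc, y * sr])

    def mm_to_px(self, pt_mm) -> np.ndarray:
        sr, sc = self.source_spacing_mm
        x, y = np.asarray(pt_mm, dtype=float)
        return np.array([x / sc, y / sr])

    def model_px_to_original_mm(self, pt_px) -> np.ndarray:
        return self.px_to_mm(self.inverse_px(pt_px))

    def original_mm_to_model_px(self, pt_mm) -> np.ndarray:
        return self.forward_px(self.mm_to_px(pt_mm))

    # -- serialisation -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {"source_spacing_mm": list(self.source_spacing_mm), "steps": self.steps}
        )

    @classmethod
    def from_json(cls, s: str) -> "TransformLog":
        d = json.loads(s)
        return cls(source_spacing_mm=tuple(d["source_spacing_mm"]), steps=d["steps"])


def map_coords(pt, log: TransformLog, direction: str = "forward") -> np.ndarray:
    """Map a pixel point through a TransformLog (``forward`` or ``inverse``)."""
    if direction == "forward":
        return log.forward_px(pt)
    if direction == "inverse":
        return log.inverse_px(pt)
    raise ValueError("direction must be 'forward' or 'inverse'")


def _new_log(img: ImageRecord) -> TransformLog:
    return TransformLog(source_spacing_mm=tuple(img.pixel_spacing_mm))


def _breast_on_right(pixels: np.ndarray) -> bool:
    """Heuristic orientation test: is the bulk of tissue in the right half?"""
    w = pixels.shape[1]
    third = max(1, w // 3)
    return pixels[:, -third:].mean() > pixels[:, :third].mean()


def standardize_orientation(
    img: ImageRecord, log: Optional[TransformLog] = None
) -> Tuple[ImageRecord, TransformLog]:
    """Flip horizontally if needed so the chest wall sits at the left edge.

    The decision is content-based (which half holds the tissue), which
    makes the operation idempotent; laterality metadata must be present
    (it is what tells a reader the mirroring is meaningful).
    """
    if img.laterality not in ("L", "R"):
        raise MetadataError("laterality must be known to canonicalise orientation")
    log = log if log is not None else _new_log(img)
    if _breast_on_right(img.pixels):
        out = img.with_pixels(img.pixels[:, ::-1].copy())
        log.append({"op": "hflip", "width_px": img.pixels.shape[1]})
        return out, log
    return img, log


def pad_to_square(
    img: ImageRecord, log: Optional[TransformLog] = None
) -> Tuple[ImageRecord, TransformLog]:
    """Pad with black to a square; portrait images gain a right stripe.

    Landscape (wider-than-tall) images are padded at the bottom instead so
    that content always stays anchored at the top-left corner.
    """
    log = log if log is not None else _new_log(img)
    rows, cols = img.pixels.shape
    side = max(rows, cols)
    if rows == cols:
        return img, log
    out = np.zeros((side, side), dtype=img.pixels.dtype)
    out[:rows, :cols] = img.pixels
    log.append({"op": "pad", "right_px": side - cols, "bottom_px": side - rows})
    return img.with_pixels(out), log


def apply_window(img: ImageRecord, lo: float, hi: float) -> ImageRecord:
    """Linear intensity window: lo -> 0, hi -> 1, clipped to [0, 1]."""
    if not lo < hi:
        raise ValueError("window requires lo < hi")
    out = np.clip((img.pixels - lo) / (hi - lo), 0.0, 1.0)
    return img.with_pixels(out)


def auto_window(img: ImageRecord, p_lo: float = 1.0, p_hi: float = 99.0) -> Tuple[float, float]:
    """Percentile window limits — a reproducible stand-in for vendor LUTs."""
    lo, hi = np.percentile(img.pixels, [p_lo, p_hi])
    if hi <= lo:  # flat image
        lo, hi = float(img.pixels.min()), float(img.pixels.min()) + 1.0
    return float(lo), float(hi)


def resize_to_model(
    img: ImageRecord, side_px: int = 224, log: Optional[TransformLog] = None
) -> Tuple[ImageRecord, TransformLog]:
    """Bilinear resize of a square image to ``side_px`` x ``side_px``."""
    rows, cols = img.pixels.shape
    if rows != cols:
        raise ValueError("resize_to_model requires a square input; pad first")
    log = log if log is not None else _new_log(img)
    if side_px != rows:
        out = _sk_resize(
            img.pixels, (side_px, side_px), order=1, mode="edge",
            anti_aliasing=side_px < rows, preserve_range=True,
        )
        out = np.clip(out, 0.0, 1.0)
        log.append({"op": "resize", "sy": side_px / rows, "sx": side_px / cols})
        return img.with_pixels(out), log
    return img, log


def crop_nipple_region(
    img: ImageRecord, nipple_xy_mm, fraction: float = 0.10
) -> ImageRecord:
    """Fixed-size crop centred on the nipple (10% of each dimension).

    The crop window is clipped at the image border and zero-padded so the
    output size is always exactly ``round(fraction * shape)``.
    """
    rows, cols = img.pixels.shape
    sr, sc = img.pixel_spacing_mm
    x_mm, y_mm = np.asarray(nipple_xy_mm, dtype=float)
    c, r = x_mm / sc, y_mm / sr
    if not (0 <= c <= cols - 1 and 0 <= r <= rows - 1):
        raise CoordinateError("nipple position lies outside the image")
    ch = max(1, int(round(fraction * rows)))
    cw = max(1, int(round(fraction * cols)))
    out = np.zeros((ch, cw), dtype=img.pixels.dtype)
    r0 = int(round(r)) - ch // 2
    c0 = int(round(c)) - cw // 2
    rs, re = max(0, r0), min(rows, r0 + ch)
    cs, ce = max(0, c0), min(cols, c0 + cw)
    out[rs - r0: re - r0, cs - c0: ce - c0] = img.pixels[rs:re, cs:ce]
    return img.with_pixels(out)


def preprocess_for_model(
    img: ImageRecord,
    side_px: int = 224,
    window: Optional[Tuple[float, float]] = None,
) -> Tuple[ImageRecord, TransformLog]:
    """Full standardisation chain: orient, window, pad square, resize.

    ``window=None`` selects per-image percentile limits (p1, p99).
    Returns the model-ready image and the complete TransformLog.
    """
    out, log = standardize_orientation(img)
    lo, hi = auto_window(out) if window is None else window
    out = apply_window(out, lo, hi)
    log.append({"op": "window", "lo": float(lo), "hi": float(hi)})
    out, log = pad_to_square(out, log)
    out, log = resize_to_model(out, side_px, log)
    return out, log
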