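"""Reading and writing images and manifests.

Images travel as lossless 16-bit PNG with a JSON sidecar carrying the
physical metadata (pixel spacing, view, laterality), or as DICOM files
(``PixelSpacing``/``ImagerPixelSpacing``, ``ViewPosition``,
``ImageLaterality`` honoured, MONOCHROME1 inverted to MONOCHROME2
polarity).  Intensities are normalised to [0, 1] on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .records import ImageRecord

try:  # pydicom is a light dependency but keep import failure local
    import pydicom
except ImportError:  # pragma: no cover
    pydicom = None


def write_png(rec: ImageRecord, path) -> None:
    """Write a 16-bit grayscale PNG plus a ``.json`` metadata sidecar."""
    path = Path(path)
    arr = np.clip(rec.pixels, 0.0, 1.0)
    Image.fromarray((arr * 65535.0 + 0.5).astype(np.uint16)).save(path)
    meta = {
        "pixel_spacing_mm": list(rec.pixel_spacing_mm),
        "view": rec.view,
        "laterality": rec.laterality,
        "source_id": rec.source_id,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_png(path) -> ImageRecord:
    """Read a PNG written by :func:`write_png` (sidecar required)."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    arr = np.asarray(Image.open(path), dtype=np.float64)
    peak = 65535.0 if arr.max() > 255 else max(arr.max(), 1.0)
    return ImageRecord(
        pixels=arr / peak,
        pixel_spacing_mm=tuple(meta["pixel_spacing_mm"]),
        view=meta["view"],
        laterality=meta["laterality"],
        source_id=meta.get("source_id", path.stem),
    )


def read_dicom(path) -> ImageRecord:
    """Read one grayscale projection from a DICOM file."""
    if pydicom is None:  # pragma: no cover
        raise ImportError("pydicom is required to read DICOM files")
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        arr = 1.0 - arr
    spacing = getattr(ds, "PixelSpacing", None) or getattr(
        ds, "ImagerPixelSpacing", None)
    if spacing is None:
        raise ValueError("DICOM file carries no pixel spacing")
    view = str(getattr(ds, "ViewPosition", "")).upper()
    if view not in ("CC", "MLO"):
        raise ValueError(f"unsupported or missing ViewPosition: {view!r}")
    lat = str(getattr(ds, "ImageLaterality", "")
              or getattr(ds, "Laterality", "")).upper()
    if lat not in ("L", "R"):
        raise ValueError(f"unsupported or missing laterality: {lat!r}")
    return ImageRecord(
        pixels=arr,
        pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
        view=view,
        laterality=lat,
        source_id=Path(path).stem,
    )


def read_image(path) -> ImageRecord:
    """Dispatch on extension: ``.png`` (sidecar) or ``.dcm``."""
    p = Path(path)
    if p.suffix.lower() == ".png":
        return read_png(p)
    if p.suffix.lower() in (".dcm", ".dicom"):
        return read_dicom(p)
    raise ValueError(f"unsupported image format: {p.suffix}")
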