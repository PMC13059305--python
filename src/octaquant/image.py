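"""En-face OCTA image container and grayscale PNG/TIFF I/O.

An en-face slab is a 2D projection of the OCTA decorrelation signal between
two depth boundaries.  Pixels are stored as floats in [0, 1]; the physical
pixel pitch (``scale_um_per_px``) ties pixel counts to areas and lengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as PILImage

SLABS = ("superficial", "deep", "choriocapillaris")

_U16_MAX = 65535


@dataclass
class EnFaceImage:
    """A 2D en-face angiogram with physical scale.

    Parameters
    ----------
    pixels : ndarray of float
        2D array, values in [0, 1].
    scale_um_per_px : float
        Physical pixel pitch in micrometers per pixel (isotropic).
    slab : str
        One of ``superficial``, ``deep``, ``choriocapillaris``.
    """

    pixels: np.ndarray
    scale_um_per_px: float
    slab: str = "superficial"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"en-face image must be 2D, got ndim={self.pixels.ndim}")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be positive")
        if self.slab not in SLABS:
            raise ValueError(f"slab must be one of {SLABS}, got {self.slab!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def scale_mm_per_px(self) -> float:
        return self.scale_um_per_px / 1000.0

    @property
    def px_area_um2(self) -> float:
        return self.scale_um_per_px**2

    @property
    def field_mm(self) -> float:
        return self.pixels.shape[1] * self.scale_mm_per_px


def read_slab(path: str | Path, scale_um_per_px: float, slab: str = "superficial") -> EnFaceImage:
    """Read an 8/16-bit grayscale PNG or TIFF and normalize it to [0, 1].

    Raises ``ValueError`` for multi-channel input.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(PILImage.open(path))
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected single-channel grayscale, got {arr.ndim}D array "
            f"with {arr.shape[-1] if arr.ndim == 3 else '?'} channels"
        )
    if arr.dtype == np.uint8:
        pixels = arr.astype(float) / 255.0
    elif arr.dtype in (np.uint16, np.int32):  # PIL reads 16-bit PNG as I;16 -> int32
        pixels = arr.astype(float) / _U16_MAX
    else:
        pixels = arr.astype(float)
        if pixels.max() > 1.0:
            pixels /= pixels.max()
    return EnFaceImage(pixels=pixels, scale_um_per_px=scale_um_per_px, slab=slab)


def write_slab(img: EnFaceImage, path: str | Path, sidecar: dict | None = None) -> Path:
    """Write a slab as 16-bit grayscale TIFF or PNG plus a JSON sidecar.

    The sidecar records the pixel scale and slab label (plus any extra
    provenance entries) next to the image as ``<stem>.json``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    quantized = np.clip(np.round(img.pixels * _U16_MAX), 0, _U16_MAX).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, quantized)
    else:
        PILImage.fromarray(quantized).save(path)  # uint16 -> 16-bit grayscale PNG
    meta = {"scale_um_per_px": img.scale_um_per_px, "slab": img.slab}
    meta.update(img.meta)
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit PNG (0/255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    PILImage.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG (any nonzero pixel is True)."""
    return np.asarray(PILImage.open(path)) > 0
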