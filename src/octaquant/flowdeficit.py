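"""Choriocapillaris flow-deficit quantification.

Flow deficits (flow voids) are regions of the choriocapillaris slab with no
detectable decorrelation signal.  The slab is binarized at a global
mean - k*SD threshold (k = 1 by default) computed over analyzable pixels,
and deficits are summarized overall and after discarding components at or
below a set of area thresholds (strict ``>``, 200/400/600/800 um^2 by
default).  Pixels under the exclusion mask (by default the superficial
large-vessel shadow) contribute to neither numerator nor denominator.
Connected components use 8-connectivity throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label

from .image import EnFaceImage

DEFAULT_SIZE_THRESHOLDS_UM2 = (200.0, 400.0, 600.0, 800.0)


@dataclass
class FlowDeficitMetrics:
    fv_density_pct: float
    fv_density_pct_at: dict[float, float] = field(default_factory=dict)
    fv_mean_size_um2: float | None = None
    fv_count: int = 0
    excluded_area_mm2: float = 0.0

    def as_row(self) -> dict:
        """Flatten to the standard clinical-report column names."""
        row = {
            "CC_FV_density": self.fv_density_pct,
            "CC_FV_size": self.fv_mean_size_um2,
            "CC_FV_number": self.fv_count,
        }
        for thr, dens in self.fv_density_pct_at.items():
            row[f"CC_FV_density_{int(thr)}"] = dens
        return row


def binarize_cc(
    img: EnFaceImage, exclusion_mask: np.ndarray | None = None, k: float = 1.0
) -> np.ndarray:
    """Flow-deficit mask: analyzable pixels strictly below mean - k*SD.

    The threshold statistics are computed over non-excluded pixels only.
    A uniform image (SD = 0) yields an empty mask because no pixel is
    strictly below its own mean.
    """
    if img.slab != "choriocapillaris":
        raise ValueError(f"binarize_cc expects a choriocapillaris slab, got {img.slab!r}")
    pixels = img.pixels
    if exclusion_mask is None:
        analyzable = np.ones(pixels.shape, bool)
    else:
        analyzable = ~np.asarray(exclusion_mask, bool)
        if analyzable.shape != pixels.shape:
            raise ValueError("exclusion mask shape differs from image")
    if not analyzable.any():
        raise ValueError("exclusion mask covers the whole field")
    vals = pixels[analyzable]
    t = float(vals.mean()) - k * float(vals.std())
    return analyzable & (pixels < t)


def flow_deficit_metrics(
    deficit_mask: np.ndarray,
    scale_um_per_px: float,
    exclusion_mask: np.ndarray | None = None,
    thresholds_um2: tuple[float, ...] = DEFAULT_SIZE_THRESHOLDS_UM2,
) -> FlowDeficitMetrics:
    """Summarize a binary flow-deficit mask.

    Density is the percentage of analyzable (non-excluded) pixels flagged as
    deficit; per-threshold densities count only 8-connected components whose
    area is strictly greater than the threshold.  Mean size and count cover
    all components regardless of threshold.
    """
    deficit = np.asarray(deficit_mask, bool)
    if exclusion_mask is None:
        analyzable = np.ones(deficit.shape, bool)
    else:
        excl = np.asarray(exclusion_mask, bool)
        if excl.shape != deficit.shape:
            raise ValueError("exclusion mask shape differs from deficit mask")
        analyzable = ~excl
        deficit = deficit & analyzable
    n_analyzable = int(analyzable.sum())
    if n_analyzable == 0:
        raise ValueError("no analyzable pixels")
    px_area = scale_um_per_px**2
    scale_mm = scale_um_per_px / 1000.0

    lab, n_comp = label(deficit, connectivity=2, return_num=True)
    sizes_px = np.bincount(lab.ravel())[1:] if n_comp else np.array([], dtype=int)
    sizes_um2 = sizes_px * px_area

    density = 100.0 * float(deficit.sum()) / n_analyzable
    at = {}
    for thr in thresholds_um2:
        kept = sizes_px[sizes_um2 > thr].sum()
        at[float(thr)] = 100.0 * float(kept) / n_analyzable
    return FlowDeficitMetrics(
        fv_density_pct=density,
        fv_density_pct_at=at,
        fv_mean_size_um2=float(sizes_um2.mean()) if n_comp else None,
        fv_count=int(n_comp),
        excluded_area_mm2=float((~analyzable).sum()) * scale_mm**2,
    )


def cc_metrics(
    img: EnFaceImage,
    exclusion_mask: np.ndarray | None = None,
    k: float = 1.0,
    thresholds_um2: tuple[float, ...] = DEFAULT_SIZE_THRESHOLDS_UM2,
) -> FlowDeficitMetrics:
    """Binarize a CC slab and summarize its flow deficits in one call."""
    deficit = binarize_cc(img, exclusion_mask, k=k)
    return flow_deficit_metrics(deficit, img.scale_um_per_px, exclusion_mask, thresholds_um2)
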