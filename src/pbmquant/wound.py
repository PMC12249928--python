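"""Wound-area quantification and closure kinetics.

Closure is always the planimetric fraction of the original gap that has
filled in:

    closed % = 100 · (A₀ − A_t) / A₀

where A₀ is the wound area at the first timepoint. The same arithmetic
serves in vitro scratch assays (hours) and in vivo wound photographs
(days); only the time unit and the source of the areas differ. Areas may
come from automatic texture segmentation (a wound is the large low-texture
region of a phase-contrast frame) or from externally supplied masks — the
mask path bypasses segmentation entirely and reproduces the closure
formula exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .errors import ParameterError, ValidationError
from .io import ImageStack, logger


def closure_percentage(original_area: float, current_area: float) -> float:
    """Closed-area percentage 100·(A₀ − A_t)/A₀.

    Negative values mean the wound enlarged; they are returned as-is and
    logged, never clipped.
    """
    if original_area <= 0:
        raise ParameterError("original_area must be > 0")
    if current_area < 0:
        raise ParameterError("current_area must be >= 0")
    pct = 100.0 * (original_area - current_area) / original_area
    if pct < 0:
        logger.warning(
            "wound enlargement: area %.6g exceeds original %.6g",
            current_area, original_area,
        )
    return pct


@dataclass(frozen=True)
class SegmentationParams:
    """Texture-based wound segmentation knobs.

    The wound is detected as the largest connected low-texture region:
    a local-variance filter (window ``variance_window`` px) maps cell
    texture to high values and the cell-free gap to low values; Otsu's
    threshold on the smoothed log-variance map separates the two classes
    (log compresses the long lawn tail that would otherwise drag the
    threshold into the lawn mode); morphological closing (radius
    ``closing_radius`` px) and hole filling regularise the mask.
    """

    variance_window: int = 9
    closing_radius: int = 5
    #: minimum separation (in log-variance units) between the wound and
    #: lawn texture classes; below it the frame is declared wound-free
    min_contrast: float = 1.5

    def __post_init__(self) -> None:
        if self.variance_window < 3 or self.variance_window % 2 == 0:
            raise ParameterError("variance_window must be an odd integer >= 3")
        if self.closing_radius < 0:
            raise ParameterError("closing_radius must be >= 0")


def _local_variance(img: np.ndarray, window: int) -> np.ndarray:
    m = ndimage.uniform_filter(img, window)
    m2 = ndimage.uniform_filter(img * img, window)
    return np.clip(m2 - m * m, 0, None)


def segment_wound(
    frame: np.ndarray,
    params: SegmentationParams | None = None,
    pixel_size: float | None = None,
) -> tuple[np.ndarray, float]:
    """Segment the wound in one grayscale frame.

    Returns ``(mask, area)``; area is px² or, when ``pixel_size`` (μm/px)
    is given, μm². When no candidate region survives, returns an empty
    mask with area 0 and logs a warning (the caller decides if that is
    fatal).
    """
    params = params or SegmentationParams()
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValidationError("segment_wound expects a single 2-D frame")
    var = _local_variance(img, params.variance_window)
    logvar = ndimage.uniform_filter(np.log1p(var), params.variance_window)
    if np.ptp(logvar) == 0:
        logger.warning("flat texture map; returning empty mask")
        return np.zeros(img.shape, dtype=bool), 0.0
    thr = threshold_otsu(logvar)
    low_texture = logvar < thr
    # a gap-free lawn: Otsu force-splits the texture into two similar
    # classes; require real contrast before accepting a wound
    if logvar[~low_texture].mean() - logvar[low_texture].mean() < params.min_contrast:
        logger.warning("low texture contrast; declaring frame wound-free")
        return np.zeros(img.shape, dtype=bool), 0.0
    if params.closing_radius:
        footprint = disk(params.closing_radius)
        low_texture = ndimage.binary_closing(low_texture, structure=footprint)
    labels, n = ndimage.label(low_texture)
    if n == 0:
        logger.warning("no wound candidate region found; returning empty mask")
        return np.zeros_like(low_texture, dtype=bool), 0.0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    # the variance window smears lawn texture ~half a window into the gap,
    # eroding the low-variance core; dilate by the matching radius
    r = (params.variance_window - 1) // 2
    if r:
        mask = ndimage.binary_dilation(mask, structure=disk(r))
        mask = ndimage.binary_fill_holes(mask)
    area = float(mask.sum())
    if pixel_size is not None:
        area *= pixel_size ** 2
    return mask, area


@dataclass(frozen=True)
class ClosureSeries:
    """Wound areas and closed percentages over time.

    ``time_unit`` is 'h' for scratch assays, 'd' for in vivo series;
    ``area_unit`` is 'px^2' or 'um^2'. ``enlarged`` flags timepoints where
    the wound grew beyond its original area (negative closure).
    """

    t: np.ndarray
    wound_area: np.ndarray
    closed_pct: np.ndarray
    time_unit: str = "h"
    area_unit: str = "px^2"

    @property
    def enlarged(self) -> np.ndarray:
        return self.closed_pct < 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                f"t_{self.time_unit}": self.t,
                f"wound_area_{self.area_unit}": self.wound_area,
                "closed_pct": self.closed_pct,
                "enlarged": self.enlarged,
            }
        )


def closure_from_areas(
    times, areas, time_unit: str = "h", area_unit: str = "px^2"
) -> ClosureSeries:
    """Closure series from already-measured areas (exact arithmetic path)."""
    t = np.asarray(times, dtype=float)
    a = np.asarray(areas, dtype=float)
    if t.shape != a.shape or t.ndim != 1:
        raise ValidationError("times and areas must be 1-D and equal length")
    if len(t) < 2:
        raise ValidationError("need at least 2 timepoints")
    if a[0] <= 0:
        raise ValidationError("first-frame wound area is 0; cannot normalise")
    pct = np.array([closure_percentage(a[0], ai) for ai in a])
    return ClosureSeries(t, a, pct, time_unit=time_unit, area_unit=area_unit)


def closure_kinetics(
    frames: ImageStack | np.ndarray,
    times,
    params: SegmentationParams | None = None,
    masks: np.ndarray | None = None,
    pixel_size: float | None = None,
    time_unit: str = "h",
) -> ClosureSeries:
    """Per-frame wound area → closure percentage against frame 0.

    ``masks`` (frames × h × w bool), when given, bypass segmentation —
    e.g. planted ground truth or manually traced in vivo wound outlines.
    """
    if isinstance(frames, ImageStack):
        if pixel_size is None:
            pixel_size = frames.pixel_size
        data = frames.data[:, :, :, 0]
    else:
        data = np.asarray(frames, dtype=float)
        if data.ndim == 2:
            data = data[None]
    t = np.asarray(times, dtype=float)
    if len(t) != len(data):
        raise ValidationError("times length must match frame count")
    if len(t) < 2:
        raise ValidationError("need at least 2 timepoints")
    scale = (pixel_size ** 2) if pixel_size is not None else 1.0
    if masks is not None:
        masks = np.asarray(masks, dtype=bool)
        if masks.shape != data.shape:
            raise ValidationError("masks shape must match frames")
        areas = masks.sum(axis=(1, 2)).astype(float) * scale
    else:
        areas = np.array(
            [segment_wound(f, params, pixel_size)[1] for f in data]
        )
    return ClosureSeries(
        t,
        areas,
        np.array([closure_percentage(areas[0], a) for a in areas])
        if areas[0] > 0
        else _raise_zero_original(),
        time_unit=time_unit,
        area_unit="um^2" if pixel_size is not None else "px^2",
    )


def _raise_zero_original():
    raise ValidationError("first-frame wound area is 0; cannot normalise")
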