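"""Fluorescence morphometrics: positive-nucleus fractions and
focal-adhesion / cytoskeleton features.

Two readouts are covered:

* proliferation fractions — count nuclei in a DNA-stain channel, score
  each as positive/negative for a marker (EdU, Ki-67) from its mean
  marker intensity, report ``100·n_positive/n_total``;
* adhesion/cytoskeleton morphometrics — within a cell mask, measure
  F-actin/p-FAK/paxillin intensities and segment adhesion puncta
  (top-hat + threshold) to get their count, area and elongation
  (major/minor axis ratio of the second-moment ellipse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import white_tophat, disk
from skimage.segmentation import watershed

from .errors import ParameterError, ValidationError
from .io import logger


def _otsu_split(values: np.ndarray) -> float:
    """Exact Otsu threshold for a small 1-D sample.

    Evaluates the between-class variance at every split of the sorted
    sample and returns the midpoint of the optimal gap. Unlike the
    histogram version, a wide empty gap between classes yields a threshold
    centred in the gap rather than at its edge, so borderline members of
    the low class cannot leak across under noise.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    csum = np.cumsum(v)
    total = csum[-1]
    k = np.arange(1, n)
    mu0 = csum[:-1] / k
    mu1 = (total - csum[:-1]) / (n - k)
    sb = k * (n - k) * (mu0 - mu1) ** 2
    best = int(np.argmax(sb))
    return 0.5 * (v[best] + v[best + 1])


# ---------------------------------------------------------------------------
# nuclei counting


@dataclass(frozen=True)
class NucleiParams:
    """Nucleus segmentation and positivity-calling parameters.

    Nuclei are thresholded (Otsu unless ``abs_threshold``), oversized
    components (area > ``split_factor`` × median) are split by
    distance-transform watershed, and components outside
    [min_area, max_area] px are discarded. A nucleus is positive when its
    mean marker intensity exceeds Otsu's threshold over the per-nucleus
    means, or ``marker_abs_threshold`` when given — per-nucleus means are
    robust to single hot pixels, so positivity is not decided per pixel.
    """

    min_area: int = 20
    max_area: int = 10_000
    abs_threshold: float | None = None
    marker_abs_threshold: float | None = None
    split_factor: float = 1.6
    watershed_min_distance: int = 5


@dataclass(frozen=True)
class NucleiQuant:
    """Total/positive nucleus counts; ``flagged`` marks a degenerate field."""

    n_total: int
    n_positive: int
    positive_pct: float
    flagged: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def _label_nuclei(nuclei: np.ndarray, params: NucleiParams) -> np.ndarray:
    img = np.asarray(nuclei, dtype=float)
    if img.max() <= 0 or np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=int)
    thr = params.abs_threshold if params.abs_threshold is not None else threshold_otsu(img)
    fg = img > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        return labels
    areas = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    median_area = float(np.median(areas))
    out = np.zeros_like(labels)
    nxt = 0
    for lab, area in zip(range(1, n + 1), areas):
        comp = labels == lab
        if area > params.split_factor * median_area and median_area > 0:
            # split touching nuclei on the distance transform
            dist = ndimage.distance_transform_edt(comp)
            peaks = peak_local_max(
                dist, min_distance=params.watershed_min_distance, labels=comp
            )
            if len(peaks) > 1:
                markers = np.zeros_like(labels)
                for i, (py, px) in enumerate(peaks, start=1):
                    markers[py, px] = i
                ws = watershed(-dist, markers, mask=comp)
                for sub in range(1, ws.max() + 1):
                    piece = ws == sub
                    if params.min_area <= piece.sum() <= params.max_area:
                        nxt += 1
                        out[piece] = nxt
                continue
        if params.min_area <= area <= params.max_area:
            nxt += 1
            out[comp] = nxt
    return out


def count_positive_nuclei(
    nuclei_channel: np.ndarray,
    marker_channel: np.ndarray,
    params: NucleiParams | None = None,
) -> NucleiQuant:
    """Count nuclei and the marker-positive subset; report the percentage.

    An empty or flat nuclei channel yields ``NucleiQuant(0, 0, 0, flagged)``
    rather than an exception: a blank field is a data problem to surface,
    not a crash.
    """
    params = params or NucleiParams()
    nuc = np.asarray(nuclei_channel, dtype=float)
    mrk = np.asarray(marker_channel, dtype=float)
    if nuc.shape != mrk.shape or nuc.ndim != 2:
        raise ValidationError("channels must be two aligned 2-D frames")
    labels = _label_nuclei(nuc, params)
    n_total = int(labels.max())
    if n_total == 0:
        logger.warning("no nuclei detected; returning flagged zero result")
        return NucleiQuant(0, 0, 0.0, flagged=True)
    means = ndimage.mean(mrk, labels, index=np.arange(1, n_total + 1))
    means = np.asarray(means, dtype=float)
    if params.marker_abs_threshold is not None:
        thr = params.marker_abs_threshold
    elif np.ptp(means) == 0 or n_total < 2:
        # all nuclei identical in marker intensity: nothing is "positive"
        return NucleiQuant(n_total, 0, 0.0)
    else:
        thr = _otsu_split(means)
    n_pos = int((means > thr).sum())
    return NucleiQuant(n_total, n_pos, 100.0 * n_pos / n_total)


# ---------------------------------------------------------------------------
# adhesion / cytoskeleton features


@dataclass(frozen=True)
class AdhesionParams:
    """Adhesion puncta detection parameters.

    Puncta are connected components of the white-top-hat-filtered marker
    channel above threshold (Otsu on in-mask top-hat values unless
    ``abs_threshold``), gated to area ∈ [min_area_um2, max_area_um2] μm²
    when pixel size is known, else [min_area_px, max_area_px] px.
    """

    tophat_radius: int = 8
    abs_threshold: float | None = None
    min_area_um2: float = 0.1
    max_area_um2: float = 10.0
    min_area_px: int = 3
    max_area_px: int = 1000

    def area_gate_px(self, pixel_size: float | None) -> tuple[float, float]:
        if pixel_size is not None:
            return (self.min_area_um2 / pixel_size ** 2,
                    self.max_area_um2 / pixel_size ** 2)
        return float(self.min_area_px), float(self.max_area_px)


@dataclass
class CellMorphometrics:
    """Per-cell feature vector (intensities per channel + shape + adhesions)."""

    cell_area: float
    aspect_ratio: float
    intensity_mean: dict = field(default_factory=dict)   # channel -> a.u.
    intensity_total: dict = field(default_factory=dict)
    adhesion_count: int = 0
    mean_adhesion_area: float = float("nan")
    mean_adhesion_elongation: float = float("nan")
    adhesions: pd.DataFrame | None = None  # per-punctum table

    def to_row(self) -> dict:
        row = {
            "cell_area": self.cell_area,
            "aspect_ratio": self.aspect_ratio,
            "adhesion_count": self.adhesion_count,
            "mean_adhesion_area": self.mean_adhesion_area,
            "mean_adhesion_elongation": self.mean_adhesion_elongation,
        }
        for ch, v in self.intensity_mean.items():
            row[f"{ch}_mean"] = v
        for ch, v in self.intensity_total.items():
            row[f"{ch}_total"] = v
        return row


def _ellipse_features(mask: np.ndarray) -> tuple[float, float]:
    """(area, major/minor axis ratio) from the mask's second moments."""
    props = regionprops(mask.astype(int))[0]
    minor = props.axis_minor_length
    major = props.axis_major_length
    ar = major / minor if minor > 0 else float("inf")
    return float(props.area), max(ar, 1.0)


def detect_puncta(
    channel: np.ndarray,
    mask: np.ndarray | None = None,
    params: AdhesionParams | None = None,
    pixel_size: float | None = None,
) -> pd.DataFrame:
    """Segment adhesion puncta in one marker channel.

    Returns one row per punctum: ``y, x, area, elongation, mean_intensity``
    (area in px² or μm²).
    """
    params = params or AdhesionParams()
    img = np.asarray(channel, dtype=float)
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    th = white_tophat(img, disk(params.tophat_radius))
    inside = th[mask]
    if inside.max() <= 0 or np.ptp(inside) == 0:
        return pd.DataFrame(columns=["y", "x", "area", "elongation", "mean_intensity"])
    thr = params.abs_threshold if params.abs_threshold is not None else threshold_otsu(inside)
    fg = (th > thr) & mask
    labels, n = ndimage.label(fg)
    lo, hi = params.area_gate_px(pixel_size)
    scale = pixel_size ** 2 if pixel_size is not None else 1.0
    rows = []
    for p in regionprops(labels, intensity_image=img):
        if not lo <= p.area <= hi:
            continue
        minor = p.axis_minor_length
        rows.append(
            dict(
                y=p.centroid[0],
                x=p.centroid[1],
                area=float(p.area) * scale,
                elongation=(p.axis_major_length / minor) if minor > 0 else float("inf"),
                mean_intensity=float(p.intensity_mean),
            )
        )
    return pd.DataFrame(rows, columns=["y", "x", "area", "elongation", "mean_intensity"])


def adhesion_metrics(
    cell_mask: np.ndarray,
    channels: Mapping[str, np.ndarray],
    params: AdhesionParams | None = None,
    pixel_size: float | None = None,
    adhesion_channels: Sequence[str] = ("pfak", "paxillin"),
) -> CellMorphometrics:
    """Feature vector of one cell.

    ``channels`` maps marker name (e.g. ``factin, pfak, paxillin``) to its
    aligned 2-D frame. Intensities are measured inside ``cell_mask``;
    puncta are pooled over the channels named in ``adhesion_channels``
    that are present.
    """
    params = params or AdhesionParams()
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValidationError("cell mask is empty")
    area_scale = pixel_size ** 2 if pixel_size is not None else 1.0
    cell_area, aspect = _ellipse_features(mask)
    result = CellMorphometrics(cell_area=cell_area * area_scale, aspect_ratio=aspect)
    for name, ch in channels.items():
        ch = np.asarray(ch, dtype=float)
        if ch.shape != mask.shape:
            raise ValidationError(f"channel {name!r} not aligned to mask")
        vals = ch[mask]
        result.intensity_mean[name] = float(vals.mean())
        result.intensity_total[name] = float(vals.sum())
    tables = [
        detect_puncta(channels[name], mask, params, pixel_size)
        for name in adhesion_channels
        if name in channels
    ]
    adh = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=["y", "x", "area", "elongation", "mean_intensity"])
    )
    result.adhesions = adh
    result.adhesion_count = len(adh)
    if len(adh):
        result.mean_adhesion_area = float(adh["area"].mean())
        fin = adh["elongation"].to_numpy(dtype=float)
        fin = fin[np.isfinite(fin)]
        result.mean_adhesion_elongation = float(fin.mean()) if len(fin) else float("nan")
    return result


def cohort_morphometrics(
    fields: Mapping[str, Sequence[tuple[np.ndarray, Mapping[str, np.ndarray]]]],
    params: AdhesionParams | None = None,
    pixel_size: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition morphometrics over many cells.

    ``fields`` maps condition -> sequence of (cell_mask, channels) pairs,
    one per cell. Returns ``(per_cell, by_condition)``: the tidy per-cell
    feature table and group means/SEM (SEM NaN for single-cell groups).
    Conditions where no cell could be measured are excluded with a log
    message rather than failing the whole cohort.
    """
    rows = []
    for cond, cells in fields.items():
        measured = 0
        for i, (mask, channels) in enumerate(cells):
            try:
                m = adhesion_metrics(mask, channels, params, pixel_size)
            except ValidationError as exc:
                logger.warning("condition %r cell %d skipped: %s", cond, i, exc)
                continue
            measured += 1
            rows.append({"condition": cond, "cell": i, **m.to_row()})
        if measured == 0:
            logger.warning("condition %r excluded: no measurable cells", cond)
    if not rows:
        raise ValidationError("no measurable cells in any condition")
    per_cell = pd.DataFrame(rows)
    feature_cols = [c for c in per_cell.columns if c not in ("condition", "cell")]
    out = []
    for cond, g in per_cell.groupby("condition", sort=False):
        row: dict = {"condition": cond, "n_cells": len(g)}
        for c in feature_cols:
            vals = g[c].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"{c}_mean"] = vals.mean() if len(vals) else float("nan")
            row[f"{c}_sem"] = (
                vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else float("nan")
            )
        out.append(row)
    return per_cell, pd.DataFrame(out)
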