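"""Per-cell colocalization and intensity quantification in tissue images.

The procedure mirrors a standard confocal immunofluorescence analysis: the
nuclei (DAPI) channel is segmented with Otsu's method, interior holes are
filled and objects smaller than 50 pixels removed, each remaining mask
defines one cell, a 100x100-pixel ROI box is centered on each mask centroid
(clipped at the image border), and within each ROI the Pearson correlation
coefficient between signal channels and the summed background-corrected
intensity per channel are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

from .config import PipelineConfig


@dataclass
class NucleusROI:
    """One segmented nucleus with its ROI measurements."""

    label: int
    area: int                      # mask area, pixels
    centroid_x: float
    centroid_y: float
    box: tuple[int, int, int, int]  # (row0, col0, height, width), half-open
    correlations: dict[tuple[int, int], float | None] = field(default_factory=dict)
    summed_intensities: dict[int, float] = field(default_factory=dict)


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold over a 256-bin histogram of the data range.

    Pixels strictly above the returned value are foreground.  A constant
    image has no foreground/background split and raises ``ValueError``.
    """
    image = np.asarray(image)
    if image.size < 2 or np.ptp(image) == 0:
        raise ValueError("Otsu thresholding requires >= 2 distinct intensity values")
    return float(threshold_otsu(image, nbins=nbins))


def clean_mask(mask: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Morphological cleanup of a binary nuclei mask -> labeled image.

    Interior holes are filled first, then 8-connected components with area
    strictly below ``area_min_px`` (default 50) are removed.  Labels are
    relabeled consecutively from 1.
    """
    mask = np.asarray(mask, dtype=bool)
    filled = ndimage.binary_fill_holes(mask)
    labeled = sk_label(filled, connectivity=2)
    if labeled.max() == 0:
        return labeled
    areas = np.bincount(labeled.ravel())
    keep = np.flatnonzero(areas >= config.area_min_px)
    keep = keep[keep != 0]
    relabel = np.zeros(areas.size, dtype=labeled.dtype)
    relabel[keep] = np.arange(1, keep.size + 1)
    return relabel[labeled]


def segment_nuclei(nuclei_channel: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Otsu segmentation of the nuclei channel followed by cleanup."""
    threshold = otsu_threshold(nuclei_channel)
    return clean_mask(nuclei_channel > threshold, config)


def cell_rois(labeled: np.ndarray, config: PipelineConfig) -> list[NucleusROI]:
    """One ROI box per labeled nucleus, centered on the mask centroid.

    Boxes are ``roi_box_px`` (default 100) pixels on a side, clipped to the
    image bounds, in half-open (row0, col0, height, width) form.
    """
    h, w = labeled.shape
    box = config.roi_box_px
    rois = []
    for prop in regionprops(labeled):
        cy, cx = prop.centroid
        r0 = int(round(cy - box / 2))
        c0 = int(round(cx - box / 2))
        r1, c1 = r0 + box, c0 + box
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, h), min(c1, w)
        rois.append(
            NucleusROI(
                label=int(prop.label),
                area=int(prop.area),
                centroid_x=float(cx),
                centroid_y=float(cy),
                box=(r0, c0, r1 - r0, c1 - c0),
            )
        )
    return rois


def roi_channel_correlation(roi_a: np.ndarray, roi_b: np.ndarray) -> float | None:
    """Pearson correlation over all pixels of two equal-shaped ROIs.

    Returns None (undefined) when either channel has zero variance inside
    the ROI.
    """
    a = np.asarray(roi_a, dtype=np.float64).ravel()
    b = np.asarray(roi_b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("ROIs must have identical shape")
    if a.size < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    if a.std() == 0.0 or b.std() == 0.0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def channel_background(channel: np.ndarray, nbins: int = 256) -> float:
    """Per-channel background level: the mode of the intensity histogram."""
    channel = np.asarray(channel, dtype=np.float64)
    if np.ptp(channel) == 0:
        return float(channel.flat[0])
    counts, edges = np.histogram(channel.ravel(), bins=nbins)
    peak = int(np.argmax(counts))
    return float(0.5 * (edges[peak] + edges[peak + 1]))


def roi_summed_intensity(roi: np.ndarray, background: float) -> float:
    """Summed background-corrected intensity, Sum(max(pixel - background, 0))."""
    roi = np.asarray(roi, dtype=np.float64)
    if roi.size == 0:
        raise ValueError("empty ROI")
    return float(np.clip(roi - background, 0.0, None).sum())


def analyze_tissue_image(
    image: np.ndarray,
    nuclei_channel: int,
    config: PipelineConfig,
    signal_channels: list[int] | None = None,
) -> list[NucleusROI]:
    """Full per-cell analysis of a multi-channel (C, H, W) tissue image.

    Segments nuclei, builds per-cell ROIs, and fills each ROI with the
    pairwise channel correlations (all declared signal-channel pairs) and the
    per-channel summed background-corrected intensities.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3:
        raise ValueError("image must be (channels, height, width)")
    n_channels = image.shape[0]
    if signal_channels is None:
        signal_channels = [c for c in range(n_channels) if c != nuclei_channel]
    labeled = segment_nuclei(image[nuclei_channel], config)
    rois = cell_rois(labeled, config)
    backgrounds = {c: channel_background(image[c]) for c in signal_channels}
    for roi in rois:
        r0, c0, hh, ww = roi.box
        for ca, cb in combinations(signal_channels, 2):
            roi.correlations[(ca, cb)] = roi_channel_correlation(
                image[ca, r0:r0 + hh, c0:c0 + ww],
                image[cb, r0:r0 + hh, c0:c0 + ww],
            )
        for c in signal_channels:
            roi.summed_intensities[c] = roi_summed_intensity(
                image[c, r0:r0 + hh, c0:c0 + ww], backgrounds[c]
            )
    return rois


def tissue_table(rois: list[NucleusROI]) -> pd.DataFrame:
    """Flatten per-nucleus results into a tidy table (one row per nucleus)."""
    rows = []
    for roi in rois:
        row: dict = {
            "label": roi.label,
            "area": roi.area,
            "x": roi.centroid_x,
            "y": roi.centroid_y,
            "row0": roi.box[0],
            "col0": roi.box[1],
            "height": roi.box[2],
            "width": roi.box[3],
        }
        for (ca, cb), r in sorted(roi.correlations.items()):
            row[f"r_ch{ca}_ch{cb}"] = np.nan if r is None else r
        for c, s in sorted(roi.summed_intensities.items()):
            row[f"sum_ch{c}"] = s
        rows.append(row)
    return pd.DataFrame(rows)
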