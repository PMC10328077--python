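"""Per-frame focus detection, sub-pixel localization and photometry.

Detection runs in three stages per frame:

1. ``find_candidates`` — band-pass smooth the frame (difference of
   Gaussians), threshold at a robust noise estimate, and keep local maxima,
   merging duplicates within one PSF width.
2. ``iterative_gaussian_mask`` — refine each candidate to sub-pixel accuracy
   by repeatedly multiplying the background-subtracted ROI with a Gaussian
   mask centered on the current estimate and recomputing the
   intensity-weighted centroid until the shift falls below tolerance.
3. ``measure_focus`` — local-background-corrected summed intensity inside a
   small square ROI: the background ``b`` is the mean of the ROI's one-pixel
   border ring, the intensity ``I`` sums ``roi - b`` over the inner square,
   and the SNR is the mean background-corrected intensity per inner pixel
   divided by the standard deviation of the border ring.

Foci are accepted when their SNR is strictly above the configured threshold
(default 0.4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import PipelineConfig


@dataclass
class Focus:
    """A detected spot in a single frame.

    Coordinates are 0-based with ``x`` the column and ``y`` the row; pixel
    centers sit at integer coordinates.
    """

    frame_index: int
    x: float
    y: float
    intensity: float          # background-corrected summed intensity I
    background: float         # local background b, counts/pixel
    snr: float
    roi_halfwidth: int
    converged: bool = True

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x, self.y)


def robust_noise_sigma(frame: np.ndarray) -> float:
    """Noise scale from the median absolute deviation (Gaussian-consistent)."""
    med = np.median(frame)
    return float(np.median(np.abs(frame - med)) / 0.67448975)


def find_candidates(frame: np.ndarray, config: PipelineConfig) -> list[tuple[int, int]]:
    """Integer-pixel candidate seeds, as ``(row, col)`` tuples.

    Local maxima of a difference-of-Gaussians band-passed frame exceeding
    ``candidate_threshold_sigmas`` times a robust noise estimate.  Duplicate
    maxima within one PSF width are merged keeping the brighter one (ties
    broken toward smaller ``(row, col)``).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValueError("frame is empty")
    s = config.mask_sigma_px
    bandpass = ndimage.gaussian_filter(frame, s) - ndimage.gaussian_filter(frame, 2.0 * s)
    sigma = robust_noise_sigma(bandpass)
    if sigma == 0:
        # Noiseless frame: accept any band-pass response clearly above float
        # round-off of the smoothing; a constant frame yields no candidates.
        threshold = 1e-6 * max(1.0, float(np.ptp(frame)))
    else:
        threshold = config.candidate_threshold_sigmas * sigma
    above = bandpass > np.median(bandpass) + threshold
    if not above.any():
        return []
    footprint = np.ones((3, 3), dtype=bool)
    is_max = bandpass == ndimage.maximum_filter(bandpass, footprint=footprint)
    seeds = np.argwhere(above & is_max)

    # Merge seeds within one PSF width, brighter wins.
    merge_radius = max(1.0, s)
    order = np.lexsort((seeds[:, 1], seeds[:, 0], -bandpass[seeds[:, 0], seeds[:, 1]]))
    kept: list[tuple[int, int]] = []
    for idx in order:
        r, c = int(seeds[idx, 0]), int(seeds[idx, 1])
        if all((r - kr) ** 2 + (c - kc) ** 2 > merge_radius**2 for kr, kc in kept):
            kept.append((r, c))
    kept.sort()
    return kept


def _extract_roi(
    frame: np.ndarray, row: int, col: int, halfwidth: int
) -> np.ndarray | None:
    """Square ROI centered on (row, col); None if it overruns the frame."""
    h, w = frame.shape
    r0, r1 = row - halfwidth, row + halfwidth + 1
    c0, c1 = col - halfwidth, col + halfwidth + 1
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        return None
    return frame[r0:r1, c0:c1]


def _border_ring(roi: np.ndarray) -> np.ndarray:
    """The ROI's one-pixel border ring as a flat array."""
    return np.concatenate([roi[0, :], roi[-1, :], roi[1:-1, 0], roi[1:-1, -1]])


def iterative_gaussian_mask(
    roi: np.ndarray,
    seed: tuple[float, float],
    config: PipelineConfig,
) -> tuple[tuple[float, float], bool]:
    """Sub-pixel centroid by iterative Gaussian masking.

    Starting at ``seed`` (``(x, y)`` within the ROI), the background-subtracted
    ROI is multiplied by a unit-height 2-D Gaussian mask of width
    ``mask_sigma_px`` centered on the current estimate and the
    intensity-weighted centroid of the product is taken as the next estimate.
    Iteration stops when the shift drops below ``convergence_tol_px`` (the
    ``converged`` flag is then True) or after ``max_iterations``.

    A ROI that is non-positive everywhere after background subtraction is
    degenerate: the seed is returned unchanged with ``converged=False``.
    """
    roi = np.asarray(roi, dtype=np.float64)
    h, w = roi.shape
    x, y = float(seed[0]), float(seed[1])
    if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
        raise ValueError("seed lies outside the ROI")
    background = float(np.mean(_border_ring(roi)))
    signal = roi - background
    if not np.any(signal > 0):
        return (x, y), False
    cols = np.arange(w, dtype=np.float64)
    rows = np.arange(h, dtype=np.float64)
    inv_two_s2 = 1.0 / (2.0 * config.mask_sigma_px**2)
    for _ in range(config.max_iterations):
        mx = np.exp(-((cols - x) ** 2) * inv_two_s2)
        my = np.exp(-((rows - y) ** 2) * inv_two_s2)
        masked = signal * np.outer(my, mx)
        total = masked.sum()
        if total <= 0:
            return (x, y), False
        new_x = float((masked.sum(axis=0) * cols).sum() / total)
        new_y = float((masked.sum(axis=1) * rows).sum() / total)
        shift = np.hypot(new_x - x, new_y - y)
        x, y = new_x, new_y
        if shift < config.convergence_tol_px:
            return (x, y), True
    return (x, y), False


def measure_focus(
    frame: np.ndarray,
    centroid: tuple[float, float],
    frame_index: int,
    config: PipelineConfig,
    converged: bool = True,
) -> Focus | None:
    """Background-corrected photometry of one focus.

    Returns None for centroids too close to the frame edge for full ROI
    support.  A zero-variance border ring yields the documented large SNR
    sentinel rather than a division error.
    """
    frame = np.asarray(frame, dtype=np.float64)
    col, row = int(round(centroid[0])), int(round(centroid[1]))
    roi = _extract_roi(frame, row, col, config.roi_halfwidth)
    if roi is None:
        return None
    ring = _border_ring(roi)
    b = float(ring.mean())
    inner = roi[1:-1, 1:-1]
    intensity = float((inner - b).sum())
    ring_sd = float(ring.std())
    if ring_sd == 0.0:
        snr = config.snr_sentinel if intensity > 0 else 0.0
    else:
        snr = (intensity / inner.size) / ring_sd
    if snr < 0:
        snr = 0.0
    return Focus(
        frame_index=frame_index,
        x=float(centroid[0]),
        y=float(centroid[1]),
        intensity=intensity,
        background=b,
        snr=snr,
        roi_halfwidth=config.roi_halfwidth,
        converged=converged,
    )


def accept_focus(focus: Focus, config: PipelineConfig) -> bool:
    """Strict SNR acceptance: True iff ``snr > snr_min`` (default 0.4)."""
    return focus.snr > config.snr_min


def detect_frame(
    frame: np.ndarray, frame_index: int, config: PipelineConfig
) -> list[Focus]:
    """Full single-frame detection: candidates, refinement, photometry, filter."""
    foci: list[Focus] = []
    for row, col in find_candidates(frame, config):
        roi = _extract_roi(frame, row, col, config.roi_halfwidth)
        if roi is None:
            continue
        h = config.roi_halfwidth
        (lx, ly), converged = iterative_gaussian_mask(roi, (h, h), config)
        centroid = (col - h + lx, row - h + ly)
        focus = measure_focus(frame, centroid, frame_index, config, converged)
        if focus is not None and accept_focus(focus, config):
            foci.append(focus)
    return foci


def detect_stack(frames: np.ndarray, config: PipelineConfig) -> list[list[Focus]]:
    """Run :func:`detect_frame` over every frame of a stack."""
    return [detect_frame(frames[t], t, config) for t in range(frames.shape[0])]
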