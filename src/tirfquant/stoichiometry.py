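"""Photobleaching analysis: trace filtering, step detection, stoichiometry.

The number of labeled molecules in a focus is estimated as

    S = I0 / I_single

where ``I0`` is the photobleach-corrected initial intensity of the focus's
track — the intercept of an ordinary least-squares line through the first 4
intensity points, which for short extrapolations is equivalent to a full
exponential fit — and ``I_single`` is the characteristic intensity of a
single fluorophore obtained from photobleaching analysis (the mode of the
distribution of final bleach-step sizes).

Chung-Kennedy filter
--------------------
The edge-preserving non-linear filter used to visualize step-wise traces.
For every sample ``t`` and window size ``w`` two predictors are formed: the
mean of the ``w`` preceding samples (forward) and of the ``w`` following
samples (backward), truncated at the trace ends (an empty window predicts
the sample itself).  Each predictor is weighted by its recent squared
prediction error summed over ``w`` samples, raised to ``-p`` (the weight
exponent), with a small additive regularizer ``eps = 1e-12`` guarding exact
zeros; weights are normalized to sum to one over all predictors.  Because a
predictor whose window straddles a step accrues a large error, its weight
collapses and the filter preserves edges while averaging plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .config import PipelineConfig
from .tracking import Track

_CK_EPS = 1e-12


@dataclass
class StepEvent:
    """A downward photobleaching step: one (or more) fluorophores lost."""

    frame: int          # first frame of the lower plateau
    size: float         # intensity drop, > 0


@dataclass
class StoichiometryEstimate:
    """Photobleach-corrected stoichiometry of one track."""

    track_id: int
    start_frame: int
    initial_intensity: float        # I0, OLS intercept at the track's first frame
    characteristic_intensity: float  # I_single
    stoichiometry: float            # S = I0 / I_single
    n_steps: int = 0


def chung_kennedy_filter(
    values: np.ndarray,
    window_sizes: tuple[int, ...] = (2, 4, 8),
    weight_exponent: float = 2.0,
) -> np.ndarray:
    """Edge-preserving Chung-Kennedy filter of an intensity trace.

    See the module docstring for the exact formula.  A constant trace passes
    through unchanged; an empty trace raises ``ValueError``.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty trace")
    n = x.size
    if n < max(window_sizes):
        raise ValueError(
            f"trace length {n} shorter than the largest window {max(window_sizes)}"
        )
    num = np.zeros(n)
    den = np.zeros(n)
    for w in window_sizes:
        fwd = np.empty(n)
        bwd = np.empty(n)
        for t in range(n):
            past = x[max(0, t - w):t]
            fwd[t] = past.mean() if past.size else x[t]
            future = x[t + 1:t + 1 + w]
            bwd[t] = future.mean() if future.size else x[t]
        err_f = (x - fwd) ** 2
        err_b = (x - bwd) ** 2
        for t in range(n):
            ef = err_f[max(0, t - w + 1):t + 1].sum()
            eb = err_b[t:t + w].sum()
            wf = (ef + _CK_EPS) ** (-weight_exponent)
            wb = (eb + _CK_EPS) ** (-weight_exponent)
            num[t] += wf * fwd[t] + wb * bwd[t]
            den[t] += wf + wb
    return num / den


def _t_statistic(left: np.ndarray, right: np.ndarray) -> float:
    """Pooled-variance two-sample t statistic; infinite when variance is 0."""
    n1, n2 = left.size, right.size
    if n1 < 2 or n2 < 2:
        return 0.0
    m1, m2 = left.mean(), right.mean()
    ss = ((left - m1) ** 2).sum() + ((right - m2) ** 2).sum()
    dof = n1 + n2 - 2
    sp2 = ss / dof
    if sp2 == 0.0:
        return np.inf if m1 != m2 else 0.0
    return float(abs(m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))


def _split_segments(x: np.ndarray, start: int, stop: int, sensitivity: float,
                    boundaries: list[int]) -> None:
    """Recursive largest-t-statistic change-point splitting of x[start:stop]."""
    n = stop - start
    if n < 4:
        return
    best_t, best_s = 0.0, -1
    for s in range(start + 2, stop - 1):
        t_stat = _t_statistic(x[start:s], x[s:stop])
        if t_stat > best_t:
            best_t, best_s = t_stat, s
    if best_s >= 0 and best_t > sensitivity:
        boundaries.append(best_s)
        _split_segments(x, start, best_s, sensitivity, boundaries)
        _split_segments(x, best_s, stop, sensitivity, boundaries)


def estimate_trace_noise(values: np.ndarray) -> float:
    """Robust noise sigma from median absolute successive differences."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(x))) / (0.67448975 * np.sqrt(2.0)))


def detect_steps(
    filtered: np.ndarray,
    sensitivity: float = 5.0,
    noise_floor: float | None = None,
) -> list[StepEvent]:
    """Detect downward photobleaching steps in a (filtered) trace.

    Change points are found by recursive splitting at the largest two-sample
    t statistic exceeding ``sensitivity``; adjacent segments whose mean
    difference falls below the noise floor (default: twice the robust noise
    sigma of the trace) are merged back.  Only downward steps are returned,
    ordered in time; ``frame`` is the first frame of the lower plateau.
    """
    x = np.asarray(filtered, dtype=np.float64)
    if x.size == 0:
        return []
    boundaries: list[int] = []
    _split_segments(x, 0, x.size, sensitivity, boundaries)
    boundaries.sort()
    if noise_floor is None:
        noise_floor = 2.0 * estimate_trace_noise(x)

    # Merge segments whose means are indistinguishable from noise.
    edges = [0] + boundaries + [x.size]
    merged = [0]
    for i in range(1, len(edges) - 1):
        left = x[merged[-1]:edges[i]]
        right = x[edges[i]:edges[i + 1]]
        if abs(left.mean() - right.mean()) >= max(noise_floor, 0.0):
            merged.append(edges[i])
    segs = merged + [x.size]

    steps: list[StepEvent] = []
    for i in range(1, len(segs) - 1):
        before = x[segs[i - 1]:segs[i]].mean()
        after = x[segs[i]:segs[i + 1]].mean()
        drop = before - after
        if drop > 0:
            steps.append(StepEvent(frame=int(segs[i]), size=float(drop)))
    return steps


def collect_single_dye_intensities(
    traces: list[np.ndarray],
    sensitivity: float = 5.0,
    window_sizes: tuple[int, ...] = (2, 4, 8),
    weight_exponent: float = 2.0,
) -> np.ndarray:
    """Candidate single-fluorophore intensities from photobleaching analysis.

    A track ends when its focus bleaches below detectability, so the final
    observed plateau of a step-wise trace is the period in which (almost
    always) a single fluorophore survives.  For every trace long enough to
    filter, steps are detected on the Chung-Kennedy-filtered trace and the
    mean of the final plateau (after the last step; the whole trace when no
    step was found) is taken as a single-dye intensity candidate.  The
    occasional multi-dye contaminant (simultaneous final bleaching, or an
    unbleached multi-dye trace) is tolerated because the characteristic
    intensity is the *mode* of this sample, not its mean.
    """
    candidates = []
    for trace in traces:
        x = np.asarray(trace, dtype=np.float64)
        if x.size < max(window_sizes):
            continue
        steps = detect_steps(
            chung_kennedy_filter(x, window_sizes, weight_exponent), sensitivity
        )
        start = steps[-1].frame if steps else 0
        plateau = x[start:]
        if plateau.size >= 2 and plateau.mean() > 0:
            candidates.append(float(plateau.mean()))
    return np.asarray(candidates, dtype=np.float64)


def characteristic_intensity(samples: np.ndarray, n_grid: int = 2048) -> float:
    """Characteristic single-fluorophore intensity I_single.

    The mode of a Gaussian kernel-density estimate over the candidate
    single-dye intensities — robust against a minority of double-step
    contaminants, unlike the mean.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError(
            "no single-dye intensity candidates; calibrate with simulate_trace "
            "or provide traces containing photobleaching steps"
        )
    if x.size == 1 or np.ptp(x) == 0.0:
        return float(x[0])
    kde = gaussian_kde(x)
    lo, hi = x.min(), x.max()
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    return float(grid[np.argmax(kde(grid))])


def photobleach_corrected_initial_intensity(
    trace: np.ndarray, n_points: int = 4
) -> float:
    """OLS intercept of the first ``n_points`` trace values at the first frame.

    Ordinary least squares of intensity against frame index 0..n_points-1;
    the fitted value at index 0 is the photobleach-corrected initial
    intensity.  For short extrapolations this linear correction is
    equivalent to a full exponential fit.
    """
    y = np.asarray(trace, dtype=np.float64)[:n_points]
    if y.size < n_points:
        raise ValueError(f"trace has fewer than {n_points} points")
    t = np.arange(n_points, dtype=np.float64)
    slope, intercept = np.polyfit(t, y, 1)
    return float(intercept)


def estimate_stoichiometry(
    track: Track,
    i_single: float,
    config: PipelineConfig,
    n_steps: int = 0,
) -> StoichiometryEstimate | None:
    """Stoichiometry of one track, or None when the track is ineligible.

    Eligibility: the track must start strictly within the first
    ``max_start_frame_for_stoichiometry`` movie frames (0-based, default
    frames 0-9) — excluding molecules that land after field bleaching began —
    and be at least ``regression_points`` frames long.
    """
    if i_single <= 0:
        raise ValueError("I_single must be > 0")
    if track.start_frame >= config.max_start_frame_for_stoichiometry:
        return None
    if track.length < config.regression_points:
        return None
    i0 = photobleach_corrected_initial_intensity(track.trace, config.regression_points)
    return StoichiometryEstimate(
        track_id=track.track_id,
        start_frame=track.start_frame,
        initial_intensity=i0,
        characteristic_intensity=float(i_single),
        stoichiometry=i0 / i_single,
        n_steps=n_steps,
    )


def estimate_stoichiometries(
    tracks: list[Track],
    i_single: float,
    config: PipelineConfig,
) -> list[StoichiometryEstimate]:
    """Apply :func:`estimate_stoichiometry` to every eligible track."""
    out = []
    for track in tracks:
        est = estimate_stoichiometry(track, i_single, config)
        if est is not None:
            out.append(est)
    return out
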