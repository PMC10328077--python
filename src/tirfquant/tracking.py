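"""Linking accepted foci across frames into tracks.

Frame-to-frame association solves an optimal bipartite assignment between the
foci of consecutive frames: only pairs closer than ``link_radius_px`` are
candidates, and among feasible assignments the total squared displacement is
minimized (scipy's Hungarian solver).  Unmatched foci start new tracks.  By
default no gap frames are allowed — a missed detection terminates a track —
because surface-immobilized complexes move little and gaps would corrupt the
photobleaching step traces.

Tracks are kept only when strictly longer than ``min_track_frames`` frames
(default 3), the pipeline's minimum-duration filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import PipelineConfig
from .detection import Focus


@dataclass
class Track:
    """A time-ordered chain of foci belonging to one molecule/complex."""

    track_id: int
    foci: list[Focus] = field(default_factory=list)

    @property
    def start_frame(self) -> int:
        return self.foci[0].frame_index

    @property
    def length(self) -> int:
        return len(self.foci)

    @property
    def trace(self) -> np.ndarray:
        """Background-corrected summed intensity per frame of the track."""
        return np.array([f.intensity for f in self.foci], dtype=np.float64)

    def positions(self) -> np.ndarray:
        return np.array([[f.x, f.y] for f in self.foci], dtype=np.float64)


def _assign_frame_pair(
    prev: list[Focus], curr: list[Focus], link_radius: float
) -> list[tuple[int, int]]:
    """Minimum-total-squared-displacement matching within the link radius."""
    if not prev or not curr:
        return []
    pp = np.array([[f.x, f.y] for f in prev])
    cc = np.array([[f.x, f.y] for f in curr])
    d2 = ((pp[:, None, :] - cc[None, :, :]) ** 2).sum(axis=2)
    feasible = d2 <= link_radius**2
    # Infeasible pairs get a huge-but-finite cost so the Hungarian solver can
    # still run; matches using such a pair are discarded afterwards.
    big = d2.max() + link_radius**2 + 1.0
    cost = np.where(feasible, d2, 1e6 * big + d2)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if feasible[r, c]]


def link_foci(per_frame_foci: list[list[Focus]], config: PipelineConfig) -> list[Track]:
    """Link per-frame accepted foci into tracks.

    ``per_frame_foci[t]`` holds the accepted foci of frame ``t``.  Every focus
    ends up in exactly one track; track ids are assigned in order of creation
    (first frame, then detection order).
    """
    tracks: list[Track] = []
    active: dict[int, Track] = {}       # index into current frame -> track
    for t, foci in enumerate(per_frame_foci):
        prev_foci = per_frame_foci[t - 1] if t > 0 else []
        matches = _assign_frame_pair(prev_foci, foci, config.link_radius_px)
        matched_curr = {}
        for pi, ci in matches:
            if pi in active:
                matched_curr[ci] = active[pi]
        new_active: dict[int, Track] = {}
        for ci, focus in enumerate(foci):
            if ci in matched_curr:
                track = matched_curr[ci]
            else:
                track = Track(track_id=len(tracks))
                tracks.append(track)
            track.foci.append(focus)
            new_active[ci] = track
        active = new_active
    return tracks


def filter_tracks(tracks: list[Track], config: PipelineConfig) -> list[Track]:
    """Keep tracks strictly longer than ``min_track_frames`` frames."""
    return [t for t in tracks if t.length > config.min_track_frames]
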