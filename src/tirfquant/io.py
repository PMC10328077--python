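"""TIFF and CSV input/output.

Image stacks travel as multi-page TIFF, one file per channel; all tabular
results are plain CSV with fixed headers.  Acquisition metadata (pixel size,
frame interval) comes from the run configuration, overriding any file tags.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .colocalization import ColocalizationRecord
from .detection import Focus
from .simulate import GroundTruth, ImageStack
from .stoichiometry import StepEvent, StoichiometryEstimate
from .tracking import Track


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an image stack as a multi-page 32-bit float TIFF."""
    tifffile.imwrite(str(path), stack.frames.astype(np.float32), photometric="minisblack")


def read_stack(
    path: str | Path,
    channel: str = "green",
    pixel_size: float = 100.0,
    frame_interval: float = 50.0,
) -> ImageStack:
    """Read a multi-page TIFF as an :class:`ImageStack`.

    Frames are ordered by page index.  Mixed frame shapes or an unreadable
    file raise ``ValueError`` — never a silently truncated stack.
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"stack file not found: {path}")
    try:
        pages = tifffile.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - surface any reader failure
        raise ValueError(f"could not read TIFF stack {path}: {exc}") from exc
    frames = np.asarray(pages, dtype=np.float64)
    if frames.size == 0:
        raise ValueError(f"could not read TIFF stack {path}: no image frames (truncated file?)")
    if frames.ndim == 2:
        frames = frames[None, :, :]
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2-D frames, got shape {frames.shape}")
    return ImageStack(
        frames=np.clip(frames, 0.0, None),
        channel=channel,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
    )


def ground_truth_frame(truth: GroundTruth) -> pd.DataFrame:
    rows = [
        {
            "spot_id": s.spot_id,
            "x": s.x,
            "y": s.y,
            "n_fluorophores": s.n_fluorophores,
            "channel": s.channel,
            "partner_id": -1 if s.partner_id is None else s.partner_id,
        }
        for s in truth.spots
    ]
    return pd.DataFrame(rows, columns=["spot_id", "x", "y", "n_fluorophores", "channel", "partner_id"])


def foci_frame(per_frame_foci: list[list[Focus]]) -> pd.DataFrame:
    rows = [
        {
            "frame": f.frame_index,
            "x": f.x,
            "y": f.y,
            "intensity": f.intensity,
            "background": f.background,
            "snr": f.snr,
            "converged": f.converged,
        }
        for foci in per_frame_foci
        for f in foci
    ]
    return pd.DataFrame(
        rows, columns=["frame", "x", "y", "intensity", "background", "snr", "converged"]
    )


def tracks_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = [
        {
            "track_id": t.track_id,
            "start_frame": t.start_frame,
            "length": t.length,
            "frame": f.frame_index,
            "x": f.x,
            "y": f.y,
            "intensity": f.intensity,
        }
        for t in tracks
        for f in t.foci
    ]
    return pd.DataFrame(
        rows, columns=["track_id", "start_frame", "length", "frame", "x", "y", "intensity"]
    )


def steps_frame(steps_by_track: dict[int, list[StepEvent]]) -> pd.DataFrame:
    rows = [
        {"track_id": tid, "frame": s.frame, "size": s.size}
        for tid, steps in steps_by_track.items()
        for s in steps
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "size"])


def stoichiometry_frame(estimates: list[StoichiometryEstimate]) -> pd.DataFrame:
    rows = [
        {
            "track_id": e.track_id,
            "start_frame": e.start_frame,
            "initial_intensity": e.initial_intensity,
            "characteristic_intensity": e.characteristic_intensity,
            "stoichiometry": e.stoichiometry,
            "n_steps": e.n_steps,
        }
        for e in estimates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "start_frame",
            "initial_intensity",
            "characteristic_intensity",
            "stoichiometry",
            "n_steps",
        ],
    )


def colocalization_frame(records: list[ColocalizationRecord]) -> pd.DataFrame:
    rows = [
        {
            "green_id": r.green_index,
            "red_id": -1 if r.red_index is None else r.red_index,
            "distance": r.distance,
            "overlap": r.overlap,
            "colocalized": r.colocalized,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["green_id", "red_id", "distance", "overlap", "colocalized"])
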