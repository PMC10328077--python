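"""Run configuration for the single-molecule and tissue pipelines.

Two dataclasses carry all tunable parameters:

* :class:`SimulationConfig` — the synthetic TIRF acquisition (image geometry,
  photophysics, noise model, spot layout).
* :class:`PipelineConfig` — the analysis thresholds.  The defaults encode the
  pipeline's procedural constants: foci are accepted when their
  signal-to-noise ratio is strictly above 0.4, tracks when they last strictly
  longer than three frames, foci pairs are colocalized when their overlap
  integral is strictly above 0.75, stoichiometry is estimated only for tracks
  starting within the first 10 movie frames using an ordinary least-squares
  fit of the first 4 intensity points, nuclei smaller than 50 pixels are
  discarded and per-cell ROIs are 100x100-pixel boxes.

Coordinate convention used throughout the package: 0-based, ``x`` is the
column index and ``y`` the row index, and pixel centers sit at integer
coordinates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

DEFAULT_SEED = 1234


@dataclass
class SpotSpec:
    """Ground-truth specification of one simulated focus.

    Parameters
    ----------
    x, y:
        Sub-pixel true position (x = column, y = row, 0-based).
    n_fluorophores:
        Number of fluorophores initially attached to the spot.
    channel:
        Channel label, ``"green"`` or ``"red"``.
    """

    x: float
    y: float
    n_fluorophores: int
    channel: str = "green"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic TIRF movie generator.

    Defaults reproduce a typical single-molecule TIRF acquisition geometry:
    100 nm pixels and 50 ms frames.  ``photon_scale_per_fluorophore`` (counts per fluorophore
    per frame) is a free parameter of the instrument model; the default of
    2000 counts/frame against a background of 100 counts/pixel/frame puts a
    single dye at a peak-pixel SNR near 18 and a per-inner-pixel SNR near
    0.9, i.e. a clean single-fluorophore step-trace regime in which the 0.4
    acceptance threshold admits single dyes.
    """

    image_width: int = 64
    image_height: int = 64
    n_frames: int = 100
    pixel_size: float = 100.0        # nm/pixel
    frame_interval: float = 50.0     # ms/frame
    psf_sigma: float = 1.3           # pixels
    photon_scale_per_fluorophore: float = 2000.0  # counts/fluorophore/frame
    bleach_prob: float = 0.05        # per fluorophore per frame
    background_rate: float = 100.0   # counts/pixel/frame
    read_noise_sigma: float = 2.0    # counts
    camera_offset: float = 0.0       # counts, added after noise
    spot_specs: list[SpotSpec] = field(default_factory=list)
    colocalized_fraction: float = 0.0
    coloc_displacement_sigma: float = 0.3   # pixels
    coloc_partner_fluorophores: int = 1
    shot_noise: bool = True          # False = expectation mode (no Poisson/read noise)
    rng_seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if not 0.0 <= self.bleach_prob <= 1.0:
            raise ValueError(f"bleach_prob must be in [0, 1], got {self.bleach_prob}")
        if not 0.0 <= self.colocalized_fraction <= 1.0:
            raise ValueError(
                f"colocalized_fraction must be in [0, 1], got {self.colocalized_fraction}"
            )
        if self.photon_scale_per_fluorophore <= 0:
            raise ValueError("photon_scale_per_fluorophore must be > 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.read_noise_sigma < 0:
            raise ValueError("read_noise_sigma must be >= 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.image_width < 1 or self.image_height < 1 or self.n_frames < 1:
            raise ValueError("image dimensions and n_frames must be >= 1")
        for spec in self.spot_specs:
            if not (0 <= spec.x <= self.image_width - 1 and 0 <= spec.y <= self.image_height - 1):
                raise ValueError(
                    f"spot at ({spec.x}, {spec.y}) lies outside the "
                    f"{self.image_width}x{self.image_height} image"
                )
            if spec.n_fluorophores < 0:
                raise ValueError("n_fluorophores must be >= 0")
            if spec.channel not in ("green", "red"):
                raise ValueError(f"unknown channel {spec.channel!r}")


@dataclass
class PipelineConfig:
    """Analysis thresholds and numerical parameters.

    The first seven fields are the pipeline's core procedural constants; all
    comparisons against them are strict inequalities (``>`` / ``<``).
    """

    snr_min: float = 0.4                    # accept focus iff snr > snr_min
    min_track_frames: int = 3               # keep track iff length > min_track_frames
    overlap_min: float = 0.75               # colocalized iff overlap > overlap_min
    max_start_frame_for_stoichiometry: int = 10   # track must start in frames [0, 9]
    regression_points: int = 4              # OLS points for photobleach correction
    area_min_px: int = 50                   # nuclei with area < 50 px removed
    roi_box_px: int = 100                   # per-cell ROI box side

    candidate_threshold_sigmas: float = 4.0
    link_radius_px: float = 5.0
    gap_frames: int = 0                     # missed detection terminates a track
    mask_sigma_px: float = 1.3
    roi_halfwidth: int = 8                  # detection ROI is (2h+1) x (2h+1)
    convergence_tol_px: float = 0.01
    max_iterations: int = 100
    snr_sentinel: float = 1e12              # snr when the border ring has zero sd

    ck_window_sizes: tuple[int, ...] = (2, 4, 8)
    ck_weight_exponent: float = 2.0
    step_sensitivity: float = 5.0           # t-statistic threshold for a split
    coloc_candidate_sigmas: float = 3.0     # pair candidates within this many sigma


@dataclass
class TissueSimulationConfig:
    """Parameters of the synthetic tissue-image generator.

    Two signal channels are produced: channel A is a shared random field,
    channel B mixes that shared field with an independent one as
    ``alpha * shared + (1 - alpha) * independent`` (equal-variance fields), so
    the expected Pearson correlation between the channels inside any ROI is
    ``alpha / sqrt(alpha**2 + (1 - alpha)**2)``.
    """

    image_width: int = 512
    image_height: int = 512
    n_nuclei: int = 12
    radius_min: float = 8.0          # pixels
    radius_max: float = 14.0
    nucleus_intensity: float = 200.0
    background: float = 20.0
    noise_sigma: float = 4.0
    alpha: float = 0.8               # channel-mixing coefficient in [0, 1]
    signal_mean: float = 100.0
    signal_sigma: float = 20.0
    min_separation: float = 4.0      # gap between nucleus borders, pixels
    rng_seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.radius_min <= 0 or self.radius_max < self.radius_min:
            raise ValueError("need 0 < radius_min <= radius_max")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")


@dataclass
class RunConfig:
    """Top-level configuration for the end-to-end pipeline."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    tissue: TissueSimulationConfig = field(default_factory=TissueSimulationConfig)
    seed: int = DEFAULT_SEED
    log_level: str = "INFO"


# ---------------------------------------------------------------------------
# YAML (de)serialization
# ---------------------------------------------------------------------------

def _asdict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        if isinstance(obj, list):
            return [clean(v) for v in obj]
        return obj

    return clean(d)


def _build(cls, data: dict):
    kwargs = dict(data)
    if cls is SimulationConfig and "spot_specs" in kwargs:
        kwargs["spot_specs"] = [
            s if isinstance(s, SpotSpec) else SpotSpec(**s) for s in kwargs["spot_specs"]
        ]
    if cls is PipelineConfig and "ck_window_sizes" in kwargs:
        kwargs["ck_window_sizes"] = tuple(kwargs["ck_window_sizes"])
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(kwargs) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize a :class:`RunConfig` to YAML (the reproducibility record)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_asdict(cfg), fh, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; missing sections take defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(
        simulation=_build(SimulationConfig, data.get("simulation", {})),
        pipeline=_build(PipelineConfig, data.get("pipeline", {})),
        tissue=_build(TissueSimulationConfig, data.get("tissue", {})),
        seed=int(data.get("seed", DEFAULT_SEED)),
        log_level=str(data.get("log_level", "INFO")),
    )
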