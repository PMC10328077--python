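"""Synthetic TIRF movies, photobleaching traces and tissue images.

The generator emulates a single-molecule TIRF acquisition: diffraction-limited
foci rendered as symmetric 2-D Gaussian point-spread functions *integrated
over the pixel area* (so sub-pixel photometry is exact), per-fluorophore
irreversible stochastic photobleaching, Poisson shot noise on the expected
photon count, additive Gaussian read noise and clipping at zero.  Every
simulated object is returned with its ground truth so downstream stages can
be validated by parameter recovery.

The expected photon image of one spot with ``n`` surviving fluorophores is

    E[I(r, c)] = lam + n * nu * Fx(c) * Fy(r)

where ``nu`` is the photon scale per fluorophore per frame, ``lam`` the
background rate, and ``Fx``/``Fy`` are the Gaussian CDF differences across
the pixel edges.  Fluorophore survival follows binomial thinning,
``n_{t+1} ~ Binomial(n_t, 1 - p)``, so ``E[n_t] = N (1 - p)**t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .config import SimulationConfig, SpotSpec, TissueSimulationConfig


@dataclass
class ImageStack:
    """An ordered stack of 2-D frames for one channel."""

    frames: np.ndarray               # (n_frames, height, width), float64, >= 0
    channel: str
    pixel_size: float = 100.0        # nm
    frame_interval: float = 50.0     # ms

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) array")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class SpotTruth:
    """Ground truth for one simulated spot."""

    spot_id: int
    x: float
    y: float
    n_fluorophores: int
    channel: str
    partner_id: int | None = None
    survival: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


@dataclass
class GroundTruth:
    """Ground truth for a simulated movie: one record per spot."""

    spots: list[SpotTruth]
    rng_seed: int

    def by_channel(self, channel: str) -> list[SpotTruth]:
        return [s for s in self.spots if s.channel == channel]


def integrated_gaussian_psf(
    shape: tuple[int, int], x: float, y: float, sigma: float
) -> np.ndarray:
    """Unit-mass symmetric 2-D Gaussian integrated over each pixel.

    Pixel centers sit at integer coordinates, so pixel ``(r, c)`` spans
    ``[c - 0.5, c + 0.5] x [r - 0.5, r + 0.5]``.  The returned array sums to
    the total mass falling inside the image (close to 1 for interior spots).
    """
    h, w = shape
    s = sigma * np.sqrt(2.0)
    cols = np.arange(w)
    rows = np.arange(h)
    fx = 0.5 * (erf((cols + 0.5 - x) / s) - erf((cols - 0.5 - x) / s))
    fy = 0.5 * (erf((rows + 0.5 - y) / s) - erf((rows - 0.5 - y) / s))
    return np.outer(fy, fx)


def _simulate_survival(
    n0: int, p: float, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame surviving fluorophore counts, n_0 = N, binomial thinning."""
    counts = np.empty(n_frames, dtype=int)
    n = n0
    for t in range(n_frames):
        counts[t] = n
        if p > 0 and n > 0:
            n = int(rng.binomial(n, 1.0 - p))
    return counts


def simulate_tirf_stack(
    config: SimulationConfig,
) -> tuple[dict[str, ImageStack], GroundTruth]:
    """Simulate a two-channel TIRF movie with known ground truth.

    Returns one :class:`ImageStack` per channel (``"green"`` and ``"red"``)
    and the :class:`GroundTruth`.  A fraction ``colocalized_fraction`` of the
    green spots receive a red partner displaced by an isotropic Gaussian of
    width ``coloc_displacement_sigma``.  With ``shot_noise=False`` and
    ``read_noise_sigma=0`` the output is the analytic expected image
    (expectation mode).  Identical config and seed give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    h, w = config.image_height, config.image_width
    nu = config.photon_scale_per_fluorophore

    spots: list[SpotTruth] = []
    for spec in config.spot_specs:
        spots.append(
            SpotTruth(
                spot_id=len(spots),
                x=spec.x,
                y=spec.y,
                n_fluorophores=spec.n_fluorophores,
                channel=spec.channel,
            )
        )

    # Assign red partners to a fraction of the green spots.
    green_ids = [s.spot_id for s in spots if s.channel == "green"]
    n_partners = int(round(config.colocalized_fraction * len(green_ids)))
    partner_of = rng.choice(green_ids, size=n_partners, replace=False) if n_partners else []
    for gid in sorted(int(g) for g in np.asarray(partner_of, dtype=int)):
        g = spots[gid]
        for _ in range(100):
            px = g.x + rng.normal(0.0, config.coloc_displacement_sigma)
            py = g.y + rng.normal(0.0, config.coloc_displacement_sigma)
            if 0 <= px <= w - 1 and 0 <= py <= h - 1:
                break
        partner = SpotTruth(
            spot_id=len(spots),
            x=px,
            y=py,
            n_fluorophores=config.coloc_partner_fluorophores,
            channel="red",
            partner_id=g.spot_id,
        )
        g.partner_id = partner.spot_id
        spots.append(partner)

    for s in spots:
        s.survival = _simulate_survival(
            s.n_fluorophores, config.bleach_prob, config.n_frames, rng
        )

    stacks: dict[str, ImageStack] = {}
    for channel in ("green", "red"):
        ch_spots = [s for s in spots if s.channel == channel]
        psfs = [
            integrated_gaussian_psf((h, w), s.x, s.y, config.psf_sigma) for s in ch_spots
        ]
        frames = np.empty((config.n_frames, h, w), dtype=np.float64)
        for t in range(config.n_frames):
            expected = np.full((h, w), float(config.background_rate))
            for s, psf in zip(ch_spots, psfs):
                n_t = s.survival[t]
                if n_t > 0:
                    expected += n_t * nu * psf
            if config.shot_noise:
                frame = rng.poisson(expected).astype(np.float64)
            else:
                frame = expected.copy()
            if config.read_noise_sigma > 0:
                frame = frame + rng.normal(0.0, config.read_noise_sigma, size=(h, w))
            frame += config.camera_offset
            frames[t] = np.clip(frame, 0.0, None)
        stacks[channel] = ImageStack(
            frames=frames,
            channel=channel,
            pixel_size=config.pixel_size,
            frame_interval=config.frame_interval,
        )

    return stacks, GroundTruth(spots=spots, rng_seed=config.rng_seed)


@dataclass
class SimulatedTrace:
    """A simulated single-spot intensity trace with known bleach times."""

    values: np.ndarray          # counts per frame
    survival: np.ndarray        # surviving fluorophores per frame
    bleach_frames: list[int]    # frames at which >= 1 fluorophore bleached
    photon_scale: float


def simulate_trace(
    n_fluorophores: int,
    photon_scale: float,
    bleach_prob: float,
    noise_sigma: float,
    n_frames: int,
    seed: int = 0,
    forced_bleach_frames: dict[int, int] | None = None,
) -> SimulatedTrace:
    """Simulate a step-wise photobleaching intensity trace.

    ``trace[t] = n_t * photon_scale + Normal(0, noise_sigma)`` where ``n_t``
    is the surviving fluorophore count.  ``forced_bleach_frames`` maps frame
    index to the number of fluorophores lost at that frame (deterministic
    steps for fixtures); otherwise bleaching is Bernoulli(``bleach_prob``)
    per fluorophore per frame.
    """
    if n_fluorophores < 0:
        raise ValueError("n_fluorophores must be >= 0")
    if not 0.0 <= bleach_prob <= 1.0:
        raise ValueError("bleach_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if forced_bleach_frames is not None:
        survival = np.empty(n_frames, dtype=int)
        n = n_fluorophores
        for t in range(n_frames):
            if t in forced_bleach_frames and t > 0:
                n = max(0, n - forced_bleach_frames[t])
            survival[t] = n
    else:
        survival = _simulate_survival(n_fluorophores, bleach_prob, n_frames, rng)
    bleach_frames = [int(t) for t in range(1, n_frames) if survival[t] < survival[t - 1]]
    values = survival.astype(np.float64) * photon_scale
    if noise_sigma > 0:
        values = values + rng.normal(0.0, noise_sigma, size=n_frames)
    return SimulatedTrace(
        values=values,
        survival=survival,
        bleach_frames=bleach_frames,
        photon_scale=photon_scale,
    )


# ---------------------------------------------------------------------------
# Tissue images
# ---------------------------------------------------------------------------


@dataclass
class NucleusTruth:
    """Ground truth for one simulated nucleus."""

    nucleus_id: int
    x: float
    y: float
    radius: float
    area_px: int                # rasterized disc area
    passes_area_filter: bool    # area_px >= 50


@dataclass
class TissueGroundTruth:
    nuclei: list[NucleusTruth]
    alpha: float
    expected_correlation: float   # analytic channel A vs B Pearson r
    rng_seed: int


def _rasterized_disc(shape: tuple[int, int], x: float, y: float, r: float) -> np.ndarray:
    h, w = shape
    rows, cols = np.ogrid[:h, :w]
    return (cols - x) ** 2 + (rows - y) ** 2 <= r * r


def expected_mixing_correlation(alpha: float) -> float:
    """Pearson correlation between the shared field and its alpha-mixture."""
    denom = np.sqrt(alpha**2 + (1.0 - alpha) ** 2)
    return float(alpha / denom) if denom > 0 else 0.0


def simulate_tissue_image(
    config: TissueSimulationConfig,
) -> tuple[np.ndarray, TissueGroundTruth]:
    """Simulate a multi-channel tissue image with known nuclei and correlation.

    Returns a ``(3, H, W)`` array — channel 0 the nuclei (DAPI-like) channel
    with bright filled discs, channels 1 and 2 the signal channels built from
    a shared field and an independent field mixed with coefficient ``alpha``
    — plus the ground truth (nucleus positions, rasterized areas, and the
    analytic expected inter-channel correlation).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    h, w = config.image_height, config.image_width

    # Rejection-sample non-overlapping nucleus centers.
    centers: list[tuple[float, float, float]] = []
    attempts = 0
    max_attempts = 2000 * max(config.n_nuclei, 1)
    while len(centers) < config.n_nuclei:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {config.n_nuclei} non-overlapping nuclei of radius "
                f"<= {config.radius_max} in a {w}x{h} image"
            )
        r = rng.uniform(config.radius_min, config.radius_max)
        x = rng.uniform(r + 1, w - r - 2)
        y = rng.uniform(r + 1, h - r - 2)
        if all(
            np.hypot(x - cx, y - cy) >= r + cr + config.min_separation
            for cx, cy, cr in centers
        ):
            centers.append((x, y, r))

    nuclei_channel = np.full((h, w), config.background, dtype=np.float64)
    truths: list[NucleusTruth] = []
    for i, (x, y, r) in enumerate(centers):
        disc = _rasterized_disc((h, w), x, y, r)
        nuclei_channel[disc] = config.background + config.nucleus_intensity
        area = int(disc.sum())
        truths.append(
            NucleusTruth(
                nucleus_id=i, x=x, y=y, radius=r, area_px=area,
                passes_area_filter=area >= 50,
            )
        )
    if config.noise_sigma > 0:
        nuclei_channel += rng.normal(0.0, config.noise_sigma, size=(h, w))
    nuclei_channel = np.clip(nuclei_channel, 0.0, None)

    # Signal channels: A = shared field; B = alpha*shared + (1-alpha)*independent.
    shared = rng.normal(0.0, config.signal_sigma, size=(h, w))
    indep = rng.normal(0.0, config.signal_sigma, size=(h, w))
    alpha = config.alpha
    chan_a = config.signal_mean + shared
    chan_b = config.signal_mean + alpha * shared + (1.0 - alpha) * indep
    image = np.stack(
        [nuclei_channel, np.clip(chan_a, 0.0, None), np.clip(chan_b, 0.0, None)]
    )

    truth = TissueGroundTruth(
        nuclei=truths,
        alpha=alpha,
        expected_correlation=expected_mixing_correlation(alpha),
        rng_seed=config.rng_seed,
    )
    return image, truth


def grid_spot_specs(
    counts: list[int],
    image_width: int,
    image_height: int,
    spacing: float = 12.0,
    margin: float = 10.0,
    channel: str = "green",
    jitter: float = 0.5,
    seed: int = 0,
) -> list[SpotSpec]:
    """Lay spots on a jittered grid so they never overlap.

    ``counts`` gives the fluorophore count of each spot; spots are placed
    row-major with ``spacing`` pixels between grid nodes plus a uniform
    sub-pixel jitter so localization is exercised off pixel centers.
    """
    rng = np.random.default_rng(seed)
    n_cols = int((image_width - 2 * margin) // spacing) + 1
    specs = []
    for i, n in enumerate(counts):
        gx = margin + (i % n_cols) * spacing
        gy = margin + (i // n_cols) * spacing
        if gy > image_height - margin:
            raise ValueError("too many spots for the image size")
        specs.append(
            SpotSpec(
                x=float(gx + rng.uniform(-jitter, jitter)),
                y=float(gy + rng.uniform(-jitter, jitter)),
                n_fluorophores=int(n),
                channel=channel,
            )
        )
    return specs
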