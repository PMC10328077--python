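import numpy as np
import pytest

from tirfquant import PipelineConfig, SimulationConfig, SpotSpec


@pytest.fixture
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def noiseless_spot_config() -> SimulationConfig:
    """One bright spot, no noise of any kind (expectation mode)."""
    return SimulationConfig(
        image_width=32,
        image_height=32,
        n_frames=5,
        spot_specs=[SpotSpec(15.3, 16.7, 1)],
        bleach_prob=0.0,
        background_rate=0.0,
        read_noise_sigma=0.0,
        shot_noise=False,
        rng_seed=1,
    )


def make_noiseless_frame(
    positions: list[tuple[float, float]],
    photons: float = 2000.0,
    shape: tuple[int, int] = (64, 64),
    background: float = 100.0,
    psf_sigma: float = 1.3,
) -> np.ndarray:
    """Analytic expected frame: background plus integrated-Gaussian spots."""
    from tirfquant import integrated_gaussian_psf

    frame = np.full(shape, background, dtype=np.float64)
    for x, y in positions:
        frame += photons * integrated_gaussian_psf(shape, x, y, psf_sigma)
    return frame
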