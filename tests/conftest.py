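import numpy as np
import pytest

from nucfish import DetectionParams, ImageStack, NO_NOISE, SceneConfig, generate_scene


def render_gaussian_stack(
    centers,
    amplitudes=None,
    sigma=1.5,
    background=10.0,
    shape=(1, 32, 32),
    read_noise=0.0,
    seed=0,
    channel="exon",
):
    """Single-channel stack with ideal 2D Gaussian puncta at given (z, y, x)."""
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    vol = np.full(shape, background, dtype=float)
    yg, xg = np.mgrid[0:ny, 0:nx].astype(float)
    if amplitudes is None:
        amplitudes = [100.0] * len(centers)
    for (z, y, x), a in zip(centers, amplitudes):
        vol[int(z)] += a * np.exp(-((yg - y) ** 2 + (xg - x) ** 2) / (2 * sigma**2))
    if read_noise > 0:
        vol = np.clip(vol + rng.normal(0, read_noise, vol.shape), 0, None)
    return ImageStack(vol[None], channel_names=(channel,))


@pytest.fixture
def clean_scene():
    """Small noise-free scene with resolvable spot density."""
    cfg = SceneConfig(
        image_shape=(3, 160, 160),
        n_nuclei=3,
        nucleus_radius_px=(28.0, 1.0),
        txn_sites_per_nucleus=("poisson", 1.5),
        single_spots_per_nucleus=("poisson", 6.0),
        min_spot_separation_px=6.0,
        noise_model=NO_NOISE,
        seed=11,
    )
    return cfg, *generate_scene(cfg)


@pytest.fixture
def detection_params():
    return DetectionParams()
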