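"""Shared fixtures and independent oracle generators."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from collmig.piv import VelocityField

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def gaussian_speckle(
    size: int = 256,
    n_spots: int = 2000,
    sigma: float = 1.0,
    seed: int = 0,
    shift: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Periodic particle-speckle image: a sum of Gaussian spots at random
    positions with wrap-around, so that np.roll is an exact translation.

    ``shift`` (dy, dx) translates every spot analytically, producing exact
    sub-pixel displacements.
    """
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, size, (n_spots, 2))
    img = np.zeros((size, size))
    half = int(np.ceil(4 * sigma)) + 1
    for y, x in pos:
        y += shift[0]
        x += shift[1]
        yi, xi = int(np.floor(y)), int(np.floor(x))
        yy, xx = np.mgrid[yi - half:yi + half + 1, xi - half:xi + half + 1]
        patch = np.exp(-(((xx - x) ** 2 + (yy - y) ** 2)) / (2 * sigma**2))
        np.add.at(img, ((yy % size).ravel(), (xx % size).ravel()), patch.ravel())
    return img


def exp_corr_component(lam: float, n: int, spacing: float, seed: int) -> np.ndarray:
    """Gaussian random field with isotropic covariance exp(-r/lam), by
    spectral synthesis: white noise colored with the square root of the 2D
    spectral density of the exponential covariance,
    S(k) = 2 pi lam^2 / (1 + (k lam)^2)^(3/2)."""
    rng = np.random.default_rng(seed)
    k = np.hypot(
        (np.fft.fftfreq(n, d=spacing) * 2 * np.pi)[:, None],
        (np.fft.fftfreq(n, d=spacing) * 2 * np.pi)[None, :],
    )
    S = 2 * np.pi * lam**2 / (1 + (k * lam) ** 2) ** 1.5
    noise = np.fft.fft2(rng.standard_normal((n, n)))
    field = np.real(np.fft.ifft2(noise * np.sqrt(S)))
    return field / field.std()


def exp_corr_velocity_field(
    lam: float, n: int = 200, spacing: float = 5.0, seed: int = 0
) -> VelocityField:
    """Velocity field whose u and v components are independent Gaussian
    fields with covariance exp(-r/lam); its vector autocorrelation is
    exp(-r/lam) by construction."""
    coords = (np.arange(n) + 0.5) * spacing
    return VelocityField(
        grid_x=coords,
        grid_y=coords,
        u=exp_corr_component(lam, n, spacing, seed),
        v=exp_corr_component(lam, n, spacing, seed + 10_000),
        valid=np.ones((n, n), dtype=bool),
    )


def uniform_velocity_field(
    u0: float, v0: float, n: int = 10, spacing: float = 10.0
) -> VelocityField:
    coords = (np.arange(n) + 0.5) * spacing
    return VelocityField(
        grid_x=coords,
        grid_y=coords,
        u=np.full((n, n), u0),
        v=np.full((n, n), v0),
        valid=np.ones((n, n), dtype=bool),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
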