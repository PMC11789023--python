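"""Shared fixtures: canonical parameter sets and synthetic inputs."""

from __future__ import annotations

import numpy as np
import pytest

from bioconvect import (
    MotilityParams,
    SuspensionParams,
    simulate_run_and_tumble,
)


@pytest.fixture(scope="session")
def suspension_3d() -> SuspensionParams:
    """The 3D-compartment parameter set (1 mm depth)."""
    return SuspensionParams(
        volume_fraction=0.021,
        density_contrast=0.05,
        kinematic_viscosity_m2_s=1e-6,
        cell_diffusion_um2_s=1.6e4,
        cell_speed_um_s=46.0,
        depth_mm=1.0,
        reorientation_time_s=3.0,
        gravity_m_s2=9.8,
    )


@pytest.fixture(scope="session")
def suspension_quasi2d() -> SuspensionParams:
    """The quasi-2D compartment parameter set (2 mm depth)."""
    return SuspensionParams(
        volume_fraction=0.021,
        density_contrast=0.05,
        kinematic_viscosity_m2_s=1e-6,
        cell_diffusion_um2_s=1.6e4,
        cell_speed_um_s=46.0,
        depth_mm=2.0,
        reorientation_time_s=3.0,
    )


@pytest.fixture(scope="session")
def rt_ensemble():
    """A mid-sized anaerobic-plateau run-and-tumble ensemble (free space)."""
    params = MotilityParams(speed_um_s=46.0, tumble_rate_per_s=1.0 / 15.0)
    return simulate_run_and_tumble(
        params, None, n_cells=400, duration_s=60.0, dt_s=1.0 / 30.0, seed=42
    )


def particle_image(shape, positions, sigma=1.2, amplitude=100.0, background=50.0):
    """Render Gaussian-spot particles at subpixel positions."""
    img = np.full(shape, float(background))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    w = int(4 * sigma) + 3
    for y, x in positions:
        y0, x0 = int(y), int(x)
        sl = (
            slice(max(0, y0 - w), min(shape[0], y0 + w + 1)),
            slice(max(0, x0 - w), min(shape[1], x0 + w + 1)),
        )
        img[sl] += amplitude * np.exp(
            -((yy[sl] - y) ** 2 + (xx[sl] - x) ** 2) / (2 * sigma**2)
        )
    return img


@pytest.fixture(scope="session")
def piv_frame_pair():
    """Particle-image pair with a known uniform (3.0, −1.5) px displacement."""
    rng = np.random.default_rng(2)
    pos = np.column_stack([rng.uniform(0, 256, 1500), rng.uniform(0, 256, 1500)])
    frame_a = particle_image((256, 256), pos)
    frame_b = particle_image((256, 256), pos + np.array([3.0, -1.5]))
    return frame_a, frame_b
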