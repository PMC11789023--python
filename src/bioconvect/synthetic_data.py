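"""Synthetic swimmer trajectories and transmitted-light image stacks.

This module generates data with the statistical structure the analysis
pipeline assumes, so every downstream stage (spectral pattern analysis,
densitometry, motility statistics, PIV) can be exercised and validated
without experimental recordings.

Three generators are provided:

* :func:`simulate_run_and_tumble` — 2D run-and-tumble motility: ballistic
  runs at constant speed interrupted by Poisson-timed complete
  reorientations, optionally with rotational diffusion. Produces the
  exponential velocity autocorrelation ``Cv(t) = v² exp(-t/τc)`` that the
  motility module fits.
* :func:`simulate_gyrotactic_swimmers` — bottom-heavy swimmers whose
  orientation relaxes toward the vertical on a timescale ``B`` while being
  rotated by the local flow vorticity (gyrotaxis), with rotational white
  noise. Reproduces the gravitactic fixed point, the tilted equilibrium
  ``sin θ = Bω`` in uniform vorticity, and inverse sedimentation profiles
  in closed columns.
* :func:`render_transmission_stack` / :func:`generate_growing_pattern` —
  Beer–Lambert image formation (per-pixel attenuation by the projected
  cell column count, PSF blur, shot/read noise, quantization) and a
  parametric growing-stripe fixture for the spectral pipeline.

Integration is Euler–Maruyama; orientations are evolved as a single angle
so the unit norm is preserved exactly. Walls are reflective for position
with orientation unchanged; passing ``domain=None`` simulates free space,
which emulates tracking in a field of view far from compartment walls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import ImageStack, ParameterError, TrajectorySet

__all__ = [
    "MotilityParams",
    "DomainSpec",
    "RenderParams",
    "PrescribedFlow",
    "simulate_run_and_tumble",
    "simulate_gyrotactic_swimmers",
    "render_transmission_stack",
    "generate_growing_pattern",
]


@dataclass
class MotilityParams:
    """Single-cell motility parameters.

    Attributes
    ----------
    speed_um_s
        Swimming speed ``u`` along the body axis, µm/s.
    tumble_rate_per_s
        Poisson rate of complete reorientations; the reciprocal of the
        target velocity correlation time ``τc`` for pure run-and-tumble.
    rot_diffusion_rad2_s
        Rotational diffusivity ``Dr`` (white noise on the body angle).
    reorientation_time_s
        Gravitactic reorientation timescale ``B``; time for a bottom-heavy
        cell to right itself against gravity (gyrotactic runs only).
    sediment_speed_um_s
        Passive sinking speed added along −z.
    cell_radius_um
        Cell radius, used by rendering and steric options.
    """

    speed_um_s: float
    tumble_rate_per_s: float = 0.0
    rot_diffusion_rad2_s: float = 0.0
    reorientation_time_s: float = 0.0
    sediment_speed_um_s: float = 0.0
    cell_radius_um: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "speed_um_s",
            "tumble_rate_per_s",
            "rot_diffusion_rad2_s",
            "reorientation_time_s",
            "sediment_speed_um_s",
            "cell_radius_um",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


@dataclass
class DomainSpec:
    """Rectangular 2D compartment with reflective walls; gravity along −z."""

    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ParameterError("domain dimensions must be positive")


@dataclass
class RenderParams:
    """Beer–Lambert image-formation parameters.

    ``attenuation_per_cell`` lumps the cell attenuation coefficient and the
    optical path length into a single dimensionless optical depth per cell
    in the pixel column.
    """

    incident_intensity: float = 1000.0
    attenuation_per_cell: float = 0.05
    psf_sigma_um: float = 0.0
    noise_model: str = "none"  # none | gaussian | poisson
    noise_sigma: float = 0.0
    pixel_size_um: float = 20.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.incident_intensity <= 0:
            raise ParameterError("incident_intensity must be positive")
        if self.attenuation_per_cell < 0:
            raise ParameterError("attenuation_per_cell must be non-negative")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ParameterError(f"unknown noise model {self.noise_model!r}")


class PrescribedFlow:
    """Externally imposed 2D flow sampled at cell positions.

    Parameters
    ----------
    velocity
        ``velocity(x, z) -> (ux, uz)`` arrays, µm/s.
    vorticity
        ``vorticity(x, z) -> ω`` array, rad/s (out-of-plane component of
        ``∇×u``); needed for the gyrotactic torque.
    """

    def __init__(
        self,
        velocity: Callable[[np.ndarray, np.ndarray], tuple],
        vorticity: Callable[[np.ndarray, np.ndarray], np.ndarray],
    ):
        self.velocity = velocity
        self.vorticity = vorticity

    @classmethod
    def uniform_vorticity(cls, omega: float) -> "PrescribedFlow":
        """Solid-body-like rotation shear characterized only by its vorticity."""
        return cls(
            velocity=lambda x, z: (np.zeros_like(x), np.zeros_like(z)),
            vorticity=lambda x, z: np.full_like(x, omega),
        )


def _validate_time(duration: float, dt: float) -> int:
    if dt <= 0 or duration <= 0:
        raise ParameterError("dt and duration must be positive")
    return int(round(duration / dt))


#: free-space starting box: side = this × sqrt(n_cells), giving ~800 cells/mm²
#: (the areal density range of the motility assays)
FREE_SPACE_SPACING_UM = 50.0


def _init_state(
    domain: Optional[DomainSpec], n_cells: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if domain is None:
        side = FREE_SPACE_SPACING_UM * np.sqrt(n_cells)
        x = rng.uniform(0.0, side, n_cells)
        z = rng.uniform(0.0, side, n_cells)
    else:
        x = rng.uniform(0.0, domain.width_um, n_cells)
        z = rng.uniform(0.0, domain.height_um, n_cells)
    return x, z


def _reflect(pos: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # fold positions back into [lo, hi]; handles multiple reflections
    span = hi - lo
    pos = np.mod(pos - lo, 2 * span)
    pos = np.where(pos > span, 2 * span - pos, pos)
    return pos + lo


def _to_trajectory_set(
    x: np.ndarray,
    z: np.ndarray,
    px: np.ndarray,
    pz: np.ndarray,
    dt: float,
    record_every: int = 1,
) -> TrajectorySet:
    n_frames, n_cells = x.shape
    frames = np.repeat(np.arange(n_frames), n_cells)
    track = np.tile(np.arange(n_cells), n_frames)
    df = pd.DataFrame(
        {
            "track_id": track,
            "frame": frames,
            "time_s": frames * (dt * record_every),
            "x_um": x.ravel(),
            "z_um": z.ravel(),
            "px": px.ravel(),
            "pz": pz.ravel(),
        }
    )
    df = df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    return TrajectorySet(df, frame_interval_s=dt * record_every)


def simulate_run_and_tumble(
    params: MotilityParams,
    domain: Optional[DomainSpec],
    n_cells: int,
    duration_s: float,
    dt_s: float = 1.0 / 30.0,
    seed: int = 0,
    record_every: int = 1,
) -> TrajectorySet:
    """Simulate 2D run-and-tumble swimmers.

    Cells move ballistically at ``speed_um_s`` along their body axis;
    tumbles occur as a Poisson process at ``tumble_rate_per_s`` and fully
    randomize the direction (uniform on the circle). Rotational diffusion,
    if nonzero, adds angular white noise between tumbles. With
    ``domain=None`` cells start at the origin in free space; otherwise they
    start uniformly in the compartment and reflect off the walls.
    ``record_every`` thins the stored frames (the integration step stays
    ``dt_s``).
    """
    n_steps = _validate_time(duration_s, dt_s)
    if params.tumble_rate_per_s > 0 and dt_s >= 1.0 / params.tumble_rate_per_s:
        raise ParameterError("dt must resolve the tumble rate (dt < 1/rate)")
    rng = np.random.default_rng(seed)
    x, z = _init_state(domain, n_cells, rng)
    theta = rng.uniform(0.0, 2 * np.pi, n_cells)

    u = params.speed_um_s
    p_tumble = -np.expm1(-params.tumble_rate_per_s * dt_s)
    sig_rot = np.sqrt(2.0 * params.rot_diffusion_rad2_s * dt_s)

    n_rec = n_steps // record_every
    X = np.empty((n_rec + 1, n_cells))
    Z = np.empty((n_rec + 1, n_cells))
    PX = np.empty((n_rec + 1, n_cells))
    PZ = np.empty((n_rec + 1, n_cells))
    X[0], Z[0] = x, z
    PX[0], PZ[0] = np.sin(theta), np.cos(theta)

    for k in range(1, n_steps + 1):
        # reorient first, then move: each recorded step is a clean run segment
        if p_tumble > 0:
            tumbling = rng.random(n_cells) < p_tumble
            if tumbling.any():
                theta[tumbling] = rng.uniform(0.0, 2 * np.pi, int(tumbling.sum()))
        if sig_rot > 0:
            theta = theta + sig_rot * rng.standard_normal(n_cells)
        px, pz = np.sin(theta), np.cos(theta)
        x = x + u * px * dt_s
        z = z + (u * pz - params.sediment_speed_um_s) * dt_s
        if domain is not None:
            x = _reflect(x, 0.0, domain.width_um)
            z = _reflect(z, 0.0, domain.height_um)
        if k % record_every == 0:
            i = k // record_every
            X[i], Z[i], PX[i], PZ[i] = x, z, px, pz

    return _to_trajectory_set(X, Z, PX, PZ, dt_s, record_every)


def simulate_gyrotactic_swimmers(
    params: MotilityParams,
    domain: Optional[DomainSpec],
    flow: Optional[PrescribedFlow],
    n_cells: int,
    duration_s: float,
    dt_s: float = 1.0 / 30.0,
    seed: int = 0,
    initial_angle_rad: Optional[float] = None,
    record_every: int = 1,
) -> TrajectorySet:
    """Simulate bottom-heavy (gyrotactic) swimmers in an optional flow.

    The body angle θ (measured from +z, the up direction) obeys

        dθ = [-sin θ / (2B) + ω/2] dt + sqrt(2 Dr) dW,

    the 2D angle form of the orientation balance dp/dt =
    (1/2B)(ẑ - (ẑ·p)p) + ½ ω×p plus rotational noise; |p| = 1 holds
    exactly. Positions advance as ``u·p + u_flow - sediment·ẑ``. A uniform
    vorticity ω with Bω < 1 yields the tilted equilibrium sin θ = Bω;
    Bω ≥ 1 yields continuous tumbling (allowed, not an error).

    ``initial_angle_rad`` pins every cell's initial orientation (useful for
    deterministic relaxation tests); by default angles are drawn uniformly.
    """
    if params.reorientation_time_s <= 0:
        raise ParameterError("gyrotactic simulation requires reorientation_time_s > 0")
    n_steps = _validate_time(duration_s, dt_s)
    rng = np.random.default_rng(seed)
    x, z = _init_state(domain, n_cells, rng)
    if initial_angle_rad is None:
        theta = rng.uniform(-np.pi, np.pi, n_cells)
    else:
        theta = np.full(n_cells, float(initial_angle_rad))

    u = params.speed_um_s
    inv2B = 1.0 / (2.0 * params.reorientation_time_s)
    sig_rot = np.sqrt(2.0 * params.rot_diffusion_rad2_s * dt_s)

    n_rec = n_steps // record_every
    X = np.empty((n_rec + 1, n_cells))
    Z = np.empty((n_rec + 1, n_cells))
    PX = np.empty((n_rec + 1, n_cells))
    PZ = np.empty((n_rec + 1, n_cells))
    X[0], Z[0] = x, z
    PX[0], PZ[0] = np.sin(theta), np.cos(theta)

    for k in range(1, n_steps + 1):
        if flow is not None:
            omega = np.asarray(flow.vorticity(x, z), dtype=float)
            ux, uz = flow.velocity(x, z)
        else:
            omega = 0.0
            ux = uz = 0.0
        dtheta = (-np.sin(theta) * inv2B + 0.5 * omega) * dt_s
        if sig_rot > 0:
            dtheta = dtheta + sig_rot * rng.standard_normal(n_cells)
        theta = theta + dtheta
        px, pz = np.sin(theta), np.cos(theta)
        x = x + (u * px + ux) * dt_s
        z = z + (u * pz + uz - params.sediment_speed_um_s) * dt_s
        if domain is not None:
            x = _reflect(x, 0.0, domain.width_um)
            z = _reflect(z, 0.0, domain.height_um)
        if k % record_every == 0:
            i = k // record_every
            X[i], Z[i], PX[i], PZ[i] = x, z, px, pz

    return _to_trajectory_set(X, Z, PX, PZ, dt_s, record_every)


def _column_counts(
    traj: TrajectorySet, domain: DomainSpec, pixel_size_um: float
) -> np.ndarray:
    """Histogram cell positions into the pixel grid, frame by frame."""
    nx = max(1, int(round(domain.width_um / pixel_size_um)))
    nz = max(1, int(round(domain.height_um / pixel_size_um)))
    x_edges = np.linspace(0.0, domain.width_um, nx + 1)
    z_edges = np.linspace(0.0, domain.height_um, nz + 1)
    frames = np.sort(traj.data["frame"].unique())
    counts = np.zeros((len(frames), nz, nx))
    grouped = traj.data.groupby("frame")
    for i, f in enumerate(frames):
        g = grouped.get_group(f)
        # clip so boundary cells land in the edge pixels
        xs = np.clip(g["x_um"].to_numpy(), 0, domain.width_um - 1e-9)
        zs = np.clip(g["z_um"].to_numpy(), 0, domain.height_um - 1e-9)
        h, _, _ = np.histogram2d(zs, xs, bins=[z_edges, x_edges])
        counts[i] = h
    return counts


def render_transmission_stack(
    source: Union[TrajectorySet, np.ndarray],
    rp: RenderParams,
    domain: Optional[DomainSpec] = None,
    frame_interval_s: Optional[float] = None,
    seed: int = 0,
) -> ImageStack:
    """Render transmitted-light images via the Beer–Lambert forward model.

    Per pixel, the transmitted intensity is ``IT = I0 · exp(-a·k)`` with
    ``a`` the per-cell attenuation and ``k`` the projected cell count in
    the pixel column; PSF blur, noise and quantization are applied in that
    order, so intensity is monotone decreasing in local cell count before
    noise.

    ``source`` may be a :class:`TrajectorySet` (requires ``domain``) or a
    ``(T, H, W)`` array of column counts / densities.
    """
    if isinstance(source, TrajectorySet):
        if domain is None:
            raise ParameterError("domain required to rasterize trajectories")
        if len(source.data) == 0:
            warnings.warn("empty trajectory set: rendering uniform frames at I0")
            nx = max(1, int(round(domain.width_um / rp.pixel_size_um)))
            nz = max(1, int(round(domain.height_um / rp.pixel_size_um)))
            counts = np.zeros((1, nz, nx))
        else:
            counts = _column_counts(source, domain, rp.pixel_size_um)
        dt = source.frame_interval_s
    else:
        counts = np.asarray(source, dtype=float)
        if counts.ndim == 2:
            counts = counts[None]
        dt = frame_interval_s if frame_interval_s is not None else 1.0
    rng = np.random.default_rng(seed)

    it = rp.incident_intensity * np.exp(-rp.attenuation_per_cell * counts)
    if rp.psf_sigma_um > 0:
        sigma_px = rp.psf_sigma_um / rp.pixel_size_um
        it = np.stack([gaussian_filter(f, sigma_px) for f in it])
    if rp.noise_model == "gaussian" and rp.noise_sigma > 0:
        it = it + rng.normal(0.0, rp.noise_sigma, it.shape)
    elif rp.noise_model == "poisson":
        it = rng.poisson(np.clip(it, 0, None)).astype(float)
    it = np.clip(np.round(it), 0, 2**rp.bit_depth - 1)
    return ImageStack(
        it,
        pixel_size_um=rp.pixel_size_um,
        frame_interval_s=dt,
        bit_depth=rp.bit_depth,
    )


def generate_growing_pattern(
    wavelength_mm: float = 1.7,
    growth_rate_per_s: float = 0.04,
    onset_time_s: float = 220.0,
    duration_s: float = 600.0,
    frame_interval_s: float = 2.0,
    noise_sigma: float = 2.0,
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
    pixel_size_um: float = 100.0,
    incident_intensity: float = 1000.0,
    initial_amplitude: float = 0.02,
    saturation_amplitude: float = 0.3,
) -> ImageStack:
    """Generate a stack with a stripe pattern growing exponentially in time.

    Uniform frames (plus noise) before ``onset_time_s``; afterwards a
    sinusoidal modulation of relative amplitude
    ``A(t) = A0·exp(growth_rate·(t - onset))``, saturating at
    ``saturation_amplitude``. Defaults place the programmed truth at the
    observed pattern scale (λ = 1.7 mm) and dynamics (ω = 0.04 s⁻¹,
    onset 220 s) of a convecting suspension.

    The initial amplitude sits above the image noise floor so that the
    programmed onset time is also the detectable onset: for exponential
    growth from a sub-noise amplitude, any onset detector necessarily
    reports the later noise-crossing time instead.
    """
    lam_px = wavelength_mm * 1000.0 / pixel_size_um
    if lam_px < 2.0:
        raise ParameterError("wavelength below the Nyquist limit of 2 pixels")
    if lam_px < 4.0:
        warnings.warn("wavelength under 4 pixels is poorly resolved")
    n_frames = int(round(duration_s / frame_interval_s))
    if n_frames < 1:
        raise ParameterError("duration shorter than one frame interval")
    rng = np.random.default_rng(seed)
    nz, nx = shape
    xpix = np.arange(nx) * pixel_size_um / 1000.0  # mm
    stripe = np.sin(2 * np.pi * xpix / wavelength_mm)[None, :] * np.ones((nz, 1))

    frames = np.empty((n_frames, nz, nx))
    t = np.arange(n_frames) * frame_interval_s
    amp = np.where(
        t < onset_time_s,
        0.0,
        np.minimum(
            initial_amplitude * np.exp(growth_rate_per_s * (t - onset_time_s)),
            saturation_amplitude,
        ),
    )
    for i in range(n_frames):
        frames[i] = incident_intensity * (1.0 + amp[i] * stripe)
    if noise_sigma > 0:
        frames = frames + rng.normal(0.0, noise_sigma, frames.shape)
    frames = np.clip(np.round(frames), 0, 2**16 - 1)
    return ImageStack(
        frames,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        bit_depth=16,
    )
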