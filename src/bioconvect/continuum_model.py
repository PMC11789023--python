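"""Gyrotactic continuum theory of bioconvection.

A suspension of up-swimming, bottom-heavy cells that are slightly denser
than the medium is described by the standard continuum model: an
incompressible Boussinesq momentum balance with buoyancy forcing
``-n·vc·(Δρ/ρ)·g·ẑ``, a cell conservation law with advection, directed
swimming ``v·p`` and diffusion ``D``, and a quasi-static orientation
balance between the gravitactic righting torque (timescale ``B``) and the
viscous torque from the local vorticity (gyrotaxis): ``sin θ = B ω``.

Nondimensionalizing lengths by the depth ``h``, time by ``h²/D`` and the
cell density by its mean ``n0`` yields four groups:

* Rayleigh number  ``R = g φ (Δρ/ρ) h³ / (ν D)``
* scaled cell speed  ``w = v h / D``
* gyrotactic number  ``G = B D / h²``
* Schmidt number  ``Sc = ν / D``

With no flow the cell flux balance ``w n = dn/dz`` gives the inverse
sedimentation base state ``n̄(z) ∝ exp(w z)`` (decay length ``D/v``
downward from the top). The layer is unstable to convection when ``R``
exceeds a critical value ``Rc(w, G, Sc)``; for deep layers with ``w > 1``
and no-slip walls ``Rc`` grows like ``w⁴``, so halving the swimming speed
lowers the instability threshold ~16-fold — the mechanism by which a
motility change switches bioconvection on and off at constant ``R``.

The linear solver discretizes the normal-mode problem on a vertical grid
(second-order finite differences, boundary-row tau treatment) and the
nonlinear solver advances the stream-function–vorticity form with a
conservative finite-volume cell update (upwind advection, central
diffusion) and semi-implicit vorticity diffusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .core import ParameterError

__all__ = [
    "SuspensionParams",
    "DimensionlessNumbers",
    "Fields2D",
    "compute_dimensionless_numbers",
    "critical_rayleigh_ratio",
    "steady_sedimentation_profile",
    "linear_growth_rate",
    "critical_rayleigh",
    "simulate_bioconvection_2d",
]

#: default wavenumber search band for the critical-Rayleigh scan, cycles/mm
Q_SEARCH_BAND_PER_MM = (0.1, 20.0)


@dataclass
class SuspensionParams:
    """Physical parameters of the suspension.

    Units are chosen to match how each quantity is usually quoted:
    SI for gravity and viscosity, µm/s and µm²/s for cell-scale speeds and
    diffusion, mm for the compartment depth.
    """

    volume_fraction: float
    density_contrast: float  # Δρ/ρ
    kinematic_viscosity_m2_s: float
    cell_diffusion_um2_s: float
    cell_speed_um_s: float
    depth_mm: float
    reorientation_time_s: Optional[float] = None  # B; may be unknown
    gravity_m_s2: float = 9.8
    cell_volume_um3: Optional[float] = None
    mean_density_per_ml: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "volume_fraction",
            "density_contrast",
            "kinematic_viscosity_m2_s",
            "cell_diffusion_um2_s",
            "cell_speed_um_s",
            "depth_mm",
            "gravity_m_s2",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.reorientation_time_s is not None and self.reorientation_time_s <= 0:
            raise ParameterError("reorientation_time_s must be positive when given")
        if self.cell_volume_um3 is not None and self.mean_density_per_ml is not None:
            # 1 mL = 1e12 µm³
            phi = self.mean_density_per_ml * self.cell_volume_um3 / 1e12
            if self.volume_fraction > 0 and abs(phi - self.volume_fraction) > 1e-6 * self.volume_fraction:
                raise ParameterError(
                    f"volume_fraction={self.volume_fraction} inconsistent with "
                    f"n0*vc={phi}"
                )


@dataclass
class DimensionlessNumbers:
    """The four groups governing bioconvective stability.

    ``gyrotactic`` is NaN when the reorientation time B is unknown.
    """

    rayleigh: float
    scaled_speed: float
    gyrotactic: float
    schmidt: float

    def as_dict(self) -> dict:
        return {
            "rayleigh": self.rayleigh,
            "scaled_speed": self.scaled_speed,
            "gyrotactic": self.gyrotactic,
            "schmidt": self.schmidt,
        }


def compute_dimensionless_numbers(p: SuspensionParams) -> DimensionlessNumbers:
    """Evaluate R, w, G and Sc from physical parameters.

    R = g φ (Δρ/ρ) h³ / (ν D);  w = v h / D;  G = B D / h²;  Sc = ν / D.
    """
    if p.cell_diffusion_um2_s == 0:
        raise ParameterError("cell_diffusion_um2_s must be positive")
    h_m = p.depth_mm * 1e-3
    d_m2_s = p.cell_diffusion_um2_s * 1e-12
    rayleigh = (
        p.gravity_m_s2
        * p.volume_fraction
        * p.density_contrast
        * h_m**3
        / (p.kinematic_viscosity_m2_s * d_m2_s)
    )
    h_um = p.depth_mm * 1e3
    w = p.cell_speed_um_s * h_um / p.cell_diffusion_um2_s
    if p.reorientation_time_s is None:
        g_num = math.nan
    else:
        g_num = p.reorientation_time_s * p.cell_diffusion_um2_s / h_um**2
    sc = p.kinematic_viscosity_m2_s / d_m2_s
    return DimensionlessNumbers(rayleigh=rayleigh, scaled_speed=w, gyrotactic=g_num, schmidt=sc)


def critical_rayleigh_ratio(w_low: float, w_high: float) -> float:
    """Ratio Rc(w_high)/Rc(w_low) from the deep-layer scaling Rc ∝ w⁴."""
    if w_low <= 0 or w_high <= 0:
        raise ParameterError("scaled speeds must be positive")
    return (w_high / w_low) ** 4


def steady_sedimentation_profile(
    p: SuspensionParams, z_um: np.ndarray
) -> np.ndarray:
    """Inverse sedimentation steady state n(z) ∝ exp(v z / D).

    ``z_um`` is measured upward from the compartment bottom. The profile is
    normalized so its column mean equals ``mean_density_per_ml`` (or 1 if
    unspecified), so ∫n dz = n0·h. The 1/e decay length downward from the
    top is D/v; as v → 0 the profile tends to uniform.
    """
    if p.cell_diffusion_um2_s <= 0 or p.depth_mm <= 0:
        raise ParameterError("cell_diffusion_um2_s and depth_mm must be positive")
    z = np.asarray(z_um, dtype=float)
    n0 = p.mean_density_per_ml if p.mean_density_per_ml is not None else 1.0
    h_um = p.depth_mm * 1e3
    k = p.cell_speed_um_s / p.cell_diffusion_um2_s  # 1/µm
    if k * h_um < 1e-12:
        return np.full_like(z, float(n0))
    # column mean of exp(k z) over [0, h] is (exp(k h) - 1)/(k h)
    norm = (np.expm1(k * h_um)) / (k * h_um)
    return n0 * np.exp(k * z) / norm


# ---------------------------------------------------------------------------
# linear stability
# ---------------------------------------------------------------------------


def _base_profile_dimless(w: float, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-normalized exponential base state and its derivative on z∈[0,1]."""
    if w < 1e-12:
        return np.ones_like(z), np.zeros_like(z)
    c = w / np.expm1(w)
    nbar = c * np.exp(w * z)
    return nbar, w * nbar


def _d1_matrix(m: int, dz: float) -> np.ndarray:
    d = np.zeros((m, m))
    for j in range(1, m - 1):
        d[j, j - 1] = -0.5 / dz
        d[j, j + 1] = 0.5 / dz
    # one-sided second order at the ends (used only where needed)
    d[0, :3] = np.array([-1.5, 2.0, -0.5]) / dz
    d[-1, -3:] = np.array([0.5, -2.0, 1.5]) / dz
    return d


def _d2_matrix(m: int, dz: float) -> np.ndarray:
    d = np.zeros((m, m))
    for j in range(1, m - 1):
        d[j, j - 1] = 1.0 / dz**2
        d[j, j] = -2.0 / dz**2
        d[j, j + 1] = 1.0 / dz**2
    return d


def _d4_matrix(m: int, dz: float) -> np.ndarray:
    d = np.zeros((m, m))
    for j in range(2, m - 2):
        d[j, j - 2 : j + 3] = np.array([1.0, -4.0, 6.0, -4.0, 1.0]) / dz**4
    return d


def _growth_rate_dimless(
    q: float,
    rayleigh: float,
    w: float,
    g_num: float,
    schmidt: float,
    n_grid: int = 96,
) -> complex:
    """Leading eigenvalue σ̃ of the linearized system at radian wavenumber q.

    Normal modes ∝ exp(iqx + σt) about the exponential base state; no-slip
    walls for the flow, zero perturbation cell flux at the walls. Returns
    the eigenvalue with the largest real part (units of D/h²).

    The cell perturbation is solved in symmetrized form N = exp(wz/2)·M,
    which turns the advection-diffusion operator −w∂z + ∂z² into the
    self-adjoint ∂z² − w²/4 with Robin walls M' = (w/2)M (closed by
    ghost-point elimination). This keeps the discrete spectrum free of the
    spurious unstable modes that the non-normal form develops on steep
    base states at moderate resolution.
    """
    m = n_grid + 1
    z = np.linspace(0.0, 1.0, m)
    dz = z[1] - z[0]
    nbar, dnbar = _base_profile_dimless(w, z)
    half = np.exp(0.5 * w * z)  # E = diag(e^{wz/2})

    D2 = _d2_matrix(m, dz)
    D4 = _d4_matrix(m, dz)
    I = np.eye(m)
    L2 = D2 - q**2 * I  # (D² - q²) on interior rows
    L4 = D4 - 2 * q**2 * D2 + q**4 * I  # (D² - q²)² on interior rows

    A = np.zeros((2 * m, 2 * m))
    B = np.zeros((2 * m, 2 * m))

    # --- stream-function block (rows 0..m-1), unknown Φ (real form Ψ = iΦ):
    #     (1/Sc) σ (D²-q²)Φ = (D²-q²)²Φ + R q N,  N = E M
    A[0:m, 0:m] = L4
    A[0:m, m : 2 * m] = rayleigh * q * np.diag(half)
    B[0:m, 0:m] = L2 / schmidt
    # no-slip BCs: Φ = 0 and Φ' = 0 at both walls (tau rows)
    for row, bc in ((0, "dirichlet"), (1, "neumann0"), (m - 2, "neumann1"), (m - 1, "dirichlet")):
        A[row, :] = 0.0
        B[row, :] = 0.0
        if bc == "dirichlet":
            A[row, row] = 1.0
        elif bc == "neumann0":
            A[row, 0:3] = np.array([-1.5, 2.0, -0.5]) / dz
        else:
            A[row, m - 3 : m] = np.array([0.5, -2.0, 1.5]) / dz

    # --- cell block (rows m..2m-1), unknown M = E⁻¹N:
    #     σM = E⁻¹[-q n̄' + w q G n̄ (D²-q²)]Φ + [D² - (w²/4 + q²)] M
    gy = 0.0 if not np.isfinite(g_num) else g_num
    coupling = -q * np.diag(dnbar / half) + w * q * gy * np.diag(nbar / half) @ L2
    S = D2 - (0.25 * w**2 + q**2) * I
    # Robin walls via ghost points: M'(0) = (w/2)M(0), M'(1) = (w/2)M(1)
    S[0, :] = 0.0
    S[0, 0] = (-2.0 - w * dz) / dz**2 - (0.25 * w**2 + q**2)
    S[0, 1] = 2.0 / dz**2
    S[-1, :] = 0.0
    S[-1, -1] = (-2.0 + w * dz) / dz**2 - (0.25 * w**2 + q**2)
    S[-1, -2] = 2.0 / dz**2
    coupling[0, :] = 0.0
    coupling[-1, :] = 0.0
    A[m : 2 * m, 0:m] = coupling
    A[m : 2 * m, m : 2 * m] = S
    B[m : 2 * m, m : 2 * m] = I

    vals = scipy.linalg.eigvals(A, B)
    vals = vals[np.isfinite(vals)]
    # discard spurious huge eigenvalues from the tau rows
    vals = vals[np.abs(vals) < 1e8]
    if len(vals) == 0:
        raise RuntimeError(
            "eigenvalue solve returned no finite modes; refine the grid"
        )
    return vals[np.argmax(vals.real)]


def linear_growth_rate(
    q_per_mm: float,
    p: SuspensionParams,
    n_grid: int = 96,
    rayleigh: Optional[float] = None,
) -> complex:
    """Growth rate σ (1/s) of the normal mode with wavenumber ``q_per_mm``.

    ``q_per_mm`` is in cycles per mm, matching the spectral module's
    convention (pattern wavelength λ = 1/q). Requires the reorientation
    time B (the quasi-static orientation closure needs G); ``rayleigh``
    overrides the Rayleigh number computed from ``p`` so stability can be
    scanned at fixed (w, G, Sc).
    """
    if q_per_mm <= 0:
        raise ParameterError("q must be positive")
    if p.reorientation_time_s is None:
        raise ParameterError(
            "linear_growth_rate requires the reorientation time B "
            "(quasi-static orientation closure)"
        )
    nums = compute_dimensionless_numbers(p)
    r = nums.rayleigh if rayleigh is None else rayleigh
    q_dimless = 2 * np.pi * q_per_mm * p.depth_mm
    sigma_dimless = _growth_rate_dimless(
        q_dimless, r, nums.scaled_speed, nums.gyrotactic, nums.schmidt, n_grid
    )
    h_um = p.depth_mm * 1e3
    return sigma_dimless * p.cell_diffusion_um2_s / h_um**2


def _critical_r_at_q(
    q: float, w: float, g_num: float, sc: float, n_grid: int, rtol: float
) -> Optional[float]:
    """Rayleigh number at which Re σ crosses zero for fixed q (dimensionless)."""

    def grows(r: float) -> bool:
        return _growth_rate_dimless(q, r, w, g_num, sc, n_grid).real > 0

    lo, hi = 1.0, 1e10
    if grows(lo):
        lo = 1e-6
        if grows(lo):
            return lo
    if not grows(hi):
        return None
    while hi / lo > 1 + rtol:
        mid = math.sqrt(lo * hi)
        if grows(mid):
            hi = mid
        else:
            lo = mid
    return math.sqrt(lo * hi)


def critical_rayleigh(
    p: SuspensionParams,
    q_band_per_mm: tuple[float, float] = Q_SEARCH_BAND_PER_MM,
    n_q: int = 25,
    n_grid: int = 96,
    rtol: float = 1e-3,
) -> tuple[float, float]:
    """Critical Rayleigh number and critical wavenumber (cycles/mm).

    For each wavenumber in a log-spaced scan band, bisect the Rayleigh
    number at which the leading growth rate crosses zero, then minimize
    over the band. When no mode in the band can be destabilized the
    explicit stable marker ``(inf, nan)`` is returned.
    """
    nums = compute_dimensionless_numbers(p)
    if not np.isfinite(nums.gyrotactic):
        raise ParameterError("critical_rayleigh requires the reorientation time B")
    qs = np.geomspace(q_band_per_mm[0], q_band_per_mm[1], n_q)
    best_r, best_q = np.inf, None
    for q in qs:
        q_dimless = 2 * np.pi * q * p.depth_mm
        rc = _critical_r_at_q(q_dimless, nums.scaled_speed, nums.gyrotactic, nums.schmidt, n_grid, rtol)
        if rc is not None and rc < best_r:
            best_r, best_q = rc, q
    if best_q is None:
        return math.inf, math.nan
    return best_r, best_q


# ---------------------------------------------------------------------------
# nonlinear 2D solver (stream function / vorticity)
# ---------------------------------------------------------------------------


@dataclass
class Fields2D:
    """Continuum state on a uniform grid, periodic in x, walls at z=0,1.

    ``n`` is cell density in units of the mean n0; ``psi`` and ``omega``
    are the dimensionless stream function and vorticity (length scaled by
    the depth h, time by h²/D). ``velocities_um_s`` converts to physical
    units.
    """

    x_um: np.ndarray
    z_um: np.ndarray
    n: np.ndarray  # (nz, nx)
    psi: np.ndarray
    omega: np.ndarray
    time_s: float
    depth_mm: float
    cell_diffusion_um2_s: float

    def velocities_um_s(self) -> tuple[np.ndarray, np.ndarray]:
        """(ux, uz) in µm/s from ψ derivatives (ux = ∂ψ/∂z, uz = −∂ψ/∂x)."""
        h_um = self.depth_mm * 1e3
        nz, nx = self.psi.shape
        dz = 1.0 / (nz - 1)
        dx = (self.x_um[1] - self.x_um[0]) / h_um
        ux = np.gradient(self.psi, dz, axis=0)
        uz = -(np.roll(self.psi, -1, axis=1) - np.roll(self.psi, 1, axis=1)) / (2 * dx)
        scale = self.cell_diffusion_um2_s / h_um
        return ux * scale, uz * scale

    def total_cells(self) -> float:
        return float(self.n.sum())


class _StokesSolver:
    """Quasi-static momentum: Δ²ψ = −R ∂n/∂x, no-slip walls, periodic x.

    At the Schmidt numbers of microbial suspensions (Sc = ν/D ~ 60) the
    viscous relaxation time is far shorter than any cell-transport time, so
    the flow is slaved to the instantaneous buoyancy torque. The biharmonic
    problem is solved spectrally in x and densely in z with ψ = ψ' = 0 at
    both walls (boundary-row treatment).
    """

    def __init__(self, nz: int, nx: int, lx: float):
        self.nz, self.nx = nz, nx
        dz = 1.0 / (nz - 1)
        self.kx = 2 * np.pi * np.fft.rfftfreq(nx, d=lx / nx)
        d2 = _d2_matrix(nz, dz)
        d4 = _d4_matrix(nz, dz)
        eye = np.eye(nz)
        self.inv = np.empty((len(self.kx), nz, nz))
        for i, k in enumerate(self.kx):
            a = d4 - 2 * k**2 * d2 + k**4 * eye
            a[0] = 0.0
            a[0, 0] = 1.0
            a[1] = 0.0
            a[1, 0:3] = np.array([-1.5, 2.0, -0.5]) / dz
            a[-2] = 0.0
            a[-2, -3:] = np.array([0.5, -2.0, 1.5]) / dz
            a[-1] = 0.0
            a[-1, -1] = 1.0
            self.inv[i] = np.linalg.inv(a)

    def solve(self, forcing_x: np.ndarray) -> np.ndarray:
        """ψ from the buoyancy forcing f = −R·n; RHS is ∂f/∂x (spectral)."""
        f_hat = np.fft.rfft(forcing_x, axis=1) * (1j * self.kx)[None, :]
        f_hat[0] = 0.0
        f_hat[1] = 0.0
        f_hat[-2] = 0.0
        f_hat[-1] = 0.0
        psi_hat = np.einsum("kij,jk->ik", self.inv, f_hat)
        return np.fft.irfft(psi_hat, n=self.nx, axis=1)


def _upwind_flux(n_edge_lo: np.ndarray, n_edge_hi: np.ndarray, vel: np.ndarray) -> np.ndarray:
    """First-order upwind advective flux at a face given the two cell values."""
    return np.where(vel > 0, vel * n_edge_lo, vel * n_edge_hi)


def simulate_bioconvection_2d(
    p: SuspensionParams,
    grid: tuple[int, int] = (64, 64),
    aspect: float = 2.0,
    duration_s: float = 100.0,
    dt_dimless: Optional[float] = None,
    seed: int = 0,
    n_snapshots: int = 11,
    rayleigh: Optional[float] = None,
    perturbation: str | tuple = "random",
    perturbation_amplitude: float = 1e-3,
) -> list[Fields2D]:
    """Time-step the nonlinear 2D bioconvection equations.

    Each step: quasi-static Stokes solve Δ²ψ = −R ∂n/∂x with no-slip
    walls (the large-Schmidt limit of the momentum balance — viscous
    relaxation is far faster than cell transport at Sc ~ 60, so the flow
    is slaved to the instantaneous buoyancy torque); vorticity ω = Δψ;
    quasi-static gyrotactic orientation ``px = clip(G·ω, ±1)``; then a
    conservative finite-volume cell update (upwind advection by
    ``u + w p``, central diffusion, no-flux walls, periodic sides).
    Total cell number is conserved to machine precision by construction.

    ``perturbation`` is ``"random"`` or ``("mode", k_index)`` to seed a
    single lateral Fourier mode (for comparison against the linear solver).
    Aborts with ``RuntimeError`` on NaN/blow-up.
    """
    nums = compute_dimensionless_numbers(p)
    r = nums.rayleigh if rayleigh is None else rayleigh
    gy = nums.gyrotactic if np.isfinite(nums.gyrotactic) else 0.0
    w, sc = nums.scaled_speed, nums.schmidt

    nz, nx = grid
    lx = aspect
    dz = 1.0 / (nz - 1)
    dx = lx / nx
    if dt_dimless is None:
        dt_dimless = 0.2 * min(dx, dz) ** 2
    dt = dt_dimless
    h_um = p.depth_mm * 1e3
    t_scale = h_um**2 / p.cell_diffusion_um2_s  # seconds per dimensionless time
    n_steps = max(1, int(round(duration_s / (dt * t_scale))))

    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, 1.0, nz)
    x = (np.arange(nx) + 0.5) * dx
    nbar, _ = _base_profile_dimless(w, z)
    n = np.tile(nbar[:, None], (1, nx))
    if perturbation == "random":
        n = n * (1.0 + perturbation_amplitude * rng.standard_normal(n.shape))
    else:
        _, k_index = perturbation
        n = n * (
            1.0
            + perturbation_amplitude
            * np.cos(2 * np.pi * k_index * x / lx)[None, :]
            * np.sin(np.pi * z)[:, None]
        )
    stokes = _StokesSolver(nz, nx, lx)

    def flow_state(n_now: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        psi = stokes.solve(-r * n_now)
        omega = np.empty_like(psi)
        omega[1:-1] = (psi[2:] - 2 * psi[1:-1] + psi[:-2]) / dz**2
        omega[0] = 2.0 * psi[1] / dz**2  # one-sided ψ_zz at the no-slip walls
        omega[-1] = 2.0 * psi[-2] / dz**2
        omega += (
            np.roll(psi, -1, axis=1) - 2 * psi + np.roll(psi, 1, axis=1)
        ) / dx**2
        return psi, omega

    x_um = x * h_um
    z_um = z * h_um
    snap_every = max(1, n_steps // max(1, n_snapshots - 1))
    out: list[Fields2D] = []

    def snapshot(t_dimless: float, psi: np.ndarray, omega: np.ndarray) -> None:
        out.append(
            Fields2D(
                x_um=x_um.copy(),
                z_um=z_um.copy(),
                n=n.copy(),
                psi=psi.copy(),
                omega=omega.copy(),
                time_s=t_dimless * t_scale,
                depth_mm=p.depth_mm,
                cell_diffusion_um2_s=p.cell_diffusion_um2_s,
            )
        )

    psi, omega = flow_state(n)
    snapshot(0.0, psi, omega)

    for step in range(1, n_steps + 1):
        psi, omega = flow_state(n)
        # velocities at cell nodes
        ux = np.gradient(psi, dz, axis=0)
        uz = -(np.roll(psi, -1, axis=1) - np.roll(psi, 1, axis=1)) / (2 * dx)
        px = np.clip(gy * omega, -1.0, 1.0)
        pz = np.sqrt(1.0 - px**2)

        # --- cell transport, flux form -----------------------------------
        vx = ux + w * px
        vz = uz + w * pz
        # x faces between i and i+1 (periodic)
        vx_face = 0.5 * (vx + np.roll(vx, -1, axis=1))
        fx = _upwind_flux(n, np.roll(n, -1, axis=1), vx_face)
        fx -= (np.roll(n, -1, axis=1) - n) / dx
        div_x = (fx - np.roll(fx, 1, axis=1)) / dx
        # z faces between j and j+1; wall faces carry zero total flux
        vz_face = 0.5 * (vz[:-1] + vz[1:])
        fz = _upwind_flux(n[:-1], n[1:], vz_face)
        fz -= (n[1:] - n[:-1]) / dz
        div_z = np.zeros_like(n)
        div_z[0] = fz[0] / dz
        div_z[1:-1] = (fz[1:] - fz[:-1]) / dz
        div_z[-1] = -fz[-1] / dz
        n = n - dt * (div_x + div_z)

        if not np.isfinite(n).all() or np.abs(n).max() > 1e6:
            raise RuntimeError(
                f"solution blew up at step {step} (t={step*dt*t_scale:.3g} s); "
                "reduce dt or the grid spacing"
            )
        if step % snap_every == 0 or step == n_steps:
            psi_s, omega_s = flow_state(n)
            snapshot(step * dt, psi_s, omega_s)

    return out
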