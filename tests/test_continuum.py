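"""Continuum theory: dimensionless groups, stability, nonlinear plumes."""

import numpy as np
import pytest

from bioconvect import (
    ParameterError,
    SuspensionParams,
    compute_dimensionless_numbers,
    critical_rayleigh,
    critical_rayleigh_ratio,
    linear_growth_rate,
    simulate_bioconvection_2d,
    steady_sedimentation_profile,
)
from bioconvect.continuum_model import _critical_r_at_q, _growth_rate_dimless


def _with(p: SuspensionParams, **changes) -> SuspensionParams:
    from dataclasses import replace

    return replace(p, **changes)


class TestDimensionlessNumbers:
    def test_rayleigh_number_of_3d_experiment(self, suspension_3d):
        nums = compute_dimensionless_numbers(suspension_3d)
        assert round(nums.rayleigh, -1) == 640

    def test_zero_volume_fraction_gives_zero_rayleigh(self, suspension_3d):
        nums = compute_dimensionless_numbers(_with(suspension_3d, volume_fraction=0.0))
        assert nums.rayleigh == 0.0

    @pytest.mark.parametrize("speed, expected", [(92.0, 11.5), (46.0, 5.75)])
    def test_scaled_speed_for_quasi2d_height(self, suspension_quasi2d, speed, expected):
        nums = compute_dimensionless_numbers(
            _with(suspension_quasi2d, cell_speed_um_s=speed)
        )
        assert nums.scaled_speed == pytest.approx(expected, rel=1e-9)

    def test_agrees_with_pure_si_arithmetic(self, suspension_quasi2d):
        """The mixed-unit interface must agree with hand SI evaluation."""
        p = suspension_quasi2d
        h = p.depth_mm * 1e-3
        d = p.cell_diffusion_um2_s * 1e-12
        v = p.cell_speed_um_s * 1e-6
        nums = compute_dimensionless_numbers(p)
        assert nums.rayleigh == pytest.approx(
            p.gravity_m_s2 * p.volume_fraction * p.density_contrast * h**3
            / (p.kinematic_viscosity_m2_s * d)
        )
        assert nums.scaled_speed == pytest.approx(v * h / d)
        assert nums.gyrotactic == pytest.approx(p.reorientation_time_s * d / h**2)
        assert nums.schmidt == pytest.approx(p.kinematic_viscosity_m2_s / d)

    def test_missing_b_marks_gyrotactic_undefined(self, suspension_3d):
        nums = compute_dimensionless_numbers(
            _with(suspension_3d, reorientation_time_s=None)
        )
        assert np.isnan(nums.gyrotactic)
        assert nums.rayleigh > 0


class TestCriticalRayleighRatio:
    def test_printed_speed_pair_gives_factor_15(self):
        assert round(critical_rayleigh_ratio(5.8, 11.5)) == 15

    def test_equal_speeds_give_unity(self):
        assert critical_rayleigh_ratio(3.3, 3.3) == pytest.approx(1.0)

    def test_doubling_gives_sixteen(self):
        assert critical_rayleigh_ratio(1.0, 2.0) == pytest.approx(16.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ParameterError):
            critical_rayleigh_ratio(0.0, 2.0)
        with pytest.raises(ParameterError):
            critical_rayleigh_ratio(1.0, -2.0)


class TestSedimentationProfile:
    def test_decay_length_is_d_over_v(self, suspension_quasi2d):
        z = np.linspace(0, 2000.0, 200)
        n = steady_sedimentation_profile(suspension_quasi2d, z)
        slope = np.polyfit(z, np.log(n), 1)[0]
        assert 1.0 / slope == pytest.approx(1.6e4 / 46.0, rel=1e-6)  # 347.8 µm

    def test_zero_speed_limit_is_uniform(self, suspension_quasi2d):
        z = np.linspace(0, 2000.0, 50)
        n = steady_sedimentation_profile(_with(suspension_quasi2d, cell_speed_um_s=0.0), z)
        assert np.allclose(n, n[0])

    def test_column_mean_normalization(self, suspension_quasi2d):
        p = _with(suspension_quasi2d, mean_density_per_ml=8e7)
        h_um = p.depth_mm * 1e3
        z = np.linspace(0, h_um, 20001)
        n = steady_sedimentation_profile(p, z)
        integral = np.trapezoid(n, z)
        assert integral == pytest.approx(8e7 * h_um, rel=1e-7)


class TestLinearStability:
    def test_no_buoyancy_always_decays(self, suspension_quasi2d):
        for q in (0.2, 0.5, 1.0, 3.0):
            sigma = linear_growth_rate(q, suspension_quasi2d, rayleigh=0.0, n_grid=64)
            assert sigma.real < 0

    def test_growth_rate_crosses_zero_once_in_rayleigh(self, suspension_quasi2d):
        signs = [
            _growth_rate_dimless(2 * np.pi * 0.5 * 2, r, 5.75, 0.012, 62.5, 64).real > 0
            for r in (10.0, 100.0, 500.0, 2000.0, 1e4, 1e5)
        ]
        # once destabilized, stays destabilized (bisection well-posed)
        first_true = signs.index(True)
        assert signs[:first_true] == [False] * first_true
        assert all(signs[first_true:])

    def test_critical_point_self_consistent(self, suspension_quasi2d):
        rc, qc = critical_rayleigh(
            suspension_quasi2d, q_band_per_mm=(0.1, 1.0), n_q=6, n_grid=64, rtol=1e-3
        )
        sigma = linear_growth_rate(qc, suspension_quasi2d, rayleigh=rc, n_grid=64)
        h_um = suspension_quasi2d.depth_mm * 1e3
        scale = suspension_quasi2d.cell_diffusion_um2_s / h_um**2  # D/h², 1/s
        # |σ̃| at the reported critical point is small on the diffusive scale
        assert abs(sigma.real) / scale < 0.5

    def test_critical_rayleigh_increases_with_speed(self):
        """Faster upswimming stabilizes the layer (w = 5.75, 8, 11.5)."""
        rcs = []
        for w, ng in [(5.75, 96), (8.0, 112), (11.5, 144)]:
            rc = min(
                r
                for r in (
                    _critical_r_at_q(2 * np.pi * q * 2, w, 0.012, 62.5, ng, 1e-2)
                    for q in (0.1, 0.2, 0.4, 0.8)
                )
                if r is not None
            )
            rcs.append(rc)
        assert rcs[0] < rcs[1] < rcs[2]

    def test_fastest_mode_matches_observed_pattern_scale(self):
        """At R ≈ 10·Rc and w = 5.75 the fastest wavelength is ~0.6 h.

        For the 2 mm side-view chamber this is ~1.1 mm, the observed
        pattern wavelength scale.
        """
        qs = np.geomspace(2.0, 40.0, 16)
        sigs = [_growth_rate_dimless(q, 5000.0, 5.75, 0.012, 62.5, 128).real for q in qs]
        q_fast = qs[int(np.argmax(sigs))]
        assert max(sigs) > 0
        assert 0.4 < 2 * np.pi / q_fast < 0.8

    def test_missing_b_rejected(self, suspension_quasi2d):
        p = _with(suspension_quasi2d, reorientation_time_s=None)
        with pytest.raises(ParameterError):
            linear_growth_rate(0.5, p)


class TestNonlinearSolver:
    def test_cell_number_conserved_over_1000_steps(self, suspension_quasi2d):
        nz = 32
        dt = 0.2 * (1.0 / (nz - 1)) ** 2
        t_scale = 2000.0**2 / 1.6e4
        snaps = simulate_bioconvection_2d(
            suspension_quasi2d,
            grid=(nz, 32),
            duration_s=1000 * dt * t_scale,
            dt_dimless=dt,
            rayleigh=2300.0,
            seed=0,
            n_snapshots=3,
        )
        totals = [s.total_cells() for s in snaps]
        assert abs(totals[-1] - totals[0]) / totals[0] < 1e-6

    def test_subcritical_perturbation_decays(self, suspension_quasi2d):
        snaps = simulate_bioconvection_2d(
            suspension_quasi2d, grid=(48, 48), duration_s=300.0, rayleigh=230.0,
            perturbation="random", perturbation_amplitude=1e-2, seed=0, n_snapshots=5,
        )
        amp = [float(np.std(s.n - s.n.mean(axis=1, keepdims=True))) for s in snaps]
        assert all(a2 < a1 for a1, a2 in zip(amp[1:-1], amp[2:]))
        assert amp[-1] < 0.1 * amp[1]

    def test_supercritical_plumes_and_gyrotactic_accumulation(self, suspension_quasi2d):
        """Above threshold, plumes form and cells sit in downwelling flow."""
        snaps = simulate_bioconvection_2d(
            suspension_quasi2d, grid=(48, 48), duration_s=300.0, rayleigh=2300.0,
            perturbation="random", perturbation_amplitude=1e-2, seed=0, n_snapshots=4,
        )
        final = snaps[-1]
        lateral_contrast = np.std(final.n - final.n.mean(axis=1, keepdims=True))
        assert lateral_contrast > 0.1  # plumes, not homogeneous
        _, uz = final.velocities_um_s()
        corr = np.corrcoef((final.n - final.n.mean()).ravel(), uz.ravel())[0, 1]
        assert corr < -0.2

    def test_incompressibility_by_construction(self, suspension_quasi2d):
        snaps = simulate_bioconvection_2d(
            suspension_quasi2d, grid=(48, 48), duration_s=50.0, rayleigh=2300.0,
            perturbation="random", perturbation_amplitude=1e-2, seed=1, n_snapshots=2,
        )
        s = snaps[-1]
        ux, uz = s.velocities_um_s()
        dz = s.z_um[1] - s.z_um[0]
        dx = s.x_um[1] - s.x_um[0]
        div = np.gradient(ux, dx, axis=1)[1:-1] + np.gradient(uz, dz, axis=0)[1:-1]
        scale = max(np.abs(ux).max(), np.abs(uz).max()) / min(dx, dz)
        assert np.abs(div).max() < 0.05 * scale
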