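"""Cell detection, trajectory linking, and VACF motility statistics."""

import numpy as np
import pandas as pd
import pytest

from bioconvect import (
    MotilityParams,
    ParameterError,
    TrajectorySet,
    detect_cells,
    fit_motility,
    link_trajectories,
    simulate_run_and_tumble,
    velocity_autocorrelation,
)
from bioconvect.motility import Detections


def _disk_frame(centers, shape=(200, 200), radius=4, bg=200.0, fg=60.0):
    frame = np.full(shape, bg)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r, c in centers:
        frame[(yy - r) ** 2 + (xx - c) ** 2 <= radius**2] = fg
    return frame


class TestDetectCells:
    def test_recall_and_localization_on_rendered_cells(self):
        rng = np.random.default_rng(5)
        centers = []
        while len(centers) < 50:
            r, c = rng.integers(15, 285, 2)
            if all((r - rr) ** 2 + (c - cc) ** 2 > 24**2 for rr, cc in centers):
                centers.append((int(r), int(c)))
        frame = _disk_frame(centers, shape=(300, 300))
        det = detect_cells(frame, pixel_size_um=1.0)
        errors = [
            np.hypot(det.centers_um[:, 0] - c, det.centers_um[:, 1] - r).min()
            for r, c in centers
        ]
        recall = np.mean(np.array(errors) < 2.0)
        assert recall >= 0.98
        assert np.median(errors) < 1.0

    def test_blank_frame_gives_empty_set(self):
        det = detect_cells(np.full((100, 100), 200.0), pixel_size_um=1.0)
        assert det.n == 0

    def test_two_separated_cells_give_two_detections(self):
        frame = _disk_frame([(50, 40), (50, 64)], shape=(100, 100))  # 3 radii apart
        det = detect_cells(frame, pixel_size_um=1.0)
        assert det.n == 2

    def test_subpixel_radius_rejected(self):
        with pytest.raises(ParameterError):
            detect_cells(np.zeros((50, 50)), pixel_size_um=5.0)  # 2.6 µm < 1 px


def _as_detections(traj: TrajectorySet) -> list[Detections]:
    out = []
    for f, g in traj.data.groupby("frame"):
        out.append(
            Detections(
                np.column_stack([g.x_um.to_numpy(), g.z_um.to_numpy()]),
                np.ones(len(g)),
                int(f),
            )
        )
    return out


class TestLinkTrajectories:
    def test_single_slow_cell_yields_one_full_track(self):
        dets = [
            Detections(np.array([[10.0 + 2.0 * f, 20.0]]), np.ones(1), f)
            for f in range(50)
        ]
        traj = link_trajectories(dets, frame_interval_s=0.1)
        assert traj.n_tracks == 1
        assert len(traj.data) == 50

    def test_jump_beyond_cap_splits_track(self):
        positions = [10.0, 12.0, 14.0, 24.0, 26.0]  # 10 µm jump at frame 3
        dets = [
            Detections(np.array([[x, 50.0]]), np.ones(1), f)
            for f, x in enumerate(positions)
        ]
        traj = link_trajectories(dets, frame_interval_s=0.1, max_disp_um=7.0)
        assert traj.n_tracks == 2

    def test_parallel_cells_never_swap(self):
        dets = []
        for f in range(100):
            x = 10.0 + 1.5 * f
            dets.append(
                Detections(
                    np.array([[x, 40.0], [x, 60.0]]), np.ones(2), f  # 20 µm apart
                )
            )
        traj = link_trajectories(dets, frame_interval_s=1 / 30)
        assert traj.n_tracks == 2
        for _, g in traj.iter_tracks():
            assert g.z_um.nunique() == 1  # each track stays on its own line

    def test_every_detection_in_exactly_one_track(self):
        rng = np.random.default_rng(0)
        traj_in = simulate_run_and_tumble(
            MotilityParams(speed_um_s=46.0, tumble_rate_per_s=1 / 15),
            None, 80, 5.0, seed=13,
        )
        linked = link_trajectories(_as_detections(traj_in), frame_interval_s=1 / 30)
        n_detections = len(traj_in.data)
        assert len(linked.data) == n_detections
        assert not linked.data.duplicated(["frame", "x_um", "z_um"]).any()


class TestVelocityAutocorrelation:
    def test_constant_velocity_track_gives_flat_cv(self):
        t = np.arange(100)
        df = pd.DataFrame(
            {
                "track_id": 0,
                "frame": t,
                "time_s": t * 0.1,
                "x_um": 3.0 * t,
                "z_um": 4.0 * t,
            }
        )
        traj = TrajectorySet(df, frame_interval_s=0.1)
        lags, cv = velocity_autocorrelation(traj)
        speed = 50.0  # |(3,4)|/0.1
        assert np.allclose(cv, speed**2, rtol=1e-9)

    def test_cv_zero_equals_mean_squared_speed(self, rt_ensemble):
        lags, cv = velocity_autocorrelation(rt_ensemble, max_lag_s=10.0)
        dt = rt_ensemble.frame_interval_s
        sq = []
        for _, g in rt_ensemble.iter_tracks():
            v = np.diff(np.column_stack([g.x_um, g.z_um]), axis=0) / dt
            sq.append((v**2).sum(axis=1))
        assert cv[0] == pytest.approx(np.concatenate(sq).mean(), rel=1e-9)

    def test_shuffled_frames_destroy_correlation(self, rt_ensemble):
        rng = np.random.default_rng(0)
        shuffled = rt_ensemble.data.copy()
        perm = shuffled.groupby("track_id", group_keys=False).apply(
            lambda g: g.assign(
                x_um=g.x_um.to_numpy()[rng.permutation(len(g))],
                z_um=g.z_um.to_numpy()[rng.permutation(len(g))],
            ),
            include_groups=False,
        )
        perm["track_id"] = shuffled["track_id"].to_numpy()
        traj = TrajectorySet(perm, rt_ensemble.frame_interval_s)
        lags, cv = velocity_autocorrelation(traj, max_lag_s=10.0)
        assert np.abs(cv[5:]).max() < 0.05 * cv[0]

    def test_rigid_translation_invariance(self, rt_ensemble):
        moved = rt_ensemble.data.copy()
        moved["x_um"] += 1234.5
        moved["z_um"] -= 987.6
        traj = TrajectorySet(moved, rt_ensemble.frame_interval_s)
        _, cv_a = velocity_autocorrelation(rt_ensemble, max_lag_s=10.0)
        _, cv_b = velocity_autocorrelation(traj, max_lag_s=10.0)
        assert np.allclose(cv_a, cv_b, rtol=1e-9)

    def test_coordinate_scaling_scales_speed_linearly(self, rt_ensemble):
        scaled = rt_ensemble.data.copy()
        scaled[["x_um", "z_um"]] *= 2.0
        traj = TrajectorySet(scaled, rt_ensemble.frame_interval_s)
        lags, cv = velocity_autocorrelation(traj, max_lag_s=10.0)
        stats = fit_motility(lags, cv)
        lags0, cv0 = velocity_autocorrelation(rt_ensemble, max_lag_s=10.0)
        stats0 = fit_motility(lags0, cv0)
        assert stats.rms_speed_um_s == pytest.approx(2 * stats0.rms_speed_um_s, rel=1e-6)

    def test_truncated_lag_grid_warns(self, rt_ensemble):
        with pytest.warns(UserWarning):
            lags, _ = velocity_autocorrelation(rt_ensemble, max_lag_s=1000.0)
        assert lags[-1] < 1000.0


class TestFitMotility:
    @pytest.mark.parametrize(
        "v, tau, expected_d",
        [(46.0, 15.0, 1.587e4), (92.0, 2.4, 1.016e4)],
    )
    def test_closed_form_diffusion_from_printed_motility(self, v, tau, expected_d):
        lags = np.linspace(0, 3 * tau, 200)
        cv = v**2 * np.exp(-lags / tau)
        stats = fit_motility(lags, cv)
        assert stats.rms_speed_um_s == pytest.approx(v, rel=1e-6)
        assert stats.correlation_time_s == pytest.approx(tau, rel=1e-6)
        assert stats.diffusion_um2_s == pytest.approx(expected_d, rel=5e-3)

    def test_green_kubo_integral_matches_closed_form(self):
        v, tau = 46.0, 15.0
        lags = np.linspace(0, 12 * tau, 4000)  # long tail for the quadrature
        cv = v**2 * np.exp(-lags / tau)
        stats = fit_motility(lags, cv)
        assert stats.diffusion_greenkubo_um2_s == pytest.approx(
            v**2 * tau / 2, rel=0.01
        )
        assert not stats.discrepancy_flagged

    def test_non_decaying_cv_marks_tau_lower_bound(self):
        lags = np.linspace(0, 10, 50)
        cv = np.full(50, 100.0)
        stats = fit_motility(lags, cv)
        assert stats.tau_lower_bound

    def test_parameter_recovery_grid(self):
        """Bias < 5% in speed, < 15% in correlation time across a 3×3 grid."""
        for u in (30.0, 46.0, 92.0):
            for tau in (2.4, 8.0, 15.0):
                traj = simulate_run_and_tumble(
                    MotilityParams(speed_um_s=u, tumble_rate_per_s=1.0 / tau),
                    None, 1500, 60.0, dt_s=1.0 / 30.0,
                    seed=int(u * 100 + tau * 10),
                )
                lags, cv = velocity_autocorrelation(traj, max_lag_s=min(3 * tau, 45.0))
                stats = fit_motility(lags, cv, n_tracks=1500)
                assert abs(stats.rms_speed_um_s - u) / u < 0.05
                assert abs(stats.correlation_time_s - tau) / tau < 0.15
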