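"""Single-cell motility: detection, tracking, and velocity statistics.

The motility assay records swimming cells in a thin (quasi-2D) chamber.
Cells appear as rings/disks a few µm across and are detected with a
circular Hough transform over a physiological radius range (2.6–5.5 µm
by default), then linked frame-to-frame into trajectories by minimum
total displacement with a hard per-link cap (7 µm by default — the
maximum plausible displacement at video rate).

Motility is quantified by the velocity autocorrelation function

    Cv(t) = ⟨v_i(0) · v_i(t)⟩,

pooled over all cells and, assuming stationarity, over all time origins
within each track (sample-weighted). For run-and-tumble motion Cv decays
exponentially, ``Cv = v² exp(−t/τc)``, where v is the RMS speed and τc
the velocity correlation time; the diffusion constant follows either in
closed form, ``D = v²τc/d`` with d = 2, or from the Green–Kubo integral
``D = (1/d)∫Cv dt`` — both are computed and compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.fft import irfft, next_fast_len, rfft
from scipy.optimize import curve_fit, linear_sum_assignment
from scipy.spatial.distance import cdist
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .core import ParameterError, TrajectorySet

__all__ = [
    "Detections",
    "MotilityStats",
    "detect_cells",
    "link_trajectories",
    "velocity_autocorrelation",
    "fit_motility",
]

#: Hough radius search range, µm
DEFAULT_RADIUS_RANGE_UM = (2.6, 5.5)
#: maximum frame-to-frame displacement for linking, µm
DEFAULT_MAX_DISP_UM = 7.0
#: normalized accumulator threshold for accepting a detection
HOUGH_SCORE_THRESHOLD = 0.35


@dataclass
class Detections:
    """Cell centers detected in one frame, with accumulator scores."""

    centers_um: np.ndarray  # (n, 2): x, y in µm
    scores: np.ndarray
    frame_index: int = 0

    @property
    def n(self) -> int:
        return len(self.centers_um)


@dataclass
class MotilityStats:
    """Fitted motility parameters and the VACF they came from."""

    lags_s: np.ndarray
    cv_um2_s2: np.ndarray
    rms_speed_um_s: float
    correlation_time_s: float
    diffusion_um2_s: float  # closed form v²τc/d
    diffusion_greenkubo_um2_s: float
    n_tracks: int
    dimensionality: int = 2
    tau_lower_bound: bool = False  # Cv did not decay within the lag window

    @property
    def discrepancy_flagged(self) -> bool:
        """True when the two diffusion estimates disagree by more than 10%."""
        if self.diffusion_um2_s == 0:
            return True
        return (
            abs(self.diffusion_greenkubo_um2_s - self.diffusion_um2_s)
            / self.diffusion_um2_s
            > 0.10
        )


def detect_cells(
    frame: np.ndarray,
    pixel_size_um: float,
    radius_range_um: tuple[float, float] = DEFAULT_RADIUS_RANGE_UM,
    max_cells: int = 5000,
    score_threshold: float = HOUGH_SCORE_THRESHOLD,
    frame_index: int = 0,
) -> Detections:
    """Detect cells in one frame with the circular Hough transform.

    The accumulator is evaluated over the radius range (converted to
    pixels), peaks are non-maximum suppressed to at least 1 px separation
    and thresholded on the normalized accumulator score.
    """
    r_lo = radius_range_um[0] / pixel_size_um
    r_hi = radius_range_um[1] / pixel_size_um
    if r_lo < 1.0:
        raise ParameterError(
            f"minimum radius {radius_range_um[0]} µm is below 1 px at "
            f"{pixel_size_um} µm/px"
        )
    frame = np.asarray(frame, dtype=float)
    span = np.ptp(frame)
    norm = (frame - frame.min()) / span if span > 0 else np.zeros_like(frame)
    edges = canny(norm, sigma=1.0)
    if not edges.any():
        return Detections(np.empty((0, 2)), np.empty(0), frame_index)
    radii_px = np.arange(int(np.floor(r_lo)), int(np.ceil(r_hi)) + 1)
    radii_px = radii_px[radii_px >= 1]
    accum = hough_circle(edges, radii_px)
    scores, cx, cy, _ = hough_circle_peaks(
        accum,
        radii_px,
        min_xdistance=max(1, int(r_lo)),
        min_ydistance=max(1, int(r_lo)),
        threshold=score_threshold,
        total_num_peaks=max_cells,
    )
    centers = np.column_stack([cx, cy]).astype(float) * pixel_size_um
    return Detections(centers, np.asarray(scores, dtype=float), frame_index)


def link_trajectories(
    detections: Sequence[Detections],
    frame_interval_s: float,
    max_disp_um: float = DEFAULT_MAX_DISP_UM,
) -> TrajectorySet:
    """Link per-frame detections into trajectories.

    Frame-to-frame assignment minimizes total displacement (Hungarian
    algorithm) subject to a hard per-link cap ``max_disp_um``; links that
    would exceed the cap are cut, ending the track, and unmatched
    detections start new tracks. Every detection belongs to exactly one
    track.
    """
    if len(detections) < 2:
        raise ParameterError("need at least two frames of detections to link")
    big = 1e9
    next_track = 0
    rows: list[tuple] = []
    active: dict[int, np.ndarray] = {}  # track_id -> last position

    first = detections[0]
    for i in range(first.n):
        active[next_track] = first.centers_um[i]
        rows.append((next_track, 0, first.centers_um[i]))
        next_track += 1

    for fi in range(1, len(detections)):
        det = detections[fi]
        prev_ids = list(active.keys())
        new_active: dict[int, np.ndarray] = {}
        matched = np.zeros(det.n, dtype=bool)
        if prev_ids and det.n:
            prev_pos = np.stack([active[t] for t in prev_ids])
            cost = cdist(prev_pos, det.centers_um)
            np.putmask(cost, cost > max_disp_um, big)
            ri, ci = linear_sum_assignment(cost)
            for r, c in zip(ri, ci):
                if cost[r, c] < big:
                    tid = prev_ids[r]
                    new_active[tid] = det.centers_um[c]
                    rows.append((tid, fi, det.centers_um[c]))
                    matched[c] = True
        for c in np.nonzero(~matched)[0]:
            new_active[next_track] = det.centers_um[c]
            rows.append((next_track, fi, det.centers_um[c]))
            next_track += 1
        active = new_active

    df = pd.DataFrame(
        {
            "track_id": [r[0] for r in rows],
            "frame": [r[1] for r in rows],
            "time_s": [r[1] * frame_interval_s for r in rows],
            "x_um": [r[2][0] for r in rows],
            "z_um": [r[2][1] for r in rows],
        }
    ).sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    return TrajectorySet(df, frame_interval_s=frame_interval_s)


def velocity_autocorrelation(
    traj: TrajectorySet,
    max_lag_s: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample-weighted velocity autocorrelation Cv(t) over all tracks.

    Velocities are frame-to-frame displacements divided by the frame
    interval. The correlation pools every (origin, origin+lag) pair within
    every track (stationarity assumed), weighting each sample equally, so
    ``Cv(0)`` is exactly the mean squared speed of all velocity samples.
    FFT-based, so cost is O(T log T) per track.

    Returns ``(lags_s, cv)``; the lag grid is truncated (with a warning)
    when no track is long enough for ``max_lag_s``.
    """
    dt = traj.frame_interval_s
    vel_arrays: list[np.ndarray] = []
    for _, g in traj.iter_tracks():
        if len(g) < 2:
            continue
        # velocities only between consecutive frames
        f = g["frame"].to_numpy()
        x = g["x_um"].to_numpy()
        z = g["z_um"].to_numpy()
        consec = np.diff(f) == 1
        if not consec.all():
            # split at gaps
            breaks = np.nonzero(~consec)[0] + 1
            segments = np.split(np.column_stack([x, z]), breaks)
        else:
            segments = [np.column_stack([x, z])]
        for seg in segments:
            if len(seg) >= 2:
                vel_arrays.append(np.diff(seg, axis=0) / dt)
    if not vel_arrays:
        raise ParameterError("no track with at least two frames")

    max_len = max(len(v) for v in vel_arrays)
    n_lag = max_len
    if max_lag_s is not None:
        want = int(round(max_lag_s / dt)) + 1
        if want > max_len:
            warnings.warn(
                f"no track supports lags up to {max_lag_s} s; truncating to "
                f"{(max_len - 1) * dt:.3g} s"
            )
        n_lag = min(want, max_len)

    nfft = next_fast_len(2 * max_len)
    power = np.zeros(nfft // 2 + 1)
    counts = np.zeros(n_lag)
    for v in vel_arrays:
        fx = rfft(v[:, 0], nfft)
        fz = rfft(v[:, 1], nfft)
        power += np.abs(fx) ** 2 + np.abs(fz) ** 2
        ln = len(v)
        lag_max = min(n_lag, ln)
        counts[:lag_max] += ln - np.arange(lag_max)
    acf = irfft(power, nfft)[:n_lag]
    cv = acf / counts
    lags = np.arange(n_lag) * dt
    return lags, cv


def fit_motility(
    lags_s: np.ndarray,
    cv: np.ndarray,
    n_tracks: int = 0,
    dimensionality: int = 2,
) -> MotilityStats:
    """Fit ``Cv = v² exp(−t/τc)`` and derive the diffusion constant.

    The fit window is restricted to lags ≤ 3× an initial τc guess from
    the 1/e crossing (uniform weights). D is reported two ways: the
    closed form ``v²τc/d`` and the Green–Kubo trapezoid of the measured
    Cv; a relative discrepancy above 10% sets ``discrepancy_flagged``.
    A Cv that never decays below 1/e marks τc as a lower bound.
    """
    lags_s = np.asarray(lags_s, dtype=float)
    cv = np.asarray(cv, dtype=float)
    if cv[0] <= 0:
        raise ParameterError("Cv(0) must be positive")
    below = np.nonzero(cv < cv[0] / np.e)[0]
    tau_lb = len(below) == 0
    tau_guess = lags_s[below[0]] if not tau_lb else lags_s[-1]
    if tau_guess == 0:
        tau_guess = lags_s[1] if len(lags_s) > 1 else 1.0
    window = lags_s <= 3.0 * tau_guess

    def model(t, v2, tau):
        return v2 * np.exp(-t / tau)

    (v2, tau), _ = curve_fit(
        model,
        lags_s[window],
        cv[window],
        p0=(cv[0], tau_guess),
        maxfev=10000,
    )
    v = float(np.sqrt(abs(v2)))
    d_closed = abs(v2) * tau / dimensionality
    d_gk = float(np.trapezoid(cv, lags_s)) / dimensionality
    return MotilityStats(
        lags_s=lags_s,
        cv_um2_s2=cv,
        rms_speed_um_s=v,
        correlation_time_s=float(tau),
        diffusion_um2_s=float(d_closed),
        diffusion_greenkubo_um2_s=d_gk,
        n_tracks=n_tracks,
        dimensionality=dimensionality,
        tau_lower_bound=tau_lb,
    )
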