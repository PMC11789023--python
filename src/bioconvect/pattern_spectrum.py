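"""Spectral quantification of bioconvection patterns.

The morphology of a pattern-forming suspension is characterized by the
power spectrum of its transmitted-light images. Each frame ``J`` is
multiplied by a Hamming window ``H`` (to limit spectral leakage from the
non-periodic field of view) and Fourier transformed; the spectrum is
normalized by the scalar window gain ``ΣH``:

    S = |F[J·H]| / ΣH.

For top-view (3D-compartment) data the 2D spectrum is azimuthally
averaged, ``S(q, t) = ⟨S(qx, qy, t)⟩_θ``; for side-view (quasi-2D) data
the frames are first averaged over z into a 1D lateral signal and a 1D
Hamming window is used. Wavenumbers are in cycles per mm, so the pattern
wavelength is simply λ = 1/qmax.

The temporal dynamics are read off the spectral peak: ``Smax(t)`` rises
exponentially once the instability sets in, so the onset time ``ton`` is
detected as a sustained exceedance of the pre-onset baseline and the
growth rate ``ω`` is a least-squares slope of ``log Smax`` between onset
and half-saturation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import ImageStack, ParameterError

__all__ = [
    "PowerSpectrumSeries",
    "PatternMetrics",
    "windowed_power_spectrum",
    "extract_wavelength",
    "characterize_dynamics",
]

#: onset rule: baseline mean + K·SD exceeded for M consecutive frames
ONSET_K_SD = 5.0
ONSET_M_CONSECUTIVE = 5
#: number of initial frames used for the baseline statistics
BASELINE_FRAMES = 10
#: peak must exceed this multiple of the median spectrum to count as a pattern
PEAK_PROMINENCE_RATIO = 4.0


@dataclass
class PowerSpectrumSeries:
    """S(q, t) on a strictly increasing q grid (cycles/mm), DC excluded."""

    q_per_mm: np.ndarray
    s_qt: np.ndarray  # (n_frames, n_q)
    times_s: np.ndarray
    mode: str  # azimuthal_2d | column_1d

    def __post_init__(self) -> None:
        if np.any(np.diff(self.q_per_mm) <= 0):
            raise ParameterError("q grid must be strictly increasing")
        if np.any(self.s_qt < 0):
            raise ParameterError("spectral power must be non-negative")

    @property
    def q_bin_width(self) -> float:
        return float(np.median(np.diff(self.q_per_mm)))

    def search_band(self) -> np.ndarray:
        """Boolean mask for the peak-search band.

        Excludes wavenumbers below two cycles per image width (window
        leakage around DC) and above half the Nyquist frequency.
        """
        q_lo = 2.0 * self.q_per_mm[0]
        q_hi = 0.5 * self.q_per_mm[-1]
        return (self.q_per_mm >= q_lo) & (self.q_per_mm <= q_hi)


@dataclass
class PatternMetrics:
    """Wavelength and temporal dynamics of a pattern; λ·qmax = 1 exactly."""

    wavelength_mm: Optional[float]
    qmax_per_mm: Optional[float]
    smax_series: np.ndarray  # (n_frames, 2): time, Smax
    onset_time_s: Optional[float]
    growth_rate_per_s: Optional[float]
    fit_r_squared: Optional[float] = None
    fit_window_s: Optional[tuple] = None

    def as_dict(self) -> dict:
        return {
            "lambda_mm": self.wavelength_mm,
            "qmax_per_mm": self.qmax_per_mm,
            "t_on_s": self.onset_time_s,
            "omega_per_s": self.growth_rate_per_s,
        }


def _hamming_2d(shape: tuple[int, int]) -> np.ndarray:
    return np.outer(np.hamming(shape[0]), np.hamming(shape[1]))


def windowed_power_spectrum(stack: ImageStack, mode: str = "azimuthal_2d") -> PowerSpectrumSeries:
    """Hamming-windowed power spectrum of every frame.

    ``mode="azimuthal_2d"`` computes the 2D spectrum and averages it over
    annuli of constant |q| (top-view geometry); ``mode="column_1d"``
    averages each frame over rows into a lateral 1D signal first
    (side-view geometry). The spectral magnitude is normalized by the
    scalar window gain ΣH; the q axis is in cycles per mm and the DC bin
    is excluded.

    The per-frame mean intensity is subtracted before windowing: the DC
    pedestal (incident intensity) otherwise leaks through the window
    sidelobes into the low-q bins and can swamp the noise floor there.
    The pattern content of the spectrum is unchanged.
    """
    if mode not in ("azimuthal_2d", "column_1d"):
        raise ParameterError(f"unknown spectrum mode {mode!r}")
    frames = stack.frames.astype(float)
    n_t, nz, nx = frames.shape
    px_mm = stack.pixel_size_um / 1000.0

    if mode == "column_1d" and nz == nx:
        warnings.warn("column_1d mode on square (top-view-like) frames")

    if mode == "azimuthal_2d":
        window = _hamming_2d((nz, nx))
        gain = window.sum()
        qx = np.fft.fftfreq(nx, d=px_mm)
        qz = np.fft.fftfreq(nz, d=px_mm)
        qr = np.hypot(qz[:, None], qx[None, :])
        # annulus width = fundamental of the larger image dimension
        dq = 1.0 / (max(nx, nz) * px_mm)
        bins = np.round(qr / dq).astype(int)
        n_bins = bins.max() + 1
        counts = np.bincount(bins.ravel(), minlength=n_bins)
        s_list = np.empty((n_t, n_bins))
        for i in range(n_t):
            spec = np.abs(np.fft.fft2((frames[i] - frames[i].mean()) * window)) / gain
            s_list[i] = np.bincount(bins.ravel(), weights=spec.ravel(), minlength=n_bins) / counts
        q_grid = np.arange(n_bins) * dq
        # drop the DC bin and anything beyond the 1D Nyquist
        keep = (q_grid > 0) & (q_grid <= 0.5 / px_mm)
        return PowerSpectrumSeries(q_grid[keep], s_list[:, keep], stack.times_s, mode)

    window = np.hamming(nx)
    gain = window.sum()
    q_grid = np.fft.rfftfreq(nx, d=px_mm)
    s_list = np.empty((n_t, len(q_grid)))
    for i in range(n_t):
        sig = frames[i].mean(axis=0)
        s_list[i] = np.abs(np.fft.rfft((sig - sig.mean()) * window)) / gain
    keep = q_grid > 0
    return PowerSpectrumSeries(q_grid[keep], s_list[:, keep], stack.times_s, mode)


def extract_wavelength(
    ps: PowerSpectrumSeries,
    frame_range: Optional[tuple[int, int]] = None,
    prominence_ratio: float = PEAK_PROMINENCE_RATIO,
) -> tuple[Optional[float], Optional[float]]:
    """Pattern wavelength from the time-averaged spectral peak.

    Returns ``(λ [mm], qmax [cycles/mm])`` with λ = 1/qmax exactly, or
    ``(None, None)`` when no peak in the search band rises above
    ``prominence_ratio`` times the in-band median (homogeneous state).
    """
    lo, hi = frame_range if frame_range is not None else (0, ps.s_qt.shape[0])
    if hi <= lo:
        raise ParameterError("frame range must contain at least one frame")
    s_mean = ps.s_qt[lo:hi].mean(axis=0)
    band = ps.search_band()
    s_band = s_mean[band]
    q_band = ps.q_per_mm[band]
    baseline = np.median(s_band)
    i_peak = int(np.argmax(s_band))
    if baseline <= 0 or s_band[i_peak] < prominence_ratio * baseline:
        return None, None
    qmax = float(q_band[i_peak])
    return 1.0 / qmax, qmax


def characterize_dynamics(
    ps: PowerSpectrumSeries,
    k_sd: float = ONSET_K_SD,
    m_consecutive: int = ONSET_M_CONSECUTIVE,
    baseline_frames: int = BASELINE_FRAMES,
) -> PatternMetrics:
    """Onset time and exponential growth rate from the Smax(t) series.

    ``Smax(t)`` is the in-band spectral maximum per frame. The onset is
    the first time Smax exceeds (baseline mean + k·SD) for m consecutive
    frames, the baseline being the first ``baseline_frames`` frames. The
    growth rate is the least-squares slope of ``log Smax`` between onset
    and the frame where Smax first reaches half its final plateau (the
    exponential regime, before nonlinear saturation). Both are None for a
    stack that never leaves the homogeneous state.
    """
    if ps.s_qt.shape[0] < 20:
        raise ParameterError("need at least 20 frames to characterize dynamics")
    band = ps.search_band()
    smax = ps.s_qt[:, band].max(axis=1)
    t = ps.times_s
    series = np.column_stack([t, smax])

    nb = min(baseline_frames, len(smax) // 4)
    base_mean = smax[:nb].mean()
    base_sd = smax[:nb].std(ddof=1) if nb > 1 else 0.0
    threshold = base_mean + k_sd * base_sd

    above = smax > threshold
    onset_idx = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= m_consecutive:
            onset_idx = i - m_consecutive + 1
            break
    lam, qmax = extract_wavelength(ps)
    if onset_idx is None:
        return PatternMetrics(lam, qmax, series, None, None)

    plateau = np.median(smax[-max(3, len(smax) // 10) :])
    half = 0.5 * plateau
    end_idx = onset_idx
    while end_idx < len(smax) - 1 and smax[end_idx] < half:
        end_idx += 1
    t_on = float(t[onset_idx])
    if end_idx - onset_idx < 2:
        return PatternMetrics(lam, qmax, series, t_on, None)

    tw = t[onset_idx : end_idx + 1]
    yw = np.log(smax[onset_idx : end_idx + 1])
    slope, intercept = np.polyfit(tw, yw, 1)
    resid = yw - (slope * tw + intercept)
    ss_tot = np.sum((yw - yw.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return PatternMetrics(
        lam,
        qmax,
        series,
        t_on,
        float(slope),
        fit_r_squared=float(r2),
        fit_window_s=(float(tw[0]), float(tw[-1])),
    )
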