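"""Relative cell-density estimation from transmitted-light images.

Beer–Lambert attenuation relates the transmitted intensity ``IT`` to the
column density of absorbing cells, ``n = -α log(IT/I0)``. Neither the
attenuation constant ``α`` (path length × attenuation coefficient) nor
the incident intensity ``I0`` needs to be known: subtracting the
area-mean of the log-intensity cancels both and yields the relative
density in units of α,

    (n - n0)/α = ⟨log IT⟩ - log IT,

which is exactly zero-mean over the analysis mask by construction and
invariant under any global intensity rescaling. Natural logarithms are
used throughout; α absorbs the base choice.

Side-view (quasi-2D) image series are reduced to vertical profiles by
row-averaging, and an exponential fit to the reconstructed density
recovers the inverse-sedimentation decay length D/v.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import ParameterError

__all__ = [
    "RelativeDensityMap",
    "relative_density_map",
    "vertical_profile",
    "fit_sedimentation_length",
]

#: quantized zero pixels are clipped to this count value before the log
ZERO_CLIP_COUNTS = 0.5


@dataclass
class RelativeDensityMap:
    """(n − n0)/α map on the source pixel grid; zero-mean over the mask."""

    values: np.ndarray
    mask: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ParameterError("mask shape must match the frame shape")
        masked_mean = self.values[self.mask].mean()
        if abs(masked_mean) > 1e-9:
            raise ParameterError("relative density map must be zero-mean over the mask")


def relative_density_map(
    frame: np.ndarray,
    mask: Optional[np.ndarray] = None,
    frame_index: int = 0,
) -> RelativeDensityMap:
    """Relative cell density (n − n0)/α = ⟨log IT⟩ − log IT.

    Pixels quantized to zero are clipped to 0.5 counts (with a warning);
    genuinely negative intensities raise, naming the pixel count affected.
    """
    frame = np.asarray(frame, dtype=float)
    if mask is None:
        mask = np.ones(frame.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.shape:
        raise ParameterError("mask shape must match the frame shape")
    n_negative = int(np.sum(frame[mask] < 0))
    if n_negative:
        raise ParameterError(
            f"{n_negative} masked pixel(s) have negative intensity; "
            "cannot take the logarithm"
        )
    n_zero = int(np.sum(frame[mask] == 0))
    work = frame.copy()
    if n_zero:
        warnings.warn(
            f"{n_zero} masked pixel(s) at zero counts clipped to {ZERO_CLIP_COUNTS}"
        )
        work[work == 0] = ZERO_CLIP_COUNTS
    log_it = np.zeros_like(work)
    log_it[mask] = np.log(work[mask])
    values = np.zeros_like(work)
    values[mask] = log_it[mask].mean() - log_it[mask]
    return RelativeDensityMap(values=values, mask=mask, frame_index=frame_index)


def vertical_profile(
    maps: list[RelativeDensityMap],
    pixel_size_um: float,
) -> pd.DataFrame:
    """Row-wise mean relative density vs height (side-view geometry).

    Averages over the mask within each row and over all supplied frames.
    Returns a DataFrame with columns ``z_um`` (measured up from the
    compartment bottom, i.e. the last image row) and ``rel_density``.
    The profile mean over z is zero up to row-population weighting.
    """
    if not maps:
        raise ParameterError("need at least one map")
    n_rows = maps[0].values.shape[0]
    acc = np.zeros(n_rows)
    cnt = np.zeros(n_rows)
    for m in maps:
        if m.values.shape[0] != n_rows:
            raise ParameterError("all maps must share the same grid")
        acc += np.where(m.mask, m.values, 0.0).sum(axis=1)
        cnt += m.mask.sum(axis=1)
    if np.any(cnt == 0):
        raise ParameterError("mask leaves empty rows; cannot form a profile")
    mean_rows = acc / cnt
    # image row 0 is the top of the compartment; z is height above the bottom
    z_um = (n_rows - 1 - np.arange(n_rows) + 0.5) * pixel_size_um
    return pd.DataFrame({"z_um": z_um, "rel_density": mean_rows})


def fit_sedimentation_length(
    profile: pd.DataFrame,
    amplitude_scale: float = 1.0,
) -> tuple[float, float]:
    """Exponential decay length [µm] of an inverse sedimentation profile.

    The map value is linear in the true density, ``n = n0 + α·value``;
    with α treated as unit the fit model is ``n0·a·exp(z/L)`` on
    ``1 + value``. Returns ``(L, R²)``; a flat profile returns
    ``(inf, R²)``. A non-monotone profile is fitted anyway — R² is the
    quality flag, no exception is raised.
    """
    z = profile["z_um"].to_numpy(dtype=float)
    v = profile["rel_density"].to_numpy(dtype=float)
    n_like = amplitude_scale + v
    if np.ptp(n_like) < 1e-12 or np.ptp(z) == 0:
        return np.inf, 1.0

    # log-linear seed, then nonlinear refinement on the linear quantity
    pos = n_like > 0
    slope_seed = np.polyfit(z[pos], np.log(n_like[pos]), 1)[0] if pos.sum() > 2 else 1e-4
    if slope_seed == 0:
        slope_seed = 1e-6

    def model(zz, a, k):
        return a * np.exp(k * zz)

    try:
        (a, k), _ = curve_fit(
            model, z, n_like, p0=(np.exp(np.polyfit(z[pos], np.log(n_like[pos]), 1)[1]), slope_seed),
            maxfev=10000,
        )
    except RuntimeError:
        return np.inf, 0.0
    if k == 0:
        return np.inf, 1.0
    resid = n_like - model(z, a, k)
    ss_tot = np.sum((n_like - n_like.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(abs(1.0 / k)), float(r2)
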