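"""Shared data containers and file I/O.

Two containers travel between every stage of the pipeline:

``TrajectorySet``
    Time-stamped 2D positions (and optionally unit orientations) of tracked
    or simulated cells, stored as a tidy :class:`pandas.DataFrame`.

``ImageStack``
    A time series of 2D transmitted-light intensity frames with the physical
    pixel size and frame interval attached.

On disk, trajectories are plain CSV with the canonical column header
``track_id,frame,time_s,x_um,z_um,px,pz`` and stacks are multi-page TIFF
accompanied by a small JSON sidecar carrying ``pixel_size_um`` and
``frame_interval_s``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import tifffile

__all__ = ["TrajectorySet", "ImageStack", "ParameterError"]

#: canonical trajectory CSV columns, in order
TRAJECTORY_COLUMNS = ["track_id", "frame", "time_s", "x_um", "z_um", "px", "pz"]

#: tolerance on |p| - 1 for stored orientations
ORIENTATION_NORM_TOL = 1e-9


class ParameterError(ValueError):
    """Raised when a physical or numerical parameter is invalid."""


@dataclass
class TrajectorySet:
    """Per-cell, time-stamped positions and orientations.

    Parameters
    ----------
    data
        DataFrame with columns ``track_id, frame, time_s, x_um, z_um`` and
        optionally ``px, pz`` (unit orientation components). Frames must be
        strictly increasing within each track.
    frame_interval_s
        Time between consecutive frames, seconds.
    """

    data: pd.DataFrame
    frame_interval_s: float

    def __post_init__(self) -> None:
        required = ["track_id", "frame", "time_s", "x_um", "z_um"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ParameterError(f"trajectory table missing columns {missing}")
        if self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be positive")

    @property
    def has_orientations(self) -> bool:
        return "px" in self.data.columns and "pz" in self.data.columns

    @property
    def n_tracks(self) -> int:
        return int(self.data["track_id"].nunique())

    def validate(self) -> None:
        """Check per-track frame monotonicity and orientation normalization."""
        frames_ok = self.data.groupby("track_id")["frame"].apply(
            lambda f: bool(np.all(np.diff(f.to_numpy()) > 0))
        )
        if not frames_ok.all():
            bad = frames_ok.index[~frames_ok].tolist()
            raise ParameterError(f"non-increasing frames in tracks {bad[:5]}")
        if self.has_orientations:
            norm = self.data["px"] ** 2 + self.data["pz"] ** 2
            finite = norm[np.isfinite(norm)]
            if len(finite) and np.abs(finite - 1.0).max() > ORIENTATION_NORM_TOL:
                raise ParameterError("orientation vectors not unit-normalized")

    def iter_tracks(self) -> Iterator[tuple[int, pd.DataFrame]]:
        yield from self.data.groupby("track_id", sort=True)

    def to_csv(self, path: str | Path) -> None:
        cols = [c for c in TRAJECTORY_COLUMNS if c in self.data.columns]
        self.data[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, frame_interval_s: float) -> "TrajectorySet":
        return cls(pd.read_csv(path), frame_interval_s=frame_interval_s)


@dataclass
class ImageStack:
    """Time series of 2D intensity frames with physical metadata.

    ``frames`` has shape ``(T, H, W)``; the first image axis is z (or y for
    top view) and the second is x, so ``frames[t, i, j]`` maps to physical
    position ``(x, z) = (j, i) * pixel_size_um``.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ParameterError("frames must be a (T, H, W) array")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ParameterError("pixel_size_um and frame_interval_s must be positive")
        if np.any(self.frames < 0):
            raise ParameterError("negative intensities in image stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def to_tiff(self, path: str | Path) -> None:
        """Write a multi-page TIFF plus a ``<path>.json`` metadata sidecar."""
        path = Path(path)
        dtype = np.uint8 if self.bit_depth <= 8 else np.uint16
        tifffile.imwrite(path, np.clip(self.frames, 0, 2**self.bit_depth - 1).astype(dtype))
        sidecar = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "bit_depth": self.bit_depth,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        frames = tifffile.imread(path).astype(float)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            frames,
            pixel_size_um=sidecar["pixel_size_um"],
            frame_interval_s=sidecar["frame_interval_s"],
            bit_depth=sidecar.get("bit_depth", 16),
        )
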