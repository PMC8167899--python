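"""Calibrated multi-dimensional image containers and TIFF I/O.

The central container is :class:`MovieStack`, a 4D ``(t, z, y, x)`` intensity
array with physical voxel sizes (µm) and a frame interval (min).  Movies are
written as plain multi-page TIFF plus a JSON sidecar holding the calibration,
so that round trips through the file system preserve physical units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["MovieStack", "read_movie", "write_movie"]


@dataclass
class MovieStack:
    """A time-lapse z-stack with physical calibration.

    Parameters
    ----------
    data:
        Intensities, axes ``(t, z, y, x)``.
    voxel_size_um:
        Physical voxel size ``(z, y, x)`` in µm; strictly positive.
    frame_interval_min:
        Time between consecutive frames in minutes; strictly positive.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    frame_interval_min: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"movie must be 4D (t,z,y,x); got shape {self.data.shape}")
        vz, vy, vx = self.voxel_size_um
        if not (vz > 0 and vy > 0 and vx > 0):
            raise ValueError(f"voxel sizes must be positive; got {self.voxel_size_um}")
        if not self.frame_interval_min > 0:
            raise ValueError("frame interval must be positive")
        self.voxel_size_um = (float(vz), float(vy), float(vx))
        self.frame_interval_min = float(self.frame_interval_min)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def voxel_to_um(self, zyx_voxels: np.ndarray) -> np.ndarray:
        """Convert ``(..., 3)`` voxel coordinates (z, y, x) to µm."""
        return np.asarray(zyx_voxels, dtype=float) * np.array(self.voxel_size_um)

    def um_to_voxel(self, zyx_um: np.ndarray) -> np.ndarray:
        """Convert ``(..., 3)`` µm coordinates to (fractional) voxels."""
        return np.asarray(zyx_um, dtype=float) / np.array(self.voxel_size_um)

    def copy_with(self, data: np.ndarray) -> "MovieStack":
        return MovieStack(data, self.voxel_size_um, self.frame_interval_min, dict(self.meta))


def write_movie(movie: MovieStack, path: str | Path) -> None:
    """Write a movie as multi-page TIFF with a ``.json`` calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.data, metadata={"axes": "TZYX"})
    sidecar = {
        "voxel_size_um": list(movie.voxel_size_um),
        "frame_interval_min": movie.frame_interval_min,
        "axes": "TZYX",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_movie(path: str | Path) -> MovieStack:
    """Read a movie written by :func:`write_movie` (TIFF + JSON sidecar)."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"calibration sidecar not found: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if data.ndim == 3:  # single frame stored without t axis
        data = data[None]
    return MovieStack(
        data,
        tuple(sidecar["voxel_size_um"]),
        sidecar["frame_interval_min"],
    )
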