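"""Movie drift compensation and fixed-image preprocessing.

Drift handling follows a store-and-restore scheme: the overall displacement
of the embryo is estimated per frame pair by cross-correlation of
maximum-intensity projections, accumulated into a :class:`DriftTable`,
cancelled on the images by uniform integer-voxel shifts before detection,
and finally restored on the detected coordinates so that tracks live in the
original acquisition frame.

The fixed-image chain mirrors the standard ImageJ-style workflow used for
fluorescence quantification: conversion to 8-bit, inversion, sliding-
paraboloid background subtraction, and pooled-stack-histogram thresholding
that keeps the brightest fraction of voxels as signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .stack import MovieStack

__all__ = [
    "DriftTable",
    "estimate_drift",
    "apply_drift",
    "restore_coordinates",
    "to_8bit_inverted",
    "subtract_background_paraboloid",
    "threshold_stack_histogram",
]


@dataclass
class DriftTable:
    """Cumulative per-frame drift in integer voxels.

    ``shifts[t]`` is the estimated cumulative displacement (dz, dy, dx) of
    frame ``t`` relative to frame 0, in voxels; row 0 is always zero.
    Compensation shifts the image content of frame ``t`` by ``-shifts[t]``;
    restoration adds ``shifts[t]`` (in µm) back onto detected coordinates.
    """

    shifts: np.ndarray  # (n_frames, 3) int

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=int)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 3:
            raise ValueError("shifts must have shape (n_frames, 3)")
        if np.any(self.shifts[0] != 0):
            raise ValueError("frame 0 shift must be (0, 0, 0)")

    def __len__(self) -> int:
        return len(self.shifts)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.column_stack([np.arange(len(self)), self.shifts]),
            columns=["frame", "dz", "dy", "dx"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DriftTable":
        df = pd.read_csv(path)
        return cls(df[["dz", "dy", "dx"]].to_numpy())


def _pair_shift(ref: np.ndarray, mov: np.ndarray) -> np.ndarray:
    """Displacement of ``mov`` relative to ``ref`` from phase correlation."""
    if ref.std() == 0 or mov.std() == 0:
        warnings.warn("blank frame encountered during drift estimation; assuming zero shift")
        return np.zeros(ref.ndim)
    # light smoothing plus plain (unnormalized) cross-correlation is more
    # robust to pixel noise than phase normalization for subvoxel steps
    ref = ndimage.gaussian_filter(ref, 1.0)
    mov = ndimage.gaussian_filter(mov, 1.0)
    shift, _, _ = phase_cross_correlation(
        ref, mov, upsample_factor=20, normalization=None
    )
    # the returned shift registers mov onto ref, i.e. minus the displacement
    return -np.asarray(shift)


def estimate_drift(movie: MovieStack) -> DriftTable:
    """Estimate the cumulative overall displacement of each frame.

    The xy shift comes from cross-correlating maximum-intensity z
    projections of consecutive frames and the z shift from y projections;
    per-pair estimates are accumulated over time and rounded to integer
    voxels (frame 0 is the zero reference).
    """
    if movie.n_frames < 2:
        raise ValueError("drift estimation needs at least 2 frames")
    increments = np.zeros((movie.n_frames, 3))
    for t in range(1, movie.n_frames):
        prev, curr = movie.data[t - 1], movie.data[t]
        dyx = _pair_shift(prev.max(axis=0), curr.max(axis=0))
        dzx = _pair_shift(prev.max(axis=1), curr.max(axis=1))
        increments[t] = (dzx[0], dyx[0], dyx[1])
    cumulative = np.cumsum(increments, axis=0)
    return DriftTable(np.round(cumulative).astype(int))


def apply_drift(movie: MovieStack, drift: DriftTable) -> MovieStack:
    """Cancel the estimated drift by uniform integer-voxel frame shifts.

    Each frame is translated by minus its cumulative shift; vacated voxels
    are filled with the modal background intensity of the movie (no
    interpolation, so blob shapes are untouched).
    """
    if len(drift) != movie.n_frames:
        raise ValueError("drift table length must match the frame count")
    shape = np.array(movie.frame_shape)
    if np.any(np.abs(drift.shifts) >= shape):
        raise ValueError("drift shift exceeds the image extent")
    fill = _modal_background(movie.data)
    out = np.empty_like(movie.data)
    for t in range(movie.n_frames):
        out[t] = _shift_frame(movie.data[t], -drift.shifts[t], fill)
    return movie.copy_with(out)


def _modal_background(data: np.ndarray) -> float:
    sample = data[0] if data.ndim == 4 else data
    values, counts = np.unique(np.round(sample).astype(np.int64), return_counts=True)
    return float(values[np.argmax(counts)])


def _shift_frame(frame: np.ndarray, shift: np.ndarray, fill: float) -> np.ndarray:
    out = np.full_like(frame, fill)
    src, dst = [], []
    for axis, s in enumerate(shift):
        n = frame.shape[axis]
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = frame[tuple(src)]
    return out


def restore_coordinates(
    points: pd.DataFrame, drift: DriftTable, voxel_size_um: tuple[float, float, float]
) -> pd.DataFrame:
    """Map coordinates from the drift-compensated frame back to acquisition.

    ``points`` must carry ``frame`` plus ``z_um, y_um, x_um`` columns; the
    cumulative shift cancelled on each frame is re-added in µm.
    """
    if len(points) == 0:
        return points.copy()
    frames = points["frame"].to_numpy().astype(int)
    if frames.min() < 0 or frames.max() >= len(drift):
        raise IndexError("frame index outside the drift table")
    shift_um = drift.shifts[frames] * np.array(voxel_size_um)
    out = points.copy()
    out[["z_um", "y_um", "x_um"]] = (
        points[["z_um", "y_um", "x_um"]].to_numpy() + shift_um
    )
    return out


# ---------------------------------------------------------------------------
# Fixed-image preprocessing


def to_8bit_inverted(image: np.ndarray) -> np.ndarray:
    """Linearly rescale the input range to 0–255 and invert (v → 255 − v).

    A constant image rescales to all zeros and therefore inverts to all 255
    (degenerate but well defined).
    """
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    scaled = np.zeros_like(image) if hi == lo else (image - lo) * (255.0 / (hi - lo))
    return (255.0 - scaled).astype(np.uint8)


def subtract_background_paraboloid(
    image: np.ndarray, radius_px: float = 150.0
) -> np.ndarray:
    """Sliding-paraboloid background subtraction.

    The background is the grayscale opening of the image by a paraboloid
    structuring surface of height ``d²/(2·radius_px)`` at lateral distance
    ``d`` (the ImageJ rolling-ball/paraboloid parameterization): the
    paraboloid is slid under the intensity landscape (erosion) and the
    surface it traces is relaxed upward (dilation).  The opening is computed
    exactly via separable 1D quadratic structuring functions.  Output is the
    image minus its background, clipped at zero.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    image = np.asarray(image, dtype=float)
    if radius_px > max(image.shape):
        warnings.warn(
            "paraboloid radius exceeds the image size; background subtraction "
            "degenerates to constant-offset removal"
        )
    c = 1.0 / (2.0 * radius_px)
    value_range = image.max() - image.min()
    # Truncating the quadratic once it exceeds the value range is exact.
    half = max(int(np.ceil(np.sqrt(max(value_range, 1e-12) / c))), 1)
    k = np.arange(-half, half + 1)
    quad = -c * k.astype(float) ** 2
    bg = image
    for structure in (quad[:, None], quad[None, :]):
        bg = ndimage.grey_erosion(bg, structure=structure, mode="nearest")
    for structure in (quad[:, None], quad[None, :]):
        bg = ndimage.grey_dilation(bg, structure=structure, mode="nearest")
    return np.clip(image - bg, 0.0, None)


def threshold_stack_histogram(
    stack: np.ndarray, signal_fraction: float = 0.03
) -> np.ndarray:
    """Keep the brightest ``signal_fraction`` of voxels, zeroing the rest.

    The threshold is the ``1 − signal_fraction`` quantile of the pooled
    stack histogram; voxels below it are set to 0, voxels at or above it
    keep their value, so mean gray values remain comparable across images.
    """
    if not 0.0 < signal_fraction <= 1.0:
        raise ValueError("signal_fraction must lie in (0, 1]")
    stack = np.asarray(stack, dtype=float)
    threshold = np.quantile(stack, 1.0 - signal_fraction, method="higher")
    out = stack.copy()
    out[stack < threshold] = 0.0
    return out
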