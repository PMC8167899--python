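"""Apical→basal wide-line intensity profiles and nuclear mean-gray levels.

A profile is sampled along a manually defined (or generator-supplied) line
running from 1 µm above the apical membrane to 1 µm below the basal surface
of the mesoderm, averaging intensities across a wide perpendicular band
(default 60 px) so that most of a cell's width contributes while lateral
membranes are excluded.  Cell profiles are averaged per embryo (minimum 10
cells of similar length, ±1 µm) and embryo profiles per condition
(typically 6 embryos).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import profile_line

__all__ = [
    "LineROI",
    "IntensityProfile",
    "sample_line_profile",
    "average_cell_profiles",
    "condition_average",
    "nuclear_mean_gray",
]


@dataclass
class LineROI:
    """A wide sampling line in µm image coordinates (y, x)."""

    start_um: tuple[float, float]
    end_um: tuple[float, float]
    width_px: int = 60
    cell_id: int | str | None = None
    embryo_id: int | str | None = None

    def __post_init__(self) -> None:
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")
        length = float(np.hypot(
            self.end_um[0] - self.start_um[0], self.end_um[1] - self.start_um[1]
        ))
        if length <= 2.0:
            raise ValueError("line must be longer than 2 µm")


@dataclass
class IntensityProfile:
    """Mean gray value vs distance along the apical→basal axis.

    ``distances_um`` starts at 0 (the line start, 1 µm above the apical
    membrane) and increases basally with a uniform step equal to the pixel
    size.
    """

    distances_um: np.ndarray
    mean_gray: np.ndarray
    level: str = "cell"  # cell | embryo | condition
    n: int = 1

    def __post_init__(self) -> None:
        self.distances_um = np.asarray(self.distances_um, dtype=float)
        self.mean_gray = np.asarray(self.mean_gray, dtype=float)
        if self.distances_um.shape != self.mean_gray.shape:
            raise ValueError("distances and values must have the same shape")
        if len(self.distances_um) >= 2 and np.any(np.diff(self.distances_um) <= 0):
            raise ValueError("distances must be strictly increasing")

    @property
    def length_um(self) -> float:
        return float(self.distances_um[-1])

    @property
    def step_um(self) -> float:
        return float(self.distances_um[1] - self.distances_um[0])


def sample_line_profile(
    image: np.ndarray, roi: LineROI, pixel_size_um: float
) -> IntensityProfile:
    """Sample a wide-line profile from a preprocessed image.

    Points are taken every pixel step along the line; at each step the
    intensity is the bilinear-interpolated mean across the perpendicular
    band of ``roi.width_px`` pixels.  The ROI (including its width) must
    lie fully inside the image.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    image = np.asarray(image, dtype=float)
    src = np.asarray(roi.start_um, dtype=float) / pixel_size_um
    dst = np.asarray(roi.end_um, dtype=float) / pixel_size_um
    direction = dst - src
    length = np.linalg.norm(direction)
    perp = np.array([-direction[1], direction[0]]) / length
    half_w = (roi.width_px - 1) / 2.0
    for endpoint in (src, dst):
        for sign in (-1.0, 1.0):
            p = endpoint + sign * half_w * perp
            if not (0 <= p[0] <= image.shape[0] - 1 and 0 <= p[1] <= image.shape[1] - 1):
                raise ValueError("line ROI (with width) extends outside the image")
    values = profile_line(
        image, src, dst, linewidth=roi.width_px, order=1, mode="constant",
        reduce_func=np.mean,
    )
    distances = np.arange(len(values)) * (length / (len(values) - 1)) * pixel_size_um
    return IntensityProfile(distances, values, level="cell", n=1)


def average_cell_profiles(
    cell_profiles: list[IntensityProfile],
    min_cells: int = 10,
    length_tolerance_um: float = 1.0,
) -> IntensityProfile:
    """Average cell profiles of similar length into one embryo profile.

    Profiles whose length deviates from the median by more than
    ``length_tolerance_um`` are dropped with a warning; the survivors are
    linearly rescaled onto the median-length uniform grid and averaged
    pointwise.
    """
    if len(cell_profiles) < min_cells:
        warnings.warn(
            f"only {len(cell_profiles)} cell profiles (expected >= {min_cells})"
        )
    lengths = np.array([p.length_um for p in cell_profiles])
    median_len = float(np.median(lengths))
    admissible = [
        p for p in cell_profiles if abs(p.length_um - median_len) <= length_tolerance_um
    ]
    if len(admissible) < len(cell_profiles):
        warnings.warn(
            f"dropped {len(cell_profiles) - len(admissible)} profiles outside "
            f"±{length_tolerance_um} µm of the median length"
        )
    if len(admissible) < 2:
        raise ValueError("fewer than 2 admissible cell profiles")
    step = float(np.median([p.step_um for p in admissible]))
    grid = np.arange(0.0, median_len + step / 2, step)
    resampled = [
        np.interp(grid, p.distances_um * (median_len / p.length_um), p.mean_gray)
        for p in admissible
    ]
    return IntensityProfile(
        grid, np.mean(resampled, axis=0), level="embryo", n=len(admissible)
    )


def condition_average(
    embryo_profiles: list[IntensityProfile],
) -> IntensityProfile:
    """Pointwise mean of embryo profiles on a common grid.

    The common grid is that of the median-length embryo profile; other
    profiles are linearly interpolated onto it.  At least 2 embryo profiles
    are required (6 is the usual design).
    """
    if len(embryo_profiles) < 2:
        raise ValueError("condition average needs at least 2 embryo profiles")
    lengths = [p.length_um for p in embryo_profiles]
    ref = embryo_profiles[int(np.argsort(lengths)[len(lengths) // 2])]
    grid = ref.distances_um
    resampled = [np.interp(grid, p.distances_um, p.mean_gray) for p in embryo_profiles]
    return IntensityProfile(
        grid, np.mean(resampled, axis=0), level="condition", n=len(embryo_profiles)
    )


def nuclear_mean_gray(
    image: np.ndarray,
    nucleus_rois: list[tuple[float, float, float, float]],
    expected_n: int = 30,
) -> float:
    """Embryo-level nuclear signal: mean over per-nucleus mean intensities.

    ``nucleus_rois`` are axis-aligned elliptical ROIs ``(cy, cx, ry, rx)``
    in pixels (the oval-tool analogue).  The usual design measures 30
    nuclei per embryo; a different count only warns.
    """
    image = np.asarray(image, dtype=float)
    if len(nucleus_rois) != expected_n:
        warnings.warn(
            f"{len(nucleus_rois)} nucleus ROIs (expected {expected_n})"
        )
    yy, xx = np.mgrid[0:image.shape[0], 0:image.shape[1]]
    means = []
    for cy, cx, ry, rx in nucleus_rois:
        mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        if not mask.any():
            raise ValueError(f"empty nucleus ROI at ({cy}, {cx})")
        means.append(image[mask].mean())
    if not means:
        raise ValueError("no nucleus ROIs supplied")
    return float(np.mean(means))
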