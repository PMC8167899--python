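"""Ground-truthed synthetic data generators.

Two generators back the test strategy of the whole package:

``simulate_movie``
    4D movies of fluorescent nuclei from two diameter classes (small
    epithelial-precursor nuclei ~3 µm, large interstitial-precursor nuclei
    ~6 µm) undergoing directed, partially coordinated 3D migration under a
    global embryo drift, rendered as Gaussian blobs with additive noise.

``simulate_epithelium``
    2D cross-sections of a columnar epithelium in which a fluorescence
    marker forms Gaussian peaks of programmable position, amplitude and
    width along the apical→basal axis, over a noisy background.

Both return the rendered image(s) together with an exact ground-truth record
(pre-noise positions, programmed peak parameters), so detection, tracking and
profile measurements can be validated against known answers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stack import MovieStack

__all__ = [
    "MovieSimParams",
    "MovieGroundTruth",
    "EpitheliumSimParams",
    "PeakSpec",
    "EpitheliumGroundTruth",
    "simulate_movie",
    "simulate_epithelium",
]

# FWHM of a Gaussian = 2*sqrt(2 ln 2) * sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _as_pair(value) -> tuple[float, float]:
    """Accept a scalar (applied to both populations) or a (pmec, icp) pair."""
    if np.isscalar(value):
        return float(value), float(value)
    a, b = value
    return float(a), float(b)


@dataclass
class MovieSimParams:
    """Parameters of the synthetic nucleus-migration movie.

    Defaults emulate the acquisition geometry of the live-imaging setup they
    stand in for: 31 frames (60 min at 2-min intervals), 14 z-slices of
    1.5 µm, and ~15 nuclei of each diameter class migrating directionally at
    ~1.2 µm/min under a slow global drift.
    """

    image_shape_voxels: tuple[int, int, int, int] = (31, 14, 256, 256)
    voxel_size_um: tuple[float, float, float] = (1.5, 0.5, 0.5)
    frame_interval_min: float = 2.0
    n_pmec: int = 15
    n_icp: int = 15
    diameter_um_pmec: tuple[float, float] = (3.0, 0.15)  # mean, sd
    diameter_um_icp: tuple[float, float] = (6.0, 0.3)
    speed_um_per_min: float | tuple[float, float] = 1.2
    direction_unit_vector: tuple[float, float, float] = (0.0, 0.30, 0.954)
    coordination_rho: float = 0.8
    step_noise_sd_um: float = 0.2
    global_drift_um_per_frame: tuple[float, float, float] = (0.0, 0.25, 0.25)
    peak_intensity: float = 120.0
    background_level: float = 10.0
    noise_sd: float = 15.0
    min_separation_um: float = 7.0
    intensity_range: tuple[float, float] = (0.0, 255.0)
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coordination_rho <= 1.0:
            raise ValueError("coordination_rho must lie in [0, 1]")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if min(self.image_shape_voxels) <= 0 or min(self.voxel_size_um) <= 0:
            raise ValueError("image shape and voxel sizes must be positive")
        if self.n_pmec < 0 or self.n_icp < 0:
            raise ValueError("cell counts must be non-negative")
        self.image_shape_voxels = tuple(int(v) for v in self.image_shape_voxels)
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        self.global_drift_um_per_frame = tuple(
            float(v) for v in self.global_drift_um_per_frame
        )
        if self.diameter_um_pmec[0] <= 0 or self.diameter_um_icp[0] <= 0:
            raise ValueError("diameters must be positive")
        if self.diameter_um_pmec[0] >= self.diameter_um_icp[0]:
            warnings.warn(
                "PMEC diameter should be smaller than ICP diameter for the "
                "two populations to straddle the classification thresholds"
            )
        u = np.asarray(self.direction_unit_vector, dtype=float)
        norm = np.linalg.norm(u)
        if norm == 0:
            raise ValueError("direction vector must be non-zero")
        self.direction_unit_vector = tuple(u / norm)

    @property
    def field_extent_um(self) -> np.ndarray:
        """Physical (z, y, x) extent of the imaged field in µm."""
        return np.array(self.image_shape_voxels[1:]) * np.array(self.voxel_size_um)


@dataclass
class MovieGroundTruth:
    """Exact per-cell trajectories and global drift of a simulated movie.

    ``cells`` has one row per (cell, frame) with columns
    ``cell_id, cell_type, frame, z_um, y_um, x_um, diameter_um`` where
    positions are pre-noise, continuous, in the acquisition frame (i.e.
    including the global drift).  ``drift`` holds the cumulative drift per
    frame in µm with columns ``frame, dz_um, dy_um, dx_um``.
    """

    cells: pd.DataFrame
    drift: pd.DataFrame
    params: MovieSimParams

    def positions(self, frame: int) -> pd.DataFrame:
        return self.cells[self.cells["frame"] == frame]


def _place_nuclei(
    rng: np.random.Generator,
    n: int,
    lo: np.ndarray,
    hi: np.ndarray,
    existing: list[np.ndarray],
    min_sep: float,
) -> list[np.ndarray]:
    """Rejection-sample nucleus centers with a minimum pairwise separation."""
    placed = list(existing)
    out = []
    for _ in range(n):
        for _attempt in range(2000):
            p = rng.uniform(lo, hi)
            if all(np.linalg.norm(p - q) >= min_sep for q in placed):
                placed.append(p)
                out.append(p)
                break
        else:
            raise RuntimeError(
                "could not place nuclei inside the field at the requested "
                "minimum separation; enlarge the field or reduce counts"
            )
    return out


def _render_blob(
    frame: np.ndarray,
    center_vox: np.ndarray,
    sigma_um: float,
    amplitude: float,
    voxel_size: np.ndarray,
) -> None:
    """Add an isotropic (in µm) Gaussian blob to a (z,y,x) frame in place."""
    half = np.ceil(4.0 * sigma_um / voxel_size).astype(int)
    lo = np.maximum(np.round(center_vox).astype(int) - half, 0)
    hi = np.minimum(np.round(center_vox).astype(int) + half + 1, frame.shape)
    if np.any(lo >= hi):
        return
    zz = (np.arange(lo[0], hi[0]) - center_vox[0]) * voxel_size[0]
    yy = (np.arange(lo[1], hi[1]) - center_vox[1]) * voxel_size[1]
    xx = (np.arange(lo[2], hi[2]) - center_vox[2]) * voxel_size[2]
    r2 = (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    )
    frame[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(
        -r2 / (2.0 * sigma_um**2)
    )


def simulate_movie(params: MovieSimParams) -> tuple[MovieStack, MovieGroundTruth]:
    """Render a ground-truthed 4D nucleus-migration movie.

    Each nucleus is an isotropic 3D Gaussian blob whose FWHM equals its
    diameter (sigma = diameter / (2*sqrt(2 ln 2))), sampled through the
    anisotropic voxel grid.  Per frame, each cell takes a step

        step_i = rho * population_step + (1 - rho) * independent_step_i

    where both step terms are drawn from N(speed*dt*direction,
    step_noise_sd^2 I); the population step is shared within a cell
    population, so the coordination parameter ``rho`` tunes how correlated
    neighbouring trajectories are.  A global drift is added to every cell,
    and noise is added last; ground truth records the exact pre-noise
    positions and the cumulative drift.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_frames = p.image_shape_voxels[0]
    frame_shape = p.image_shape_voxels[1:]
    voxel = np.array(p.voxel_size_um)
    extent = p.field_extent_um
    dt = p.frame_interval_min
    speed = _as_pair(p.speed_um_per_min)
    u = np.asarray(p.direction_unit_vector)

    # cumulative drift, frame 0 = 0
    drift_step = np.asarray(p.global_drift_um_per_frame, dtype=float)
    cum_drift = np.outer(np.arange(n_frames), drift_step)

    # Start box: keep every nucleus inside the field (with a margin for the
    # blob itself) over the whole programmed trajectory.
    margin = 0.75 * max(p.diameter_um_pmec[0], p.diameter_um_icp[0])
    n_steps = n_frames - 1
    slack = 3.0 * p.step_noise_sd_um * np.sqrt(max(n_steps, 1))
    lo = np.full(3, margin) + slack
    hi = extent - margin - slack
    for pop in range(2):
        total = n_steps * speed[pop] * dt * u + cum_drift[-1]
        lo_pop = lo - np.minimum(total, 0.0)
        hi_pop = hi - np.maximum(total, 0.0)
        if np.any(lo_pop >= hi_pop):
            raise ValueError(
                "programmed motion does not fit inside the field: nuclei "
                "would be initialized or driven outside the image"
            )
        if pop == 0:
            lo0, hi0 = lo_pop, hi_pop
        else:
            lo = np.maximum(lo0, lo_pop)
            hi = np.minimum(hi0, hi_pop)
    if np.any(lo >= hi):
        raise ValueError(
            "programmed motion does not fit inside the field: nuclei "
            "would be initialized or driven outside the image"
        )

    centers = _place_nuclei(rng, p.n_pmec, lo, hi, [], p.min_separation_um)
    centers += _place_nuclei(rng, p.n_icp, lo, hi, centers, p.min_separation_um)
    n_cells = p.n_pmec + p.n_icp
    cell_types = ["PMEC"] * p.n_pmec + ["ICP"] * p.n_icp
    diam_mean_sd = [p.diameter_um_pmec] * p.n_pmec + [p.diameter_um_icp] * p.n_icp
    diameters = np.array(
        [max(0.5, rng.normal(m, s)) for (m, s) in diam_mean_sd]
    )

    # trajectories in the embryo frame (drift added afterwards)
    pos = np.empty((n_cells, n_frames, 3))
    pos[:, 0] = np.array(centers)
    pop_index = np.array([0] * p.n_pmec + [1] * p.n_icp)
    for t in range(1, n_frames):
        pop_steps = [
            speed[k] * dt * u + rng.normal(0.0, p.step_noise_sd_um, 3)
            for k in range(2)
        ]
        for i in range(n_cells):
            ind = speed[pop_index[i]] * dt * u + rng.normal(
                0.0, p.step_noise_sd_um, 3
            )
            step = (
                p.coordination_rho * pop_steps[pop_index[i]]
                + (1.0 - p.coordination_rho) * ind
            )
            pos[i, t] = pos[i, t - 1] + step

    acq_pos = pos + cum_drift[None, :, :]

    data = np.empty((n_frames,) + frame_shape, dtype=np.float32)
    sigma_um = diameters / FWHM_PER_SIGMA
    for t in range(n_frames):
        frame = np.full(frame_shape, p.background_level, dtype=np.float64)
        for i in range(n_cells):
            _render_blob(
                frame, acq_pos[i, t] / voxel, sigma_um[i], p.peak_intensity, voxel
            )
        if p.poisson_noise:
            frame = rng.poisson(np.maximum(frame, 0.0)).astype(np.float64)
        if p.noise_sd > 0:
            frame = frame + rng.normal(0.0, p.noise_sd, frame_shape)
        data[t] = np.clip(frame, *p.intensity_range)

    rows = []
    for i in range(n_cells):
        for t in range(n_frames):
            rows.append(
                (i, cell_types[i], t, *acq_pos[i, t], diameters[i])
            )
    cells = pd.DataFrame(
        rows,
        columns=["cell_id", "cell_type", "frame", "z_um", "y_um", "x_um", "diameter_um"],
    )
    drift = pd.DataFrame(
        np.column_stack([np.arange(n_frames), cum_drift]),
        columns=["frame", "dz_um", "dy_um", "dx_um"],
    ).astype({"frame": int})
    movie = MovieStack(data, p.voxel_size_um, p.frame_interval_min)
    return movie, MovieGroundTruth(cells, drift, p)


# ---------------------------------------------------------------------------
# Columnar-epithelium cross-sections


@dataclass
class PeakSpec:
    """One programmed marker peak along the apical→basal axis.

    ``position_um`` is measured along the profile line, whose origin sits
    1 µm above the apical membrane (so the apical membrane is at 1 µm).
    """

    position_um: float
    amplitude: float
    fwhm_um: float

    def __post_init__(self) -> None:
        if self.fwhm_um <= 0:
            raise ValueError("fwhm_um must be positive")
        if not 0 <= self.amplitude <= 255:
            raise ValueError("amplitude must lie in [0, 255]")

    @property
    def sigma_um(self) -> float:
        return self.fwhm_um / FWHM_PER_SIGMA


@dataclass
class EpitheliumSimParams:
    """Parameters of the synthetic polarized-epithelium cross-section."""

    pixel_size_um: float = 0.1
    cell_length_um: float = 15.0
    cell_length_jitter_um: float = 1.0
    n_cells: int = 10
    cell_width_px: int = 80
    peaks: tuple[PeakSpec, ...] = (
        PeakSpec(2.0, 120.0, 1.0),   # apical-like
        PeakSpec(17.0, 100.0, 1.3),  # basal-like (endoderm/mesoderm interface)
    )
    mesoderm_band_um: float = 4.0
    background_level: float = 0.0
    background_gradient: float = 0.0
    noise_sd: float = 2.0
    apical_offset_um: float = 1.0  # line starts this far above the apical membrane
    basal_offset_um: float = 1.0   # and ends this far below the mesoderm
    # Background-only rows below the tissue band, emulating the large empty
    # field of a real micrograph; the pooled-histogram threshold sees them.
    margin_rows_px: int = 0
    seed: int = 0
    # optional separate stream for the pixel noise, so the same geometry can
    # be re-rendered under different noise realizations
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        self.peaks = tuple(
            pk if isinstance(pk, PeakSpec) else PeakSpec(*pk) for pk in self.peaks
        )
        line_max = (
            self.apical_offset_um
            + self.cell_length_um
            + self.mesoderm_band_um
            + self.basal_offset_um
        )
        for pk in self.peaks:
            if not -1.0 <= pk.position_um <= line_max + 1.0:
                raise ValueError(
                    f"peak position {pk.position_um} µm outside the profiled span"
                )

    @property
    def nominal_line_length_um(self) -> float:
        return (
            self.apical_offset_um
            + self.cell_length_um
            + self.mesoderm_band_um
            + self.basal_offset_um
        )


@dataclass
class EpitheliumGroundTruth:
    """Per-cell line ROIs and programmed peak parameters.

    ``lines`` columns: cell_id, x_center_px, y_start_um, y_end_um,
    length_um, cell_length_um.  ``peaks`` columns: cell_id, peak_index,
    position_um, amplitude, fwhm_um (positions after per-cell length jitter).
    """

    lines: pd.DataFrame
    peaks: pd.DataFrame
    params: EpitheliumSimParams


def simulate_epithelium(
    params: EpitheliumSimParams,
) -> tuple[np.ndarray, EpitheliumGroundTruth]:
    """Render a 2D columnar-epithelium cross-section for one marker channel.

    The image rows run along the apical→basal axis (row 0 = 1 µm above the
    apical membrane); columns tile ``n_cells`` side-by-side cell strips.
    Within each strip the marker intensity is laterally uniform and equals a
    sum of Gaussians at the programmed positions plus background.  Cell
    lengths jitter by ±``cell_length_jitter_um``; peak positions inside the
    cell scale with the jittered length, while peaks in the mesoderm band
    shift rigidly with the basal membrane.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    noise_rng = np.random.default_rng(p.seed if p.noise_seed is None else p.noise_seed)
    px = p.pixel_size_um
    L0 = p.cell_length_um
    max_len = p.nominal_line_length_um + p.cell_length_jitter_um
    height = int(np.ceil(max_len / px)) + 2 + p.margin_rows_px
    width = p.n_cells * p.cell_width_px
    image = np.full((height, width), float(p.background_level))
    if p.background_gradient:
        image += p.background_gradient * (
            np.arange(height)[:, None] / max(height - 1, 1)
        )

    y_um = np.arange(height) * px
    line_rows, peak_rows = [], []
    for c in range(p.n_cells):
        jitter = rng.uniform(-p.cell_length_jitter_um, p.cell_length_jitter_um)
        L = L0 + jitter
        apical = p.apical_offset_um
        profile = np.zeros(height)
        for k, pk in enumerate(p.peaks):
            if pk.position_um <= apical + L0:
                # inside the cell: scale position with the jittered length
                pos = apical + (pk.position_um - apical) * (L / L0)
            else:
                # in the mesoderm band: rigid shift with the basal membrane
                pos = pk.position_um + (L - L0)
            profile += pk.amplitude * np.exp(
                -((y_um - pos) ** 2) / (2.0 * pk.sigma_um**2)
            )
            peak_rows.append((c, k, pos, pk.amplitude, pk.fwhm_um))
        x0, x1 = c * p.cell_width_px, (c + 1) * p.cell_width_px
        image[:, x0:x1] += profile[:, None]
        line_len = apical + L + p.mesoderm_band_um + p.basal_offset_um
        line_rows.append((c, (x0 + x1 - 1) / 2.0, 0.0, line_len, line_len, L))

    if p.noise_sd > 0:
        image = image + noise_rng.normal(0.0, p.noise_sd, image.shape)
    image = np.clip(image, 0.0, 255.0)

    gt = EpitheliumGroundTruth(
        lines=pd.DataFrame(
            line_rows,
            columns=[
                "cell_id", "x_center_px", "y_start_um", "y_end_um",
                "length_um", "cell_length_um",
            ],
        ),
        peaks=pd.DataFrame(
            peak_rows,
            columns=["cell_id", "peak_index", "position_um", "amplitude", "fwhm_um"],
        ),
        params=p,
    )
    return image.astype(np.float32), gt
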