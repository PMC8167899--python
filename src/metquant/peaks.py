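"""Windowed peak amplitude and full width at half maximum (FWHM).

Peak height is the maximum of the embryo-level profile inside a window of
the apical→basal axis (by convention 0–10 µm for apical peaks and 10–20 µm
for basal peaks, configurable per marker); FWHM is the width of that peak
at half its maximum height, with the half-level crossings located by linear
interpolation on each flank.  Profiles arrive background-subtracted and
thresholded, so the half-maximum baseline is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiler import IntensityProfile
from .trackstats import significance_stars

__all__ = [
    "PeakMetrics",
    "APICAL_WINDOW_UM",
    "BASAL_WINDOW_UM",
    "peak_amplitude",
    "fwhm",
    "measure_peak",
    "peak_stats",
]

APICAL_WINDOW_UM = (0.0, 10.0)
BASAL_WINDOW_UM = (10.0, 20.0)


@dataclass
class PeakMetrics:
    """Measured peak for one embryo/marker/window."""

    embryo_id: int | str
    marker: str
    window_label: str
    window_um: tuple[float, float]
    amplitude: float
    peak_position_um: float
    fwhm_um: float
    bounded: bool


def _window_slice(profile: IntensityProfile, window_um: tuple[float, float]) -> slice:
    lo, hi = window_um
    if hi <= lo:
        raise ValueError("window bounds must satisfy lo < hi")
    d = profile.distances_um
    if hi < d[0] or lo > d[-1]:
        raise ValueError("window lies outside the profile domain")
    idx = np.nonzero((d >= lo) & (d <= hi))[0]
    if len(idx) == 0:
        raise ValueError("window contains no profile samples")
    return slice(idx[0], idx[-1] + 1)


def peak_amplitude(
    profile: IntensityProfile, window_um: tuple[float, float]
) -> tuple[float, float]:
    """Maximum profile value in the window and its (refined) position.

    The position is refined by a parabolic fit through the maximum and its
    two neighbours.  An all-zero window returns amplitude 0 with NaN
    position (degenerate, flagged to the caller by the NaN).
    """
    sl = _window_slice(profile, window_um)
    d, v = profile.distances_um[sl], profile.mean_gray[sl]
    i = int(np.argmax(v))
    amp = float(v[i])
    if amp == 0.0:
        return 0.0, float("nan")
    pos = float(d[i])
    if 0 < i < len(v) - 1:
        denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
        if denom < 0:
            pos += 0.5 * (v[i - 1] - v[i + 1]) / denom * (d[1] - d[0])
    return amp, pos


def fwhm(
    profile: IntensityProfile, window_um: tuple[float, float]
) -> tuple[float, bool]:
    """Width of the windowed peak at half its maximum height.

    Starting from the peak sample, each flank is searched outward (across
    the whole profile domain, not just the window) for the first crossing
    of ``amplitude / 2``; crossings are located by linear interpolation.
    Returns ``(width, bounded)``; if a flank never descends to the half
    level the peak is unbounded and the width is NaN.
    """
    amp, _ = peak_amplitude(profile, window_um)
    if amp == 0.0:
        return float("nan"), False
    half = amp / 2.0
    sl = _window_slice(profile, window_um)
    d, v = profile.distances_um, profile.mean_gray
    i_peak = sl.start + int(np.argmax(v[sl]))

    def _cross(direction: int) -> float | None:
        i = i_peak
        while 0 <= i + direction < len(v):
            j = i + direction
            if v[j] <= half:
                # linear interpolation between samples i and j
                if v[i] == v[j]:
                    return d[j]
                frac = (v[i] - half) / (v[i] - v[j])
                return d[i] + frac * (d[j] - d[i])
            i = j
        return None

    left = _cross(-1)
    right = _cross(+1)
    if left is None or right is None:
        return float("nan"), False
    return float(right - left), True


def measure_peak(
    profile: IntensityProfile,
    window_um: tuple[float, float],
    embryo_id: int | str = 0,
    marker: str = "",
    window_label: str = "custom",
) -> PeakMetrics:
    """Amplitude, position, and FWHM of the peak in one window."""
    amp, pos = peak_amplitude(profile, window_um)
    width, bounded = fwhm(profile, window_um) if amp > 0 else (float("nan"), False)
    return PeakMetrics(
        embryo_id, marker, window_label, tuple(window_um), amp, pos, width, bounded
    )


def peak_stats(
    per_embryo_metrics: pd.DataFrame,
    control: str,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Mutant-vs-control t tests on per-embryo peak metrics.

    ``per_embryo_metrics`` needs columns ``condition, embryo_id, marker,
    window_label, amplitude, fwhm_um``.  Each (marker, window, metric) of
    every non-control condition is compared with the control by an unpaired
    two-tailed t test; means and SDs are reported for scatter plotting.
    """
    if control not in set(per_embryo_metrics["condition"]):
        raise ValueError(f"control condition {control!r} missing from the table")
    rows = []
    grouped = per_embryo_metrics.groupby(["marker", "window_label"])
    for (marker, window), sub in grouped:
        ctrl = sub[sub["condition"] == control]
        for cond in sub["condition"].unique():
            if cond == control:
                continue
            mut = sub[sub["condition"] == cond]
            for metric in ("amplitude", "fwhm_um"):
                a = mut[metric].dropna().to_numpy()
                b = ctrl[metric].dropna().to_numpy()
                if len(a) < 2 or len(b) < 2:
                    raise ValueError(
                        f"need >= 2 embryos per condition for {marker}/{window}"
                    )
                t, p = stats.ttest_ind(a, b, equal_var=equal_var)
                rows.append(
                    {
                        "marker": marker,
                        "window_label": window,
                        "condition": cond,
                        "control": control,
                        "metric": metric,
                        "mean": float(np.mean(a)),
                        "sd": float(np.std(a, ddof=1)),
                        "control_mean": float(np.mean(b)),
                        "control_sd": float(np.std(b, ddof=1)),
                        "t": float(t),
                        "p": float(p),
                        "stars": significance_stars(float(p)),
                    }
                )
    return pd.DataFrame(rows)
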