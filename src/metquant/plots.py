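"""Figure helpers: profile overlays and per-embryo dot plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .profiler import IntensityProfile

__all__ = ["plot_profiles", "plot_embryo_dots"]


def plot_profiles(
    condition_profile: IntensityProfile,
    embryo_profiles: list[IntensityProfile],
    path: str | Path,
    title: str = "",
) -> None:
    """Embryo means as dashed black lines, condition mean as a solid red line."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for p in embryo_profiles:
        ax.plot(p.distances_um, p.mean_gray, "k--", lw=0.8, alpha=0.6)
    ax.plot(
        condition_profile.distances_um, condition_profile.mean_gray, "r-", lw=1.8
    )
    ax.set_xlabel("distance along apical→basal axis (µm)")
    ax.set_ylabel("mean gray value")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_embryo_dots(
    values_by_condition: dict[str, np.ndarray],
    path: str | Path,
    ylabel: str = "",
    error: str = "sem",
    title: str = "",
) -> None:
    """Scatter of per-embryo values with mean ± SEM (or SD) bars."""
    fig, ax = plt.subplots(figsize=(1.2 * len(values_by_condition) + 1.5, 3.5))
    for i, (label, vals) in enumerate(values_by_condition.items()):
        vals = np.asarray(vals, dtype=float)
        jitter = np.linspace(-0.12, 0.12, len(vals))
        ax.plot(i + jitter, vals, "o", ms=5, color="0.3")
        mean = np.nanmean(vals)
        if error == "sd":
            err = np.nanstd(vals, ddof=1)
        else:
            err = np.nanstd(vals, ddof=1) / np.sqrt(np.sum(~np.isnan(vals)))
        ax.hlines(mean, i - 0.25, i + 0.25, color="k", lw=1.5)
        ax.errorbar(i, mean, yerr=err, fmt="none", ecolor="k", capsize=4)
    ax.set_xticks(range(len(values_by_condition)))
    ax.set_xticklabels(list(values_by_condition), rotation=20)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
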