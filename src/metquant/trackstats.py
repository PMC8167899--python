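"""Migration statistics: velocity, directional persistence, coordination.

Per track:

* instantaneous speed — 3D frame-to-frame displacement over the frame
  interval (µm/min);
* velocity — arithmetic mean of the instantaneous speeds;
* directional persistence — net displacement divided by total path length
  (1 for a straight path, 0 for a closed loop);
* coordination — Pearson correlation between a track's instantaneous
  velocity time series and that of its nearest neighbouring track (nearest
  by first-frame position), with the three vector components stacked so the
  statistic is sensitive to both direction and magnitude.  A mean-cosine
  variant is available for direction-only coordination.

Aggregation follows a two-stage scheme: track metrics are averaged per
embryo and per cell type, and conditions are compared on the embryo means
(unpaired two-tailed t tests, one-way ANOVA across three or more groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .linker import Track

__all__ = [
    "instantaneous_speeds",
    "track_velocity",
    "directional_persistence",
    "coordination",
    "track_metrics",
    "embryo_summary",
    "compare_groups",
    "significance_stars",
    "GroupSummary",
]

METRIC_NAMES = ("velocity_um_per_min", "directional_persistence", "coordination")


def _velocities(track: Track, frame_interval_min: float) -> np.ndarray:
    """(n-1, 3) instantaneous velocity vectors in µm/min."""
    pos = track.positions
    if len(pos) < 2:
        raise ValueError("track must have at least 2 detections")
    return np.diff(pos, axis=0) / frame_interval_min


def instantaneous_speeds(track: Track, frame_interval_min: float) -> np.ndarray:
    """Frame-to-frame 3D speeds in µm/min (one value per frame pair)."""
    return np.linalg.norm(_velocities(track, frame_interval_min), axis=1)


def track_velocity(track: Track, frame_interval_min: float) -> float:
    """Track average velocity: mean of the instantaneous speeds."""
    return float(np.mean(instantaneous_speeds(track, frame_interval_min)))


def directional_persistence(track: Track) -> float:
    """Net displacement over total path length, in [0, 1].

    Undefined (NaN, with a warning) for a track with zero path length.
    """
    pos = track.positions
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    path = steps.sum()
    if path == 0:
        warnings.warn(f"track {track.track_id} has zero path length; persistence undefined")
        return float("nan")
    return float(np.linalg.norm(pos[-1] - pos[0]) / path)


def _nearest_partner(tracks: list[Track], i: int) -> int:
    """Index of the track whose first-frame position is nearest to track i."""
    p0 = tracks[i].detections[0].position
    best, best_d = -1, np.inf
    for j, other in enumerate(tracks):
        if j == i:
            continue
        d = np.linalg.norm(other.detections[0].position - p0)
        # ties broken by lower track_id via strict inequality in id order
        if d < best_d or (d == best_d and other.track_id < tracks[best].track_id):
            best, best_d = j, d
    return best


def coordination(
    tracks: list[Track],
    frame_interval_min: float,
    mode: str = "correlation",
) -> pd.DataFrame:
    """Per-track coordination with the nearest neighbouring track.

    ``mode='correlation'`` (default) stacks the (z, y, x) components of the
    two velocity time series over their common frames and returns their
    Pearson correlation; ``mode='cosine'`` returns the mean frame-wise
    cosine similarity instead.  Tracks whose own velocity series has zero
    variance get NaN with a warning.
    """
    if len(tracks) < 2:
        raise ValueError("coordination needs at least 2 tracks")
    if mode not in ("correlation", "cosine"):
        raise ValueError(f"unknown coordination mode: {mode}")
    rows = []
    for i, tr in enumerate(tracks):
        j = _nearest_partner(tracks, i)
        vi = _velocities(tr, frame_interval_min)
        vj = _velocities(tracks[j], frame_interval_min)
        fi, fj = tr.frames[:-1], tracks[j].frames[:-1]
        common, ii, jj = np.intersect1d(fi, fj, return_indices=True)
        value = float("nan")
        if len(common) >= 2:
            a, b = vi[ii].ravel(), vj[jj].ravel()
            if mode == "correlation":
                if a.std() == 0 or b.std() == 0:
                    warnings.warn(
                        f"track {tr.track_id}: zero-variance velocity series; "
                        "coordination undefined"
                    )
                else:
                    value = float(np.corrcoef(a, b)[0, 1])
            else:
                va, vb = vi[ii], vj[jj]
                na = np.linalg.norm(va, axis=1)
                nb = np.linalg.norm(vb, axis=1)
                ok = (na > 0) & (nb > 0)
                if ok.any():
                    value = float(
                        np.mean(np.sum(va[ok] * vb[ok], axis=1) / (na[ok] * nb[ok]))
                    )
        rows.append((tr.track_id, tracks[j].track_id, value))
    return pd.DataFrame(rows, columns=["track_id", "partner_track_id", "coordination"])


def track_metrics(
    tracks: list[Track],
    frame_interval_min: float,
    coordination_mode: str = "correlation",
) -> pd.DataFrame:
    """Per-track velocity, persistence, and coordination table."""
    coord = (
        coordination(tracks, frame_interval_min, coordination_mode)
        if len(tracks) >= 2
        else pd.DataFrame(columns=["track_id", "partner_track_id", "coordination"])
    )
    rows = []
    for tr in tracks:
        rows.append(
            (
                tr.track_id,
                tr.cell_type,
                track_velocity(tr, frame_interval_min),
                directional_persistence(tr),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["track_id", "cell_type", "velocity_um_per_min", "directional_persistence"],
    )
    return df.merge(coord, on="track_id", how="left")


def embryo_summary(
    metrics: pd.DataFrame, embryo_id: str | int, min_tracks: int = 15
) -> pd.DataFrame:
    """Mean of each metric across one embryo's tracks, per cell type.

    Undefined per-track values are skipped (never treated as zero); the
    number of contributing tracks is reported per cell type.
    """
    if len(metrics) == 0:
        raise ValueError("no track metrics to summarize")
    classified = metrics[metrics["cell_type"].isin(["PMEC", "ICP"])]
    if len(classified) == 0:
        raise ValueError("no classified tracks to summarize")
    rows = []
    for cell_type, sub in classified.groupby("cell_type"):
        if len(sub) < min_tracks:
            warnings.warn(
                f"embryo {embryo_id}: only {len(sub)} {cell_type} tracks "
                f"(expected >= {min_tracks})"
            )
        row = {"embryo_id": embryo_id, "cell_type": cell_type, "n_tracks": len(sub)}
        for name in METRIC_NAMES:
            row[name] = float(sub[name].mean(skipna=True))
        rows.append(row)
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Prism-style stars: p ≤ 0.05 *, ≤ 0.01 **, ≤ 0.001 ***."""
    if np.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class GroupSummary:
    """Per-condition means ± SEM plus pairwise and ANOVA test results."""

    means: pd.DataFrame          # condition, n, mean, sem per metric
    pairwise: pd.DataFrame       # condition vs control: t, p, stars per metric
    anova: pd.DataFrame = field(default_factory=pd.DataFrame)  # metric, F, p

    def to_dict(self) -> dict:
        return {
            "means": self.means.to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
            "anova": self.anova.to_dict(orient="records"),
        }


def compare_groups(
    embryo_values_by_condition: dict[str, pd.DataFrame],
    control: str | None = None,
    metrics: tuple[str, ...] = METRIC_NAMES,
    equal_var: bool = True,
) -> GroupSummary:
    """Compare per-embryo means across conditions.

    Each value of ``embryo_values_by_condition`` is an embryo-level table
    (one row per embryo, columns = metrics; a ``cell_type`` column, if
    present, is compared within cell type).  Mutant conditions are tested
    against ``control`` (default: first condition) with unpaired two-tailed
    t tests (classic equal-variance by default; Welch with
    ``equal_var=False``); with three or more conditions a one-way ANOVA is
    run per metric.
    """
    conditions = list(embryo_values_by_condition)
    if control is None:
        control = conditions[0]
    for cond, df in embryo_values_by_condition.items():
        if df["embryo_id"].nunique() < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 embryos")

    has_celltype = all(
        "cell_type" in df.columns for df in embryo_values_by_condition.values()
    )
    groups = (
        sorted(
            set().union(
                *(df["cell_type"].unique() for df in embryo_values_by_condition.values())
            )
        )
        if has_celltype
        else [None]
    )

    def _values(cond: str, cell_type, metric: str) -> np.ndarray:
        df = embryo_values_by_condition[cond]
        if cell_type is not None:
            df = df[df["cell_type"] == cell_type]
        return df[metric].dropna().to_numpy()

    mean_rows, pair_rows, anova_rows = [], [], []
    for cell_type in groups:
        for metric in metrics:
            samples = {c: _values(c, cell_type, metric) for c in conditions}
            for cond, x in samples.items():
                mean_rows.append(
                    {
                        "condition": cond,
                        "cell_type": cell_type,
                        "metric": metric,
                        "n": len(x),
                        "mean": float(np.mean(x)) if len(x) else float("nan"),
                        "sem": float(stats.sem(x)) if len(x) > 1 else float("nan"),
                    }
                )
            for cond in conditions:
                if cond == control:
                    continue
                t, p = stats.ttest_ind(
                    samples[cond], samples[control], equal_var=equal_var
                )
                pair_rows.append(
                    {
                        "condition": cond,
                        "control": control,
                        "cell_type": cell_type,
                        "metric": metric,
                        "t": float(t),
                        "p": float(p),
                        "stars": significance_stars(float(p)),
                    }
                )
            if len(conditions) >= 3:
                f, p = stats.f_oneway(*(samples[c] for c in conditions))
                anova_rows.append(
                    {
                        "cell_type": cell_type,
                        "metric": metric,
                        "F": float(f),
                        "p": float(p),
                    }
                )
    return GroupSummary(
        pd.DataFrame(mean_rows), pd.DataFrame(pair_rows), pd.DataFrame(anova_rows)
    )
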