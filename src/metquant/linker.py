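"""Frame-to-frame track building, curation, and cell-type classification.

Linking solves, for every consecutive frame pair, a constrained linear
assignment on squared-distance costs in which every detection may instead
"die" (track end) or "be born" (track start) at a cost of
``max_link_dist_um²``; links longer than ``max_link_dist_um`` are forbidden
outright.  There is no gap closing: curation keeps only tracks that span the
whole video, so a missed detection is fatal by construction.  Cell types are
assigned from the per-track median nuclear diameter (small nuclei = PMEC,
large = ICP, in-between = unclassified).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .detect import Detection

__all__ = [
    "Track",
    "link_pair",
    "link_frames",
    "curate_tracks",
    "classify_tracks",
    "tracks_to_dataframe",
    "tracks_from_dataframe",
]

PMEC_MAX_DIAMETER_UM = 3.5
ICP_MIN_DIAMETER_UM = 5.5
DEFAULT_MAX_LINK_DIST_UM = 4.0


@dataclass
class Track:
    """A time-ordered chain of detections with one detection per frame."""

    track_id: int
    detections: list[Detection] = field(default_factory=list)
    cell_type: str = "unclassified"

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections])

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) positions in µm, ordered by frame."""
        return np.array([d.position for d in self.detections])

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame

    @property
    def median_diameter_um(self) -> float:
        if not self.detections:
            return float("nan")
        return float(np.median([d.diameter_um for d in self.detections]))

    def validate(self) -> None:
        frames = self.frames
        if len(frames) and np.any(np.diff(frames) != 1):
            raise ValueError(f"track {self.track_id} has frame gaps")


def link_pair(
    a_positions: np.ndarray,
    b_positions: np.ndarray,
    max_link_dist_um: float,
) -> tuple[list[tuple[int, int]], float]:
    """Optimally link one frame pair; return (links, total cost).

    The total cost is the sum of squared link distances plus
    ``max_link_dist_um²`` for every unlinked source (death) and every
    unlinked target (birth) — the quantity the assignment minimizes.
    """
    a = np.atleast_2d(np.asarray(a_positions, dtype=float))
    b = np.atleast_2d(np.asarray(b_positions, dtype=float))
    n = 0 if a.size == 0 else len(a)
    m = 0 if b.size == 0 else len(b)
    alt = max_link_dist_um**2
    if n == 0 or m == 0:
        return [], (n + m) * alt
    big = (n + m + 1) * alt * 1e6
    cost = np.full((n + m, n + m), big)
    d2 = cdist(a, b, "sqeuclidean")
    d2[d2 > alt] = big
    cost[:n, :m] = d2
    cost[np.arange(n), m + np.arange(n)] = alt          # deaths
    cost[n + np.arange(m), np.arange(m)] = alt          # births
    cost[n:, m:] = 0.0                                  # matched alternatives
    rows, cols = linear_sum_assignment(cost)
    links = [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n and j < m and d2[i, j] <= alt
    ]
    total = sum(d2[i, j] for i, j in links) + (n + m - 2 * len(links)) * alt
    return links, float(total)


def link_frames(
    detections_per_frame: list[list[Detection]],
    max_link_dist_um: float = DEFAULT_MAX_LINK_DIST_UM,
) -> list[Track]:
    """Build tracks by optimal frame-to-frame assignment.

    Unmatched detections in a frame start new tracks; unmatched track ends
    terminate.  Track ids are assigned in order of creation (frame, then
    detection order within the frame).
    """
    if max_link_dist_um <= 0:
        raise ValueError("max_link_dist_um must be positive")
    tracks: list[Track] = []
    active: list[Track] = []
    for det in detections_per_frame[0] if detections_per_frame else []:
        tracks.append(Track(len(tracks), [det]))
        active.append(tracks[-1])
    for t in range(1, len(detections_per_frame)):
        dets = detections_per_frame[t]
        a_pos = np.array([tr.detections[-1].position for tr in active]).reshape(-1, 3)
        b_pos = np.array([d.position for d in dets]).reshape(-1, 3)
        links, _ = link_pair(a_pos, b_pos, max_link_dist_um)
        linked_b = set()
        next_active: list[Track] = []
        for i, j in links:
            active[i].detections.append(dets[j])
            next_active.append(active[i])
            linked_b.add(j)
        for j, det in enumerate(dets):
            if j not in linked_b:
                tracks.append(Track(len(tracks), [det]))
                next_active.append(tracks[-1])
        active = next_active
    for tr in tracks:
        tr.validate()
    return tracks


def curate_tracks(
    tracks: list[Track],
    roi: tuple[tuple[float, float], ...] | None,
    n_frames: int,
) -> list[Track]:
    """Keep tracks starting inside ``roi`` that span the whole video.

    ``roi`` is an axis-aligned ((zlo, zhi), (ylo, yhi), (xlo, xhi)) box in
    µm, or None for the full field.
    """
    kept = []
    for tr in tracks:
        if len(tr) != n_frames:
            continue
        if roi is not None:
            p = tr.detections[0].position
            if not all(lo <= v <= hi for v, (lo, hi) in zip(p, roi)):
                continue
        kept.append(tr)
    return kept


def classify_tracks(
    tracks: list[Track],
    pmec_max_um: float = PMEC_MAX_DIAMETER_UM,
    icp_min_um: float = ICP_MIN_DIAMETER_UM,
) -> list[Track]:
    """Assign cell types from the median nuclear diameter (in place).

    Diameter < ``pmec_max_um`` → PMEC; > ``icp_min_um`` → ICP; tracks in
    between stay unclassified and are excluded from group statistics.
    """
    for tr in tracks:
        d = tr.median_diameter_um
        if np.isnan(d):
            warnings.warn(f"track {tr.track_id} has no diameter; left unclassified")
            tr.cell_type = "unclassified"
        elif d < pmec_max_um:
            tr.cell_type = "PMEC"
        elif d > icp_min_um:
            tr.cell_type = "ICP"
        else:
            tr.cell_type = "unclassified"
    return tracks


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    """Serialize tracks to the hand-off CSV layout used by trackstats."""
    rows = [
        (
            tr.track_id, d.frame, d.z_um, d.y_um, d.x_um,
            d.quality, d.diameter_um, tr.cell_type,
        )
        for tr in tracks
        for d in tr.detections
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "track_id", "frame", "z_um", "y_um", "x_um",
            "quality", "diameter_um", "cell_type",
        ],
    )


def tracks_from_dataframe(df: pd.DataFrame) -> list[Track]:
    """Rebuild Track objects from the CSV layout."""
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        dets = [
            Detection(
                int(r.frame), float(r.z_um), float(r.y_um), float(r.x_um),
                float(getattr(r, "quality", 0.0)),
                float(r.diameter_um) / 2.0,
            )
            for r in sub.itertuples()
        ]
        cell_type = sub["cell_type"].iloc[0] if "cell_type" in sub else "unclassified"
        tracks.append(Track(int(tid), dets, str(cell_type)))
    return tracks
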