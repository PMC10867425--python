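"""Particle linking, sister-kinetochore pairing and inter-centromere stretch.

Kinetochores are linked through time by greedy mutual-nearest-neighbour
assignment between consecutive frames with a hard displacement cap — at a
6-min (or faster) cadence the two dozen spots of a mitotic cell are well
separated, so nothing fancier is needed. Sister kinetochores are paired as
mutual nearest neighbours whose separation falls in a physiological window
(default 0.5–2.5 µm, bracketing published metaphase inter-kinetochore
distances). A pair's inter-centromere distance trace d(t) reports
microtubule-mediated pulling; normalizing each pair to its unstretched
state T0 (the minimum-distance frame by default) exposes sustained changes
in pulling force, and the per-pair maximum summarises stretch capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .quantify import LabelMask

__all__ = [
    "Trajectory",
    "StretchSeries",
    "link_particles",
    "pair_sisters",
    "pair_trajectories",
    "intercentromere_series",
    "normalize_T0",
    "stretch_summary",
    "tracks_table",
]


@dataclass
class Trajectory:
    """One particle's path: rows of (frame, y_px, x_px, label)."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    y_px: list[float] = field(default_factory=list)
    x_px: list[float] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)

    def append(self, frame: int, y: float, x: float, label: int) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("frames must be strictly increasing")
        self.frames.append(frame)
        self.y_px.append(float(y))
        self.x_px.append(float(x))
        self.labels.append(int(label))

    def __len__(self) -> int:
        return len(self.frames)

    def position(self, frame: int) -> tuple[float, float]:
        i = self.frames.index(frame)
        return self.y_px[i], self.x_px[i]


def _mutual_nn(a: np.ndarray, b: np.ndarray, max_dist: float) -> list[tuple[int, int]]:
    """Mutual nearest-neighbour matches between point sets, capped at max_dist."""
    if len(a) == 0 or len(b) == 0:
        return []
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, j_ab = tb.query(a)  # nearest b for each a
    d_ba, i_ba = ta.query(b)  # nearest a for each b
    matches = []
    for i in range(len(a)):
        j = int(j_ab[i])
        if d_ab[i] <= max_dist and int(i_ba[j]) == i:
            matches.append((i, j))
    return matches


def link_particles(
    frames: Sequence[LabelMask | np.ndarray], max_disp_px: float
) -> list[Trajectory]:
    """Link per-frame detections into trajectories.

    Each frame is a :class:`LabelMask` or a bare (n, 2) centroid array.
    Greedy mutual-nearest-neighbour assignment between consecutive frames;
    displacements above ``max_disp_px`` are never linked. Unmatched
    particles start new tracks; tracks whose particle vanishes terminate.
    Deterministic given the input.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    tracks: list[Trajectory] = []
    # active: particle row index in current frame -> track
    active: dict[int, Trajectory] = {}
    prev_pts: np.ndarray | None = None
    for t, mask in enumerate(frames):
        if isinstance(mask, LabelMask):
            pts = mask.centroids()
            labels = mask.table["label"].to_numpy() if mask.n_particles else np.array([], int)
        else:
            pts = np.asarray(mask, dtype=float).reshape(-1, 2)
            labels = np.arange(1, len(pts) + 1)
        new_active: dict[int, Trajectory] = {}
        if prev_pts is not None and len(prev_pts) and len(pts):
            for i, j in _mutual_nn(prev_pts, pts, max_disp_px):
                if i in active:
                    tr = active[i]
                    tr.append(t, pts[j, 0], pts[j, 1], labels[j])
                    new_active[j] = tr
        for j in range(len(pts)):
            if j not in new_active:
                tr = Trajectory(track_id=len(tracks))
                tr.append(t, pts[j, 0], pts[j, 1], labels[j])
                tracks.append(tr)
                new_active[j] = tr
        active = new_active
        prev_pts = pts
    return tracks


def pair_sisters(
    points: np.ndarray,
    pixel_size_um: float,
    d_min_um: float = 0.5,
    d_max_um: float = 2.5,
) -> tuple[list[tuple[int, int]], list[int]]:
    """Pair sister kinetochores in one frame.

    Pairs are mutual nearest neighbours whose separation lies in
    [d_min_um, d_max_um]; each particle joins at most one pair. Returns
    (pairs, unpaired) as index lists, each pair ordered (low, high index).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or (len(pts) and pts.shape[1] != 2):
        raise ValueError("points must be an (n, 2) array")
    pairs = []
    used = set()
    if len(pts) >= 2:
        tree = cKDTree(pts)
        d, j = tree.query(pts, k=2)
        nn_d, nn_j = d[:, 1], j[:, 1]
        for i in range(len(pts)):
            jj = int(nn_j[i])
            if i < jj and int(nn_j[jj]) == i:
                sep_um = nn_d[i] * pixel_size_um
                if d_min_um <= sep_um <= d_max_um:
                    pairs.append((i, jj))
                    used.update((i, jj))
    unpaired = [i for i in range(len(pts)) if i not in used]
    return pairs, unpaired


def pair_trajectories(
    tracks: Sequence[Trajectory],
    pixel_size_um: float,
    d_min_um: float = 0.5,
    d_max_um: float = 2.5,
) -> list[tuple[Trajectory, Trajectory]]:
    """Pair whole trajectories by their positions on the earliest common frame."""
    if not tracks:
        return []
    first = min(tr.frames[0] for tr in tracks)
    present = [tr for tr in tracks if first in tr.frames]
    pts = np.array([tr.position(first) for tr in present])
    pairs, _ = pair_sisters(pts, pixel_size_um, d_min_um, d_max_um)
    return [(present[i], present[j]) for i, j in pairs]


@dataclass
class StretchSeries:
    """A sister pair's inter-centromere distance trace (µm)."""

    pair_id: int
    frames: np.ndarray
    d_um: np.ndarray
    t0_index: int | None = None
    n: np.ndarray | None = None  # d / d(t0)

    @property
    def d_max(self) -> float:
        return float(self.d_um.max())

    @property
    def n_max(self) -> float | None:
        return None if self.n is None else float(self.n.max())


def intercentromere_series(
    pair: tuple[Trajectory, Trajectory],
    pixel_size_um: float,
    pair_id: int = 0,
) -> StretchSeries:
    """Euclidean inter-centromere distance per common frame, in µm."""
    a, b = pair
    common = sorted(set(a.frames) & set(b.frames))
    if len(common) < 2:
        raise ValueError("trajectories share fewer than 2 frames")
    d = np.empty(len(common))
    for k, f in enumerate(common):
        ya, xa = a.position(f)
        yb, xb = b.position(f)
        d[k] = np.hypot(ya - yb, xa - xb) * pixel_size_um
    return StretchSeries(pair_id=pair_id, frames=np.asarray(common), d_um=d)


def normalize_T0(series: StretchSeries, mode: str = "min") -> StretchSeries:
    """Normalize a distance trace to its unstretched state T0.

    ``mode='min'`` (default) takes T0 as the minimum-distance frame
    (earliest on ties); ``mode='first'`` uses the first frame. The
    normalized trace satisfies n(T0) = 1 exactly.
    """
    if series.d_um.size == 0:
        raise ValueError("empty series")
    if mode == "min":
        t0 = int(np.argmin(series.d_um))  # argmin returns the earliest tie
    elif mode == "first":
        t0 = 0
    else:
        raise ValueError(f"unknown T0 mode {mode!r}")
    d0 = series.d_um[t0]
    if d0 == 0:
        raise ValueError("zero distance at T0; cannot normalize")
    return StretchSeries(
        pair_id=series.pair_id,
        frames=series.frames,
        d_um=series.d_um,
        t0_index=t0,
        n=series.d_um / d0,
    )


def stretch_summary(
    series: Sequence[StretchSeries],
    frame_interval_min: float = 6.0,
) -> pd.DataFrame:
    """Per-pair maxima of d and n, plus trace duration in minutes."""
    rows = [
        {
            "pair_id": s.pair_id,
            "d_max": s.d_max,
            "n_max": s.n_max,
            "duration_min": (len(s.frames) - 1) * frame_interval_min,
        }
        for s in series
    ]
    return pd.DataFrame(rows, columns=["pair_id", "d_max", "n_max", "duration_min"])


def tracks_table(tracks: Sequence[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories to a track_id,frame,y_px,x_px table."""
    rows = []
    for tr in tracks:
        for f, y, x in zip(tr.frames, tr.y_px, tr.x_px):
            rows.append({"track_id": tr.track_id, "frame": f, "y_px": y, "x_px": x})
    return pd.DataFrame(rows, columns=["track_id", "frame", "y_px", "x_px"])
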