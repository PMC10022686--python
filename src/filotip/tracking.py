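"""Frame-to-frame linking of filopodia tip spots and track statistics.

Detected MYO10-positive spots are linked between consecutive frames by
an optimal bipartite assignment (the "simple LAP" contract): per cell
and frame pair, the assignment minimises total link distance among
matchings that link as many spot pairs as possible within the maximum
linking distance (default 1 µm).  Gap closing is disabled: a spot with
no link in the next frame ends its track, an unlinked spot opens a new
one.

Track statistics follow the fixed definitions: duration =
(n_frames − 1) × frame interval, total distance = sum of consecutive
Euclidean steps, mean speed = total distance / duration (0 for
single-frame tracks).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "Track",
    "link_spots",
    "track_stats",
    "per_cell_summary",
    "tracks_to_frame",
    "detect_spots",
]

DEFAULT_MAX_LINK_UM = 1.0
DEFAULT_FRAME_INTERVAL_S = 5.0

_INF = 1e12


@dataclass(frozen=True)
class Track:
    """One linked trajectory: strictly consecutive frames, no gaps."""

    track_id: int
    cell_id: str
    frames: np.ndarray
    positions: np.ndarray  # (n, 2) µm
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=int)
        positions = np.asarray(self.positions, dtype=float)
        if positions.shape != (frames.size, 2):
            raise ValueError("positions must align with frames")
        if frames.size > 1 and not np.all(np.diff(frames) == 1):
            raise ValueError("track frames must be consecutive (gap closing is disabled)")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "positions", positions)

    @property
    def n_frames(self) -> int:
        return self.frames.size

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s

    @property
    def total_distance_um(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.positions, axis=0), axis=1)))

    @property
    def mean_speed_um_per_s(self) -> float:
        d = self.duration_s
        return self.total_distance_um / d if d > 0 else 0.0


def _frame_pair_links(
    a: np.ndarray, b: np.ndarray, max_link_um: float
) -> list[tuple[int, int]]:
    """Optimal links between spot sets of two consecutive frames.

    Jaqaman-style augmented assignment: the (n+m)×(m+n) cost matrix
    offers each spot a "no link" alternative priced just above the
    maximum linking distance, so the optimum links as many pairs as
    possible within range and, among those, minimises total distance.
    Ties are broken deterministically by the solver on row order.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return []
    dist = cdist(a, b)
    cost = np.full((n + m, m + n), _INF)
    cost[:n, :m] = np.where(dist <= max_link_um, dist, _INF)
    no_link = 1.05 * max_link_um
    cost[np.arange(n), m + np.arange(n)] = no_link  # source i unlinked
    cost[n + np.arange(m), np.arange(m)] = no_link  # target j unlinked
    cost[n:, m:] = 0.0  # unlinked dummies pair freely
    rows, cols = linear_sum_assignment(cost)
    return [
        (i, j)
        for i, j in zip(rows, cols)
        if i < n and j < m and dist[i, j] <= max_link_um
    ]


def link_spots(
    spots: pd.DataFrame,
    max_link_um: float = DEFAULT_MAX_LINK_UM,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> list[Track]:
    """Link a spot table (cell_id, frame, x_um, y_um) into tracks.

    Linking is independent per cell and per consecutive frame pair;
    every input spot ends up in exactly one track.
    """
    if max_link_um < 0:
        raise ValueError("max_link_um must be nonnegative")
    required = {"cell_id", "frame", "x_um", "y_um"}
    missing = required - set(spots.columns)
    if missing:
        raise ValueError(f"spot table missing columns: {sorted(missing)}")

    tracks: list[Track] = []
    next_id = 0
    for cell_id, cell in spots.groupby("cell_id", sort=True):
        cell = cell.sort_index(kind="stable")
        frames = np.sort(cell["frame"].unique())
        by_frame = {
            int(f): g[["x_um", "y_um"]].to_numpy(float)
            for f, g in cell.groupby("frame", sort=True)
        }
        # open[i] = list of (frame, xy) for the track currently ending at spot i of frame f
        open_tracks: list[list[tuple[int, np.ndarray]]] = []
        prev_frame: int | None = None
        finished: list[list[tuple[int, np.ndarray]]] = []

        for f in frames:
            pts = by_frame[int(f)]
            if prev_frame is None or f != prev_frame + 1:
                finished.extend(open_tracks)
                open_tracks = [[(int(f), xy)] for xy in pts]
            else:
                prev_pts = np.array([t[-1][1] for t in open_tracks]).reshape(-1, 2)
                links = _frame_pair_links(prev_pts, pts, max_link_um)
                linked_prev = {i for i, _ in links}
                linked_next = {j for _, j in links}
                new_open: list[list[tuple[int, np.ndarray]]] = []
                for i, j in sorted(links):
                    open_tracks[i].append((int(f), pts[j]))
                    new_open.append(open_tracks[i])
                finished.extend(t for i, t in enumerate(open_tracks) if i not in linked_prev)
                new_open.extend(
                    [(int(f), pts[j])] for j in range(len(pts)) if j not in linked_next
                )
                open_tracks = new_open
            prev_frame = int(f)
        finished.extend(open_tracks)

        # deterministic ordering: by first frame, then first position
        finished.sort(key=lambda t: (t[0][0], t[0][1][0], t[0][1][1]))
        for t in finished:
            tracks.append(
                Track(
                    track_id=next_id,
                    cell_id=str(cell_id),
                    frames=np.array([f for f, _ in t]),
                    positions=np.array([xy for _, xy in t]),
                    frame_interval_s=frame_interval_s,
                )
            )
            next_id += 1
    return tracks


def track_stats(t: Track) -> tuple[float, float, float]:
    """(duration_s, total_distance_um, mean_speed_um_per_s) of one track."""
    return t.duration_s, t.total_distance_um, t.mean_speed_um_per_s


def per_cell_summary(tracks: list[Track]) -> pd.DataFrame:
    """Arithmetic per-cell means of duration, speed and distance.

    One row per cell: cell_id, n_tracks, mean_duration_s,
    mean_speed_um_per_s, mean_distance_um.  Feeds the between-condition
    statistical comparisons.
    """
    if not tracks:
        raise ValueError("no tracks to summarise")
    df = pd.DataFrame(
        {
            "cell_id": [t.cell_id for t in tracks],
            "duration_s": [t.duration_s for t in tracks],
            "speed_um_per_s": [t.mean_speed_um_per_s for t in tracks],
            "distance_um": [t.total_distance_um for t in tracks],
        }
    )
    out = (
        df.groupby("cell_id")
        .agg(
            n_tracks=("duration_s", "size"),
            mean_duration_s=("duration_s", "mean"),
            mean_speed_um_per_s=("speed_um_per_s", "mean"),
            mean_distance_um=("distance_um", "mean"),
        )
        .reset_index()
    )
    return out


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Long-format track table: track_id, cell_id, frame, x_um, y_um."""
    rows = []
    for t in tracks:
        for f, (x, y) in zip(t.frames, t.positions):
            rows.append((t.track_id, t.cell_id, int(f), float(x), float(y)))
    return pd.DataFrame(rows, columns=["track_id", "cell_id", "frame", "x_um", "y_um"])


def detect_spots(
    image: np.ndarray,
    pixel_size_um: float,
    threshold: float,
    min_distance_px: int = 3,
) -> pd.DataFrame:
    """Threshold + local-maximum spot detector for synthetic images.

    A deliberately simple stand-in detector for simulated data (real
    acquisitions use trained segmentation models): local intensity
    maxima above ``threshold`` become spots, coordinates returned in µm.
    """
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        np.asarray(image, float), min_distance=min_distance_px, threshold_abs=threshold
    )
    return pd.DataFrame(
        {
            "x_um": peaks[:, 1] * pixel_size_um,
            "y_um": peaks[:, 0] * pixel_size_um,
        }
    )
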