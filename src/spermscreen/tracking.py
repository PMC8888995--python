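"""Spot detection and frame-to-frame track linking.

The linker follows the Crocker-Grier family: for each consecutive frame
pair, detections are assigned to active tracks by minimizing total
squared displacement over the feasible bipartite graph (links longer
than ``max_displacement`` are forbidden), solved exactly per connected
component with the Jonker-Volgenant algorithm
(:func:`scipy.optimize.linear_sum_assignment`).  Leaving a track
unlinked or starting a new track costs ``max_displacement**2``, so a
link is always preferred to a break when one is feasible.  Tracks may
be missing for up to ``memory`` consecutive frames before they are
closed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "Detection",
    "Track",
    "detect_spots",
    "filter_tracks",
    "link_detections",
    "tracks_from_table",
]


@dataclass(frozen=True)
class Detection:
    """A single localized sperm head in one frame (um, image convention:
    origin top-left, y increasing downward)."""

    frame: int
    x: float
    y: float
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame must be >= 0")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("coordinates must be finite")


@dataclass
class Track:
    """Ordered per-frame positions of one cell in one field of view."""

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x, y must have equal length")
        if len(self.frames) >= 2 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) positions in um."""
        return np.column_stack([self.x, self.y])


def tracks_from_table(table: pd.DataFrame) -> Iterator[Track]:
    """Yield :class:`Track` objects from a linked table
    (columns track_id, frame, x_um, y_um), in track-id order."""
    for tid, grp in table.sort_values(["track_id", "frame"]).groupby("track_id", sort=True):
        yield Track(
            track_id=int(tid),
            frames=grp["frame"].to_numpy(),
            x=grp["x_um"].to_numpy(),
            y=grp["y_um"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# spot detection (image input path)


def detect_spots(
    image_frame: np.ndarray,
    spot_sigma: float,
    threshold: float,
    pixel_size_um: float = 1.0,
) -> pd.DataFrame:
    """Detect bright spots in one grayscale frame.

    Difference-of-Gaussians band-pass (sigma, 1.6*sigma), local maxima
    above ``threshold`` (on the band-passed image), then sub-pixel
    centroid refinement by intensity-weighted center of mass in a
    +-2 sigma window.  Returns a DataFrame with columns x_um, y_um,
    intensity; a blank/flat frame yields an empty frame, not an error.
    """
    from skimage.feature import peak_local_max
    from skimage.filters import difference_of_gaussians

    img = np.asarray(image_frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale frame")
    if img.size == 0 or np.ptp(img) == 0:
        return pd.DataFrame(columns=["x_um", "y_um", "intensity"])
    band = difference_of_gaussians(img, spot_sigma, 1.6 * spot_sigma)
    min_dist = max(1, int(round(2 * spot_sigma)))
    peaks = peak_local_max(band, min_distance=min_dist, threshold_abs=threshold)
    half = max(1, int(math.ceil(2 * spot_sigma)))
    rows = []
    pos = np.clip(band, 0, None)
    for r, c in peaks:
        r0, r1 = max(0, r - half), min(img.shape[0], r + half + 1)
        c0, c1 = max(0, c - half), min(img.shape[1], c + half + 1)
        patch = pos[r0:r1, c0:c1]
        total = patch.sum()
        if total <= 0:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        rows.append(
            (
                float((cc * patch).sum() / total) * pixel_size_um,
                float((rr * patch).sum() / total) * pixel_size_um,
                float(band[r, c]),
            )
        )
    return pd.DataFrame(rows, columns=["x_um", "y_um", "intensity"])


# ---------------------------------------------------------------------------
# linking


def _solve_component(
    cost: np.ndarray, penalty: float
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal assignment for one component's track x detection cost
    matrix (np.inf = infeasible).  Returns (track_idx, det_idx) links.

    The matrix is augmented with per-track "death" and per-detection
    "birth" dummies at ``penalty`` so partial matchings are allowed.
    """
    n_t, n_d = cost.shape
    size = n_t + n_d
    aug = np.full((size, size), np.inf)
    aug[:n_t, :n_d] = cost
    aug[:n_t, n_d:] = np.where(np.eye(n_t, dtype=bool), penalty, np.inf)
    aug[n_t:, :n_d] = np.where(np.eye(n_d, dtype=bool), penalty, np.inf)
    aug[n_t:, n_d:] = 0.0
    rows, cols = linear_sum_assignment(aug)
    keep = (rows < n_t) & (cols < n_d)
    return rows[keep], cols[keep]


def assign_frame(
    track_positions: np.ndarray,
    detection_positions: np.ndarray,
    max_displacement: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-frame assignment of detections to active tracks.

    Minimizes total squared displacement over the feasible bipartite
    graph (links longer than ``max_displacement`` forbidden; leaving a
    track or detection unmatched costs ``max_displacement**2`` each).
    Returns (track_indices, detection_indices) of the chosen links.
    Solved exactly per connected component; a component that is a
    single mutually-nearest pair short-circuits the LAP.
    """
    act_pos = np.asarray(track_positions, dtype=float).reshape(-1, 2)
    dpos = np.asarray(detection_positions, dtype=float).reshape(-1, 2)
    n_t, n_d = len(act_pos), len(dpos)
    if n_t == 0 or n_d == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    penalty = max_displacement * max_displacement
    dmat = cKDTree(act_pos).sparse_distance_matrix(
        cKDTree(dpos), max_displacement, output_type="coo_matrix"
    )
    out_t: list[int] = []
    out_d: list[int] = []
    if not dmat.nnz:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ti, dj, dist = dmat.row, dmat.col, dmat.data
    t_deg = np.bincount(ti, minlength=n_t)
    d_deg = np.bincount(dj, minlength=n_d)
    if t_deg.max() <= 1 and d_deg.max() <= 1:
        # all candidate edges are isolated pairs: link directly
        return ti.astype(np.int64), dj.astype(np.int64)
    graph = coo_matrix((np.ones(dmat.nnz), (ti, n_t + dj)), shape=(n_t + n_d, n_t + n_d))
    _, labels = connected_components(graph, directed=False)
    cost_sq = dist * dist
    edge_comp = labels[ti]
    comp_order = np.argsort(edge_comp, kind="stable")
    e = 0
    while e < dmat.nnz:
        comp = edge_comp[comp_order[e]]
        e2 = e
        while e2 < dmat.nnz and edge_comp[comp_order[e2]] == comp:
            e2 += 1
        sel = comp_order[e:e2]
        e = e2
        ts = np.unique(ti[sel])
        ds = np.unique(dj[sel])
        if len(ts) == 1 and len(ds) == 1:
            out_t.append(int(ts[0]))
            out_d.append(int(ds[0]))
            continue
        t_local = {t: k for k, t in enumerate(ts)}
        d_local = {d: k for k, d in enumerate(ds)}
        cm = np.full((len(ts), len(ds)), np.inf)
        for k in sel:
            cm[t_local[ti[k]], d_local[dj[k]]] = cost_sq[k]
        lt, ld = _solve_component(cm, penalty)
        out_t.extend(int(v) for v in ts[lt])
        out_d.extend(int(v) for v in ds[ld])
    return np.asarray(out_t, dtype=np.int64), np.asarray(out_d, dtype=np.int64)


def link_detections(
    detections: pd.DataFrame,
    max_displacement: float,
    memory: int = 1,
) -> pd.DataFrame:
    """Link per-frame detections into tracks.

    Parameters
    ----------
    detections
        DataFrame with columns ``frame``, ``x_um``, ``y_um``.
    max_displacement
        Maximum allowed per-link displacement in um (also the radius
        used when re-acquiring a track after a memory gap).
    memory
        Number of consecutive frames a track may go undetected before
        it is closed.

    Returns a copy of ``detections`` with a ``track_id`` column; every
    detection belongs to exactly one track.  New track ids are assigned
    in order of first appearance, which (with the exact per-frame
    assignment) makes the output deterministic for a given input order.
    """
    if not np.isfinite(max_displacement) or max_displacement <= 0:
        raise ValueError("max_displacement must be > 0")
    if memory < 0:
        raise ValueError("memory must be >= 0")
    required = {"frame", "x_um", "y_um"}
    missing = required - set(detections.columns)
    if missing:
        raise ValueError(f"detections table lacks columns {sorted(missing)}")

    frames_col = detections["frame"].to_numpy()
    xy = detections[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("detection coordinates must be finite")
    n = len(detections)
    track_of = np.full(n, -1, dtype=np.int64)

    order = np.argsort(frames_col, kind="stable")
    next_id = 0

    # active track state
    act_pos = np.empty((0, 2))
    act_id = np.empty(0, dtype=np.int64)
    act_frame = np.empty(0, dtype=np.int64)

    start = 0
    sorted_frames = frames_col[order]
    while start < n:
        f = sorted_frames[start]
        stop = start
        while stop < n and sorted_frames[stop] == f:
            stop += 1
        idx = order[start:stop]  # detection row indices in this frame
        dpos = xy[idx]
        start = stop

        # retire tracks whose gap exceeded memory
        alive = f - act_frame - 1 <= memory
        act_pos, act_id, act_frame = act_pos[alive], act_id[alive], act_frame[alive]

        n_d = len(idx)
        det_track = np.full(n_d, -1, dtype=np.int64)
        lt, ld = assign_frame(act_pos, dpos, max_displacement)
        if lt.size:
            det_track[ld] = act_id[lt]
            act_pos[lt] = dpos[ld]
            act_frame[lt] = f

        # unmatched detections found new tracks, in detection order
        new = det_track < 0
        n_new = int(new.sum())
        if n_new:
            new_ids = np.arange(next_id, next_id + n_new, dtype=np.int64)
            next_id += n_new
            det_track[new] = new_ids
            act_pos = np.vstack([act_pos, dpos[new]])
            act_id = np.concatenate([act_id, new_ids])
            act_frame = np.concatenate([act_frame, np.full(n_new, f, dtype=np.int64)])

        track_of[idx] = det_track

    out = detections.copy()
    out["track_id"] = track_of
    return out


def filter_tracks(tracks: pd.DataFrame, min_track_length: int = 5) -> pd.DataFrame:
    """Drop tracks with fewer than ``min_track_length`` observed points.

    Works on a linked table (columns track_id, frame, ...).  The count
    of discarded tracks is logged at INFO level.
    """
    if min_track_length < 2:
        raise ValueError("min_track_length must be >= 2")
    sizes = tracks.groupby("track_id", sort=False)["frame"].size()
    keep_ids = sizes.index[sizes >= min_track_length]
    n_dropped = sizes.size - keep_ids.size
    if n_dropped:
        logger.info("filter_tracks: discarded %d tracks shorter than %d points",
                    n_dropped, min_track_length)
    return tracks[tracks["track_id"].isin(set(keep_ids))].reset_index(drop=True)
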