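"""CASA kinematics: VCL, VSL, LIN, track classification, well summaries.

VCL (curvilinear velocity) is the total point-to-point path length of a
track divided by its elapsed time; VSL (straight-line velocity) is the
net first-to-last displacement over the same time; LIN = VSL/VCL.  For
tracks containing memory gaps, elapsed time uses the true frame span
while path length uses the straight segment across the gap, so a gap
can only lower VCL, never inflate it.

Tracks are classified immotile (IM), non-progressively motile (NPM) or
progressively motile (PM) by speed thresholds; the well statistic the
screen is built on is the median VCL over ALL tracks (including
immotile ones), averaged over the two imaged positions per well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracking import Track

__all__ = [
    "ClassThresholds",
    "KinematicRecord",
    "WellSummary",
    "classify_track",
    "compute_lin",
    "compute_vcl",
    "compute_vsl",
    "kinematics_table",
    "summarize_well",
]

CLASS_LABELS = ("IM", "NPM", "PM")


@dataclass(frozen=True)
class ClassThresholds:
    """Speed thresholds of the IM/NPM/PM rule.

    IM if VCL < vcl_im; else PM if VSL >= vsl_pm; else NPM.  The
    defaults (15 and 25 um/s) follow common CASA conventions and are an
    assumption of this package, not a published rule.
    """

    vcl_im: float = 15.0
    vsl_pm: float = 25.0


def _as_track(track) -> Track:
    if isinstance(track, Track):
        return track
    arr = np.asarray(track, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a Track or an (n, 2) array of positions")
    return Track(track_id=-1, frames=np.arange(len(arr)), x=arr[:, 0], y=arr[:, 1])


def _elapsed_seconds(t: Track, frame_rate: float) -> float:
    if len(t) < 2:
        raise ValueError("kinematics need a track of length >= 2")
    if not np.isfinite(frame_rate) or frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    return float(t.frames[-1] - t.frames[0]) / frame_rate


def compute_vcl(track, frame_rate: float) -> float:
    """Curvilinear velocity in um/s: path length / elapsed time."""
    t = _as_track(track)
    dt = _elapsed_seconds(t, frame_rate)
    path = float(np.hypot(np.diff(t.x), np.diff(t.y)).sum())
    return path / dt


def compute_vsl(track, frame_rate: float) -> float:
    """Straight-line velocity in um/s: net displacement / elapsed time."""
    t = _as_track(track)
    dt = _elapsed_seconds(t, frame_rate)
    return float(np.hypot(t.x[-1] - t.x[0], t.y[-1] - t.y[0])) / dt


def compute_lin(vcl: float, vsl: float) -> float:
    """Linearity VSL/VCL in [0, 1]; defined 0 when VCL = 0."""
    return vsl / vcl if vcl > 0 else 0.0


def classify_track(
    vcl: float, vsl: float, thresholds: ClassThresholds = ClassThresholds()
) -> str:
    """Apply the IM/NPM/PM threshold rule to one track's kinematics."""
    if not (np.isfinite(vcl) and np.isfinite(vsl)):
        raise ValueError("VCL and VSL must be finite")
    if vcl < thresholds.vcl_im:
        return "IM"
    return "PM" if vsl >= thresholds.vsl_pm else "NPM"


@dataclass(frozen=True)
class KinematicRecord:
    track_id: int
    vcl: float
    vsl: float
    lin: float
    class_label: str


def kinematics_table(
    tracks: pd.DataFrame,
    frame_rate: float,
    thresholds: ClassThresholds = ClassThresholds(),
) -> pd.DataFrame:
    """Per-track kinematics of a linked table, vectorized.

    ``tracks`` needs columns track_id, frame, x_um, y_um; every track
    must have >= 2 points (run :func:`tracking.filter_tracks` first).
    Returns columns track_id, VCL, VSL, LIN, class_label.
    """
    if not np.isfinite(frame_rate) or frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    if tracks.empty:
        return pd.DataFrame(columns=["track_id", "VCL", "VSL", "LIN", "class_label"])
    df = tracks.sort_values(["track_id", "frame"], kind="stable")
    tid = df["track_id"].to_numpy()
    fr = df["frame"].to_numpy(dtype=float)
    x = df["x_um"].to_numpy(dtype=float)
    y = df["y_um"].to_numpy(dtype=float)
    boundary = np.flatnonzero(np.r_[True, tid[1:] != tid[:-1]])
    sizes = np.diff(np.r_[boundary, tid.size])
    if sizes.min() < 2:
        raise ValueError("all tracks must have >= 2 points; filter short tracks first")
    step = np.hypot(np.diff(x), np.diff(y))
    step[boundary[1:] - 1] = 0.0  # zero out inter-track seams
    path = np.add.reduceat(np.r_[step, 0.0], boundary)
    last = np.r_[boundary[1:], tid.size] - 1
    elapsed = (fr[last] - fr[boundary]) / frame_rate
    vcl = path / elapsed
    vsl = np.hypot(x[last] - x[boundary], y[last] - y[boundary]) / elapsed
    lin = np.where(vcl > 0, vsl / np.where(vcl > 0, vcl, 1.0), 0.0)
    label = np.where(
        vcl < thresholds.vcl_im, "IM", np.where(vsl >= thresholds.vsl_pm, "PM", "NPM")
    )
    return pd.DataFrame(
        {"track_id": tid[boundary], "VCL": vcl, "VSL": vsl, "LIN": lin, "class_label": label}
    )


@dataclass
class WellSummary:
    """Per-well motility summary.

    ``well_value`` is the arithmetic mean of the available per-field
    median VCLs (median over ALL tracks, immotile included).  A well
    with zero tracks in every field is flagged invalid rather than
    reported as zero.
    """

    well: str
    field_medians: list[float]
    well_value: float
    n_tracks: list[int]
    class_fractions: Mapping[str, float]
    valid: bool
    single_field: bool


def summarize_well(
    well: str,
    field_records: Sequence[pd.DataFrame],
    pool_fields: bool = False,
) -> WellSummary:
    """Summarize one well from its per-field kinematics tables.

    ``field_records`` holds one kinematics table (as produced by
    :func:`kinematics_table`) per imaged position; normally two.  With
    ``pool_fields=True`` the tracks of all fields are pooled before
    taking a single median instead of averaging per-field medians.
    """
    if len(field_records) == 0:
        raise ValueError("need at least one field record")
    medians, n_tracks = [], []
    counts = {c: 0 for c in CLASS_LABELS}
    for rec in field_records:
        n_tracks.append(len(rec))
        if len(rec):
            medians.append(float(rec["VCL"].median()))
            for c, k in rec["class_label"].value_counts().items():
                counts[c] += int(k)
    total = sum(n_tracks)
    if not medians:
        return WellSummary(well, [], float("nan"), n_tracks,
                           {c: float("nan") for c in CLASS_LABELS}, False, False)
    if pool_fields:
        pooled = pd.concat([r for r in field_records if len(r)])
        well_value = float(pooled["VCL"].median())
    else:
        well_value = float(np.mean(medians))
    fractions = {c: counts[c] / total for c in CLASS_LABELS}
    return WellSummary(
        well=well,
        field_medians=medians,
        well_value=well_value,
        n_tracks=n_tracks,
        class_fractions=fractions,
        valid=True,
        single_field=len(medians) < len(field_records) or len(field_records) == 1,
    )
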