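"""Detection linking and migration-speed summaries for time-lapse imaging.

Cells imaged every 30 min for 20 h are detected per frame (externally or via
:func:`nichemech.image_quant.count_particles` centroids) and linked into
tracks by mutual-nearest-neighbor assignment between consecutive frames,
with optional bridging of short detection gaps.  Track velocity is the mean
instantaneous path speed: total path length divided by track duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import GroupComparison, mann_whitney_two_tailed

__all__ = [
    "Track",
    "TrackStats",
    "link_detections",
    "track_speed",
    "summarize_by_animal",
]

REQUIRED_COLUMNS = ("frame", "t", "x", "y")


@dataclass
class Track:
    """One cell's ordered detections (columns frame, t, x, y)."""

    track_id: int
    detections: pd.DataFrame

    def __len__(self):
        return len(self.detections)


@dataclass(frozen=True)
class TrackStats:
    track_id: int
    mean_speed: float  # um/h, path length / duration
    duration: float  # h
    path_length: float  # um
    n_detections: int


def _mutual_nearest_pairs(dist, allowed):
    """Mutual-nearest-neighbor pairs under a boolean feasibility mask.

    Repeated rounds: pair (i, j) when j is i's nearest allowed partner and
    vice versa (ties resolved toward the lowest index), remove both, repeat
    until no pair forms.  Deterministic for sorted input.
    """
    dist = np.where(allowed, dist, np.inf)
    n_rows, n_cols = dist.shape
    pairs = []
    free_rows = np.ones(n_rows, dtype=bool)
    free_cols = np.ones(n_cols, dtype=bool)
    while True:
        sub = dist.copy()
        sub[~free_rows, :] = np.inf
        sub[:, ~free_cols] = np.inf
        if not np.isfinite(sub).any():
            break
        row_best = sub.argmin(axis=1)  # argmin takes the lowest index on ties
        col_best = sub.argmin(axis=0)
        matched_any = False
        for i in np.nonzero(free_rows)[0]:
            j = row_best[i]
            if np.isfinite(sub[i, j]) and col_best[j] == i:
                pairs.append((int(i), int(j)))
                free_rows[i] = False
                free_cols[j] = False
                matched_any = True
        if not matched_any:
            break
    return pairs


def link_detections(detections, max_displacement, max_gap=0):
    """Link per-frame detections into tracks.

    Parameters
    ----------
    detections : DataFrame
        Columns ``frame`` (int), ``t`` (h), ``x``, ``y`` (um), sorted by
        frame.  Duplicate (frame, x, y) rows are rejected.
    max_displacement : float
        Maximum allowed frame-to-frame displacement (um); after a gap of
        ``g`` missing frames the allowance grows to
        ``max_displacement * (g + 1)``.
    max_gap : int
        Maximum number of consecutive missing frames a track may bridge.

    Returns
    -------
    list of Track
    """
    det = pd.DataFrame(detections).reset_index(drop=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in det.columns]
    if missing:
        raise ValueError(f"detections missing columns: {missing}")
    if det.duplicated(subset=["frame", "x", "y"]).any():
        raise ValueError("duplicate (frame, position) detections")
    if not det["frame"].is_monotonic_increasing:
        det = det.sort_values("frame", kind="stable").reset_index(drop=True)

    tracks_rows: dict[int, list] = {}
    active: list[dict] = []  # {"id", "last_frame", "xy"}
    next_id = 0
    for frame, group in det.groupby("frame", sort=True):
        group = group.sort_index()
        pts = group[["x", "y"]].to_numpy(dtype=float)
        candidates = [
            tr for tr in active if frame - tr["last_frame"] - 1 <= max_gap
        ]
        pairs = []
        if candidates and len(pts):
            ends = np.array([tr["xy"] for tr in candidates])
            gaps = np.array([frame - tr["last_frame"] for tr in candidates])
            dist = np.linalg.norm(ends[:, None, :] - pts[None, :, :], axis=2)
            allowed = dist <= max_displacement * gaps[:, None]
            pairs = _mutual_nearest_pairs(dist, allowed)
        matched_dets = set()
        for ti, di in pairs:
            tr = candidates[ti]
            row = group.iloc[di]
            tracks_rows[tr["id"]].append(row)
            tr["last_frame"] = int(frame)
            tr["xy"] = pts[di]
            matched_dets.add(di)
        for di in range(len(pts)):
            if di in matched_dets:
                continue
            row = group.iloc[di]
            tracks_rows[next_id] = [row]
            active.append(
                {"id": next_id, "last_frame": int(frame), "xy": pts[di]}
            )
            next_id += 1
        active = [tr for tr in active if frame - tr["last_frame"] <= max_gap]

    return [
        Track(tid, pd.DataFrame(rows).reset_index(drop=True))
        for tid, rows in sorted(tracks_rows.items())
    ]


def track_speed(track: Track, min_frames=5) -> TrackStats:
    """Mean path speed of a track: sum of step lengths over duration.

    Tracks shorter than ``min_frames`` detections are rejected — transient
    cells do not yield meaningful 20-h velocities.
    """
    det = track.detections
    if len(det) < min_frames:
        raise ValueError(
            f"track {track.track_id} has {len(det)} < {min_frames} detections"
        )
    t = det["t"].to_numpy(dtype=float)
    xy = det[["x", "y"]].to_numpy(dtype=float)
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise ValueError("track duration must be positive")
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    path = float(steps.sum())
    return TrackStats(track.track_id, path / duration, duration, path, len(det))


def net_displacement_speed(track: Track, min_frames=5) -> float:
    """Alternative speed: net start-to-end displacement over duration."""
    det = track.detections
    if len(det) < min_frames:
        raise ValueError("too few detections")
    t = det["t"].to_numpy(dtype=float)
    xy = det[["x", "y"]].to_numpy(dtype=float)
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise ValueError("track duration must be positive")
    return float(np.linalg.norm(xy[-1] - xy[0]) / duration)


def summarize_by_animal(track_stats, mapping, group_of=None):
    """Per-animal mean speed, optionally compared between two groups.

    Parameters
    ----------
    track_stats : iterable of TrackStats (or DataFrame with track_id, mean_speed)
    mapping : dict track_id -> animal id
    group_of : dict animal -> group label, optional
        When given (two groups), animal means are compared by a two-tailed
        Mann-Whitney test.

    Returns
    -------
    dict with ``animal_means`` (DataFrame) and, when groups are supplied,
    ``comparison`` (GroupComparison).
    """
    if isinstance(track_stats, pd.DataFrame):
        df = track_stats[["track_id", "mean_speed"]].copy()
    else:
        df = pd.DataFrame(
            {"track_id": s.track_id, "mean_speed": s.mean_speed}
            for s in track_stats
        )
    unmapped = set(df["track_id"]) - set(mapping)
    if unmapped:
        raise ValueError(f"tracks not mapped to an animal: {sorted(unmapped)}")
    df["animal"] = df["track_id"].map(mapping)
    animal_means = (
        df.groupby("animal")["mean_speed"].mean().rename("mean_speed").reset_index()
    )
    result = {"animal_means": animal_means}
    if group_of is not None:
        silent = [a for a in group_of if a not in set(df["animal"])]
        if silent:
            warnings.warn(
                f"animals with no tracks excluded: {silent}", stacklevel=2
            )
        animal_means = animal_means.assign(
            group=animal_means["animal"].map(group_of)
        )
        groups = [g for g in pd.unique(animal_means["group"]) if g is not None]
        if len(groups) != 2:
            raise ValueError("group comparison needs exactly two groups")
        g1, g2 = groups
        result["comparison"] = mann_whitney_two_tailed(
            animal_means.loc[animal_means["group"] == g1, "mean_speed"],
            animal_means.loc[animal_means["group"] == g2, "mean_speed"],
        )
        result["groups"] = (g1, g2)
        result["animal_means"] = animal_means
    return result
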