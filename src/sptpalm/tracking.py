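"""Frame-to-frame trajectory linking and track-length retention.

Localizations in consecutive frames are linked by a globally optimal
one-to-one assignment (minimum total distance) among candidate pairs within
a hard distance gate of 320 nm (two pixels).  Unmatched localizations start
new tracks; a track ends as soon as its particle goes unmatched — there is
no gap closing.  The retention filter keeps tracks of 4-12 localizations
(0.4-1.2 s at 10 Hz); longer tracks are rejected whole, never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "DEFAULT_LINK_DISTANCE_NM",
    "TrackLengthFilterResult",
    "link_localizations",
    "filter_track_lengths",
    "track_lengths",
]

DEFAULT_LINK_DISTANCE_NM = 320.0  # two 160 nm pixels

TRACK_COLUMNS = ["track_id", "frame", "x_nm", "y_nm"]

_INFEASIBLE = 1e12


def _gated_assignment(cost: np.ndarray, gate: float) -> list[tuple[int, int]]:
    """Minimum-total-distance one-to-one matching with a hard gate.

    Uses the classic augmentation: each row and column gets a dummy partner
    of cost ``gate`` (the price of leaving it unmatched), so any pair within
    the gate is preferred to leaving both ends unlinked, infeasible pairs
    are never chosen, and among feasible matchings the total distance is
    minimal.
    """
    n, m = cost.shape
    big = np.full((n + m, n + m), 0.0)
    core = np.where(cost <= gate, cost, _INFEASIBLE)
    big[:n, :m] = core
    big[:n, m:] = _INFEASIBLE
    big[n:, :m] = _INFEASIBLE
    big[:n, m:][np.arange(n), np.arange(n)] = gate
    big[n:, :m][np.arange(m), np.arange(m)] = gate
    rows, cols = linear_sum_assignment(big)
    return [(r, c) for r, c in zip(rows, cols) if r < n and c < m and core[r, c] <= gate]


def link_localizations(
    localizations: pd.DataFrame,
    max_link_distance: float = DEFAULT_LINK_DISTANCE_NM,
) -> pd.DataFrame:
    """Link a localization table into tracks.

    Parameters
    ----------
    localizations : DataFrame
        Must contain ``frame, x_nm, y_nm``; additional columns are carried
        through unchanged.
    max_link_distance : float
        Hard linking gate in nm (default 320 nm, two pixels).

    Returns
    -------
    DataFrame with an added leading ``track_id`` column, sorted by
    ``(track_id, frame)``.  Every localization belongs to exactly one track.
    """
    if localizations.empty:
        out = localizations.copy()
        out.insert(0, "track_id", pd.Series(dtype=int))
        return out
    df = localizations.sort_values("frame", kind="stable").reset_index(drop=True)
    frames = df["frame"].to_numpy()
    xy = df[["x_nm", "y_nm"]].to_numpy(dtype=float)

    track_of = np.full(len(df), -1, dtype=int)
    next_track = 0
    unique_frames = np.unique(frames)
    prev_idx: np.ndarray | None = None
    prev_frame: int | None = None
    for f in unique_frames:
        cur_idx = np.flatnonzero(frames == f)
        if prev_idx is not None and prev_frame is not None and f == prev_frame + 1:
            cost = cdist(xy[prev_idx], xy[cur_idx])
            for r, c in _gated_assignment(cost, max_link_distance):
                track_of[cur_idx[c]] = track_of[prev_idx[r]]
        for i in cur_idx:
            if track_of[i] < 0:
                track_of[i] = next_track
                next_track += 1
        prev_idx, prev_frame = cur_idx, int(f)

    df.insert(0, "track_id", track_of)
    return df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)


def track_lengths(tracks: pd.DataFrame) -> pd.Series:
    """Number of localizations per track."""
    return tracks.groupby("track_id").size()


def track_durations(tracks: pd.DataFrame, frame_interval: float = 0.1) -> pd.Series:
    """Reported per-track duration in seconds.

    Durations are reported as ``n_frames * frame_interval`` (each retained
    localization counts one camera exposure), so the 4-12-frame retention
    window maps to 0.4-1.2 s at 10 Hz.
    """
    return track_lengths(tracks) * frame_interval


class TrackLengthFilterResult(NamedTuple):
    tracks: pd.DataFrame
    n_too_short: int
    n_too_long: int


def filter_track_lengths(
    tracks: pd.DataFrame,
    min_frames: int = 4,
    max_frames: int = 12,
) -> TrackLengthFilterResult:
    """Retain tracks with ``min_frames <= n <= max_frames`` localizations
    (bounds inclusive); rejected tracks are counted by cause.

    A track longer than ``max_frames`` is rejected whole, not truncated.
    """
    if tracks.empty:
        return TrackLengthFilterResult(tracks.copy(), 0, 0)
    n = track_lengths(tracks)
    keep = n[(n >= min_frames) & (n <= max_frames)].index
    out = tracks[tracks["track_id"].isin(keep)].reset_index(drop=True)
    return TrackLengthFilterResult(
        out, int((n < min_frames).sum()), int((n > max_frames).sum())
    )
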