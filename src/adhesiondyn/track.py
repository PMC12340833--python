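"""Frame-to-frame puncta linking, track QC filters, and cell migration speed.

Linking is per-frame-pair minimum-cost bipartite assignment on centroid
distance with a hard displacement gate; there is no gap closing, so a puncta
that drops out for one frame starts a new track. This matches the downstream
QC filter, which presumes contiguous tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detect import Puncta

__all__ = [
    "PunctaTrack",
    "CellTrajectory",
    "link_tracks",
    "filter_tracks",
    "duration",
    "cell_speed",
]

#: QC flag names used on tracks
TOUCHES_FIRST = "touches_first_frame"
TOUCHES_LAST = "touches_last_frame"
TOO_SHORT = "too_short"
LOW_FIT_QUALITY = "low_fit_quality"


@dataclass
class PunctaTrack:
    """One adhesion followed over contiguous frames."""

    track_id: int
    punctae: list[Puncta]
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        frames = [p.frame_index for p in self.punctae]
        if len(frames) == 0:
            raise ValueError("track must contain at least one detection")
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing and contiguous")

    @property
    def start_frame(self) -> int:
        return self.punctae[0].frame_index

    @property
    def end_frame(self) -> int:
        return self.punctae[-1].frame_index

    @property
    def n_frames(self) -> int:
        return len(self.punctae)

    @property
    def mfi_series(self) -> np.ndarray:
        return np.array([p.mfi for p in self.punctae], dtype=float)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([p.centroid for p in self.punctae], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "track_id": self.track_id,
                "frame": [p.frame_index for p in self.punctae],
                "row": [p.centroid[0] for p in self.punctae],
                "col": [p.centroid[1] for p in self.punctae],
                "area_px": [p.area_px for p in self.punctae],
                "mfi": [p.mfi for p in self.punctae],
            }
        )


def tracks_to_frame(tracks: list[PunctaTrack]) -> pd.DataFrame:
    cols = ["track_id", "frame", "row", "col", "area_px", "mfi"]
    if not tracks:
        return pd.DataFrame(columns=cols)
    return pd.concat([t.to_frame() for t in tracks], ignore_index=True)


def tracks_from_frame(df: pd.DataFrame) -> list[PunctaTrack]:
    """Rebuild tracks from a long-format table (as written by the CLI).

    Pixel masks are not stored in the table; each puncta is represented by
    the single pixel nearest its centroid, which is sufficient for kinetics
    (MFI is stored) but not for colocalization against a second channel.
    """
    tracks = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("frame")
        punctae = [
            Puncta(
                frame_index=int(r.frame),
                centroid=(float(r.row), float(r.col)),
                pixels=np.array([[int(round(r.row)), int(round(r.col))]]),
                area_px=int(getattr(r, "area_px", 1)),
                mfi=float(r.mfi),
            )
            for r in grp.itertuples()
        ]
        tracks.append(PunctaTrack(track_id=int(tid), punctae=punctae))
    return tracks


def link_tracks(
    punctae_by_frame: list[list[Puncta]], max_disp_px: float = 5.0
) -> list[PunctaTrack]:
    """Link per-frame detections into tracks.

    For each consecutive frame pair, the assignment minimising total centroid
    displacement (Hungarian algorithm) is computed; links longer than
    ``max_disp_px`` are forbidden. Unmatched detections start new tracks and a
    track ends the first frame it finds no match. Every input detection ends
    up in exactly one track.
    """
    open_tracks: list[list[Puncta]] = []
    closed: list[list[Puncta]] = []
    for frame_dets in punctae_by_frame:
        frame_dets = list(frame_dets)
        if not open_tracks:
            open_tracks = [[d] for d in frame_dets]
            continue
        if not frame_dets:
            closed.extend(open_tracks)
            open_tracks = []
            continue
        prev = np.array([t[-1].centroid for t in open_tracks])
        curr = np.array([d.centroid for d in frame_dets])
        dist = np.linalg.norm(prev[:, None, :] - curr[None, :, :], axis=2)
        cost = np.where(dist <= max_disp_px, dist, 1e6)
        rows, cols = linear_sum_assignment(cost)
        matched_prev, matched_curr = set(), set()
        for i, j in zip(rows, cols):
            if dist[i, j] <= max_disp_px:
                open_tracks[i].append(frame_dets[j])
                matched_prev.add(i)
                matched_curr.add(j)
        next_open = [t for i, t in enumerate(open_tracks) if i in matched_prev]
        closed.extend(t for i, t in enumerate(open_tracks) if i not in matched_prev)
        next_open.extend([d] for j, d in enumerate(frame_dets) if j not in matched_curr)
        open_tracks = next_open
    closed.extend(open_tracks)
    closed.sort(key=lambda t: (t[0].frame_index, t[0].centroid))
    return [PunctaTrack(track_id=i, punctae=t) for i, t in enumerate(closed)]


def filter_tracks(
    tracks: list[PunctaTrack], n_frames_total: int, min_frames: int = 9
) -> tuple[list[PunctaTrack], list[PunctaTrack]]:
    """Apply the track QC rules and partition into (kept, removed).

    A track is removed if it is present in the first or last frame of the
    movie, or if it spans ``min_frames - 1`` frames or fewer (default: tracks
    of 8 frames or shorter are removed). Removed tracks carry the reason in
    ``qc_flags``; kept tracks have these flags cleared. The function is
    idempotent and kept + removed partition the input.
    """
    kept, removed = [], []
    for t in tracks:
        flags = set(t.qc_flags) - {TOUCHES_FIRST, TOUCHES_LAST, TOO_SHORT}
        if t.start_frame == 0:
            flags.add(TOUCHES_FIRST)
        if t.end_frame == n_frames_total - 1:
            flags.add(TOUCHES_LAST)
        if t.n_frames <= min_frames - 1:
            flags.add(TOO_SHORT)
        t.qc_flags = flags
        if flags & {TOUCHES_FIRST, TOUCHES_LAST, TOO_SHORT}:
            removed.append(t)
        else:
            kept.append(t)
    return kept, removed


def duration(track: PunctaTrack) -> int:
    """Adhesion duration: total number of frames the puncta was detected."""
    return track.n_frames


@dataclass
class CellTrajectory:
    """Whole-cell centroid per frame; NaN rows mark flagged frames."""

    centroids: np.ndarray  # (n_frames, 2), NaN where segmentation failed
    frame_interval_s: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[1] != 2:
            raise ValueError("centroids must be (n_frames, 2)")
        if np.isfinite(self.centroids).all(axis=1).sum() < 2:
            raise ValueError("trajectory needs at least 2 valid frames")


def measure_cell_trajectory(
    channel: np.ndarray,
    frame_interval_s: float,
    pixel_size_um: float,
    smooth_window: int = 5,
) -> CellTrajectory:
    """Segment the cell in every frame and build its centroid trajectory.

    Per-frame binary centroids carry a few tenths of a pixel of segmentation
    noise, which inflates the mean-step speed estimate; a centred rolling
    mean of width ``smooth_window`` over the valid centroids suppresses it
    while leaving steady drift unchanged (the rolling mean commutes with a
    linear trend). Frames where segmentation fails stay NaN and are excluded
    both from the averaging windows and, downstream, from the speed.
    """
    from .detect import segment_cell

    n = channel.shape[0]
    raw = np.full((n, 2), np.nan)
    for f in range(n):
        seg = segment_cell(channel[f])
        if seg.ok:
            raw[f] = seg.centroid
    if smooth_window <= 1:
        smoothed = raw
    else:
        half = smooth_window // 2
        smoothed = np.full_like(raw, np.nan)
        for i in range(n):
            window = raw[max(0, i - half) : i + half + 1]
            ok = np.isfinite(window).all(axis=1)
            if ok.any() and np.isfinite(raw[i]).all():
                smoothed[i] = window[ok].mean(axis=0)
    return CellTrajectory(smoothed, frame_interval_s, pixel_size_um)


def cell_speed(traj: CellTrajectory) -> float:
    """Mean instantaneous migration speed in µm/s.

    Speed is averaged over consecutive frame pairs, Euclidean displacement
    divided by the frame interval; pairs touching a flagged (NaN) frame are
    excluded.
    """
    valid = np.isfinite(traj.centroids).all(axis=1)
    pair_ok = valid[:-1] & valid[1:]
    if not pair_ok.any():
        raise ValueError("no consecutive pair of valid frames")
    disp_px = np.linalg.norm(np.diff(traj.centroids, axis=0), axis=1)[pair_ok]
    speeds = disp_px * traj.pixel_size_um / traj.frame_interval_s
    return float(speeds.mean())
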