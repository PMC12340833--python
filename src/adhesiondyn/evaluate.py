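"""Recovery metrics against synthetic ground truth.

These helpers score detection (recall/precision), tracking (purity) and
colocalization (label accuracy) against the :class:`GroundTruthTable` a
simulation produced. A ground-truth object counts as detectable in a frame
only when its true spot amplitude reaches ``min_true_amplitude`` — spots
shallower than the detector's prominence cutoff are invisible to it by
construction, so recall is defined over the detectable set while precision
is scored against ALL true objects regardless of amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coloc import POSITIVE
from .detect import Puncta
from .simulate import GroundTruthTable
from .track import PunctaTrack

__all__ = [
    "DetectionScore",
    "score_detections",
    "track_purity",
    "match_tracks_to_objects",
    "coloc_accuracy",
]


@dataclass
class DetectionScore:
    recall: float
    precision: float
    n_true: int
    n_detected: int
    n_matched: int


def _match_frame(
    dets: np.ndarray, truths: np.ndarray, max_dist_px: float
) -> list[tuple[int, int]]:
    """Greedy nearest-first one-to-one matching between detections and truths."""
    if len(dets) == 0 or len(truths) == 0:
        return []
    dist = np.linalg.norm(dets[:, None, :] - truths[None, :, :], axis=2)
    pairs = []
    used_d, used_t = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    for i, j in order:
        if dist[i, j] > max_dist_px:
            break
        if i in used_d or j in used_t:
            continue
        pairs.append((int(i), int(j)))
        used_d.add(i)
        used_t.add(j)
    return pairs


def score_detections(
    punctae_by_frame: list[list[Puncta]],
    truth: GroundTruthTable,
    max_dist_px: float = 3.0,
    min_true_amplitude: float = 60.0,
) -> DetectionScore:
    """Frame-wise recall and precision of a detector against ground truth."""
    pos = truth.positions
    n_true = n_matched = n_det = n_false = 0
    for f, dets in enumerate(punctae_by_frame):
        frame_truth = pos[pos["frame"] == f]
        det_xy = np.array([p.centroid for p in dets]) if dets else np.empty((0, 2))
        all_xy = frame_truth[["row", "col"]].to_numpy()
        detectable = frame_truth["true_intensity"].to_numpy() >= min_true_amplitude
        n_det += len(dets)
        n_true += int(detectable.sum())
        pairs = _match_frame(det_xy, all_xy, max_dist_px)
        matched_d = {i for i, _ in pairs}
        n_matched += sum(1 for _, j in pairs if detectable[j])
        n_false += len(dets) - len(matched_d)
    recall = n_matched / n_true if n_true else np.nan
    precision = (n_det - n_false) / n_det if n_det else np.nan
    return DetectionScore(
        recall=float(recall),
        precision=float(precision),
        n_true=n_true,
        n_detected=n_det,
        n_matched=n_matched,
    )


def _detection_object(
    p: Puncta, truth_pos: pd.DataFrame, max_dist_px: float
) -> int | None:
    """Ground-truth object id a detection originates from, by nearest centre."""
    frame_truth = truth_pos[truth_pos["frame"] == p.frame_index]
    if not len(frame_truth):
        return None
    d = np.linalg.norm(
        frame_truth[["row", "col"]].to_numpy() - np.array(p.centroid), axis=1
    )
    i = int(np.argmin(d))
    return int(frame_truth.iloc[i]["object_id"]) if d[i] <= max_dist_px else None


def track_purity(
    tracks: list[PunctaTrack], truth: GroundTruthTable, max_dist_px: float = 3.0
) -> float:
    """Mean over tracks of the fraction of detections from the modal object."""
    purities = []
    for t in tracks:
        ids = [_detection_object(p, truth.positions, max_dist_px) for p in t.punctae]
        counts: dict[int, int] = {}
        for i in ids:
            if i is not None:
                counts[i] = counts.get(i, 0) + 1
        best = max(counts.values()) if counts else 0
        purities.append(best / len(ids))
    return float(np.mean(purities)) if purities else np.nan


def match_tracks_to_objects(
    tracks: list[PunctaTrack], truth: GroundTruthTable, max_dist_px: float = 3.0
) -> dict[int, int]:
    """Track id → modal ground-truth object id (tracks with no match omitted)."""
    out = {}
    for t in tracks:
        ids = [_detection_object(p, truth.positions, max_dist_px) for p in t.punctae]
        counts: dict[int, int] = {}
        for i in ids:
            if i is not None:
                counts[i] = counts.get(i, 0) + 1
        if counts:
            out[t.track_id] = max(counts, key=counts.get)
    return out


def coloc_accuracy(
    labels: dict[int, str],
    track_to_object: dict[int, int],
    truth: GroundTruthTable,
) -> float:
    """Fraction of labelled tracks whose call matches the true channel-2 class."""
    truth_by_id = truth.objects.set_index("object_id")["channel2_positive"]
    n = correct = 0
    for tid, label in labels.items():
        if tid not in track_to_object:
            continue
        true_pos = bool(truth_by_id.loc[track_to_object[tid]])
        n += 1
        correct += int((label == POSITIVE) == true_pos)
    return correct / n if n else np.nan
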