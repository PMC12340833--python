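"""Two-channel colocalization classification of adhesion tracks.

A track detected in channel 1 is called channel-2 positive when, in enough of
its frames, the channel-2 intensity inside the puncta mask is enriched over
the local background — the median channel-2 intensity in an annulus around
the mask. The ratio criterion makes the call invariant to global affine
rescaling of channel-2 intensities and to smooth illumination gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology

from .track import PunctaTrack

__all__ = ["ColocParams", "classify_track", "classify_tracks", "POSITIVE", "NEGATIVE", "UNDEFINED"]

POSITIVE = "positive"
NEGATIVE = "negative"
UNDEFINED = "undefined"


@dataclass
class ColocParams:
    """Criterion parameters for the channel-2 positivity call.

    enrichment_ratio_min
        Minimum (mask MFI) / (annulus median) ratio for a frame to count as
        enriched.
    annulus_width_px
        Width of the local-background ring around the (slightly dilated)
        puncta mask.
    min_positive_fraction
        Fraction of a track's scored frames that must be enriched for the
        track to be called positive.
    """

    enrichment_ratio_min: float = 1.5
    annulus_width_px: int = 3
    min_positive_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.enrichment_ratio_min <= 1:
            raise ValueError("enrichment_ratio_min must exceed 1")
        if not 0 < self.min_positive_fraction <= 1:
            raise ValueError("min_positive_fraction must lie in (0, 1]")
        if self.annulus_width_px < 1:
            raise ValueError("annulus_width_px must be >= 1")


def _frame_ratio(
    pixels: np.ndarray, frame2: np.ndarray, annulus_width_px: int
) -> float | None:
    """Channel-2 enrichment ratio for one detection; None if unscorable."""
    shape = frame2.shape
    rows, cols = pixels[:, 0], pixels[:, 1]
    pad = annulus_width_px + 1
    r0, r1 = rows.min() - pad, rows.max() + pad + 1
    c0, c1 = cols.min() - pad, cols.max() + pad + 1
    if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
        return None  # annulus would leave the image
    crop = frame2[r0:r1, c0:c1]
    mask = np.zeros(crop.shape, dtype=bool)
    mask[rows - r0, cols - c0] = True
    inner = morphology.dilation(mask, morphology.disk(1))
    outer = morphology.dilation(mask, morphology.disk(annulus_width_px))
    ring = outer & ~inner
    if not ring.any():
        return None
    background = float(np.median(crop[ring]))
    if background <= 0:
        return None
    return float(crop[mask].mean() / background)


def classify_track(
    track: PunctaTrack, channel2: np.ndarray, params: ColocParams | None = None
) -> str:
    """Label one track ``positive``/``negative`` on channel-2 enrichment.

    ``channel2`` is the (frames, rows, cols) second-channel array registered
    with the detection channel. Frames whose annulus leaves the image are
    skipped; a track with no scorable frame is labelled ``undefined`` and the
    caller should QC-flag it.
    """
    params = params or ColocParams()
    ratios = []
    for p in track.punctae:
        ratio = _frame_ratio(p.pixels, channel2[p.frame_index], params.annulus_width_px)
        if ratio is not None:
            ratios.append(ratio)
    if not ratios:
        return UNDEFINED
    enriched = np.array(ratios) >= params.enrichment_ratio_min
    frac = enriched.mean()
    return POSITIVE if frac >= params.min_positive_fraction else NEGATIVE


def classify_tracks(
    tracks: list[PunctaTrack], channel2: np.ndarray, params: ColocParams | None = None
) -> dict[int, str]:
    """Labels for many tracks, keyed by track id."""
    params = params or ColocParams()
    return {t.track_id: classify_track(t, channel2, params) for t in tracks}
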