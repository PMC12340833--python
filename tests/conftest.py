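import numpy as np
import pytest

from adhesiondyn.detect import Puncta
from adhesiondyn.simulate import SimConfig, simulate_timelapse
from adhesiondyn.track import PunctaTrack


def make_track(mfi, start_frame=0, track_id=0, centroid=(5.0, 5.0)):
    """Build a PunctaTrack with the given MFI series at a fixed position."""
    punctae = [
        Puncta(
            frame_index=start_frame + i,
            centroid=centroid,
            pixels=np.array([[int(round(centroid[0])), int(round(centroid[1]))]]),
            area_px=4,
            mfi=float(m),
        )
        for i, m in enumerate(mfi)
    ]
    return PunctaTrack(track_id=track_id, punctae=punctae)


def span_track(start, length, track_id=0):
    """Track occupying frames start..start+length-1 with constant MFI."""
    return make_track(np.full(length, 50.0), start_frame=start, track_id=track_id)


@pytest.fixture(scope="session")
def small_stack():
    """A short noisy two-channel stack with ground truth (shared, read-only)."""
    cfg = SimConfig(n_frames=60, n_punctae=12, rng_seed=11)
    stack, truth = simulate_timelapse(cfg)
    return cfg, stack, truth
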