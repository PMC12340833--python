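"""Timelapse image container and TIFF I/O.

An :class:`ImageStack` holds a ``(frames, rows, cols, channels)`` float array
together with the two pieces of acquisition metadata every downstream
computation needs: the frame interval (seconds) and the pixel size (µm).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """Multi-frame, multi-channel fluorescence timelapse.

    Parameters
    ----------
    data
        Intensity array of shape ``(n_frames, rows, cols, n_channels)``.
    frame_interval_s
        Time between consecutive frames, in seconds.
    pixel_size_um
        Side length of one pixel, in micrometres.
    """

    data: np.ndarray
    frame_interval_s: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # single channel supplied without axis
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(
                f"expected (frames, rows, cols, channels) array, got shape {self.data.shape}"
            )
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, frame 0 at t = 0."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def channel(self, index: int) -> np.ndarray:
        """One channel as a ``(frames, rows, cols)`` view."""
        return self.data[..., index]

    # ------------------------------------------------------------------ I/O

    def save_tiff(self, path: str | Path, split_channels: bool = False) -> list[Path]:
        """Write the stack to TIFF.

        With ``split_channels=False`` a single multi-page file is written with
        axes ``TCYX`` (interleaved-channel dialect). With ``split_channels=True``
        one single-channel file per channel is written, suffixed ``_ch<i>``.
        Returns the list of paths written.
        """
        path = Path(path)
        meta = {
            "axes": "TCYX",
            "frame_interval_s": self.frame_interval_s,
            "pixel_size_um": self.pixel_size_um,
        }
        written: list[Path] = []
        if split_channels:
            for c in range(self.n_channels):
                p = path.with_name(f"{path.stem}_ch{c}{path.suffix or '.tif'}")
                tifffile.imwrite(
                    p,
                    self.channel(c).astype(np.float32),
                    metadata={**meta, "axes": "TYX"},
                )
                written.append(p)
        else:
            # (T, C, Y, X) page order, the layout NIS/ImageJ-style readers expect
            arr = np.moveaxis(self.data, 3, 1).astype(np.float32)
            tifffile.imwrite(path, arr, metadata=meta)
            written.append(path)
        return written

    @classmethod
    def from_tiff(
        cls,
        paths: str | Path | list[str | Path],
        frame_interval_s: float | None = None,
        pixel_size_um: float | None = None,
    ) -> "ImageStack":
        """Read a stack from one interleaved TIFF or a list of per-channel TIFFs.

        Metadata written by :meth:`save_tiff` is recovered automatically;
        explicit arguments override it (and are required for third-party files
        that carry none).
        """
        if isinstance(paths, (str, Path)):
            paths = [paths]
        arrays = []
        meta_interval = meta_pixel = None
        for p in paths:
            with tifffile.TiffFile(p) as tf:
                arr = tf.asarray()
                try:
                    desc = tf.shaped_metadata[0] if tf.shaped_metadata else {}
                except (AttributeError, IndexError):
                    desc = {}
                meta_interval = meta_interval or desc.get("frame_interval_s")
                meta_pixel = meta_pixel or desc.get("pixel_size_um")
            if arr.ndim == 2:
                arr = arr[np.newaxis]
            arrays.append(arr)
        if len(arrays) == 1:
            arr = arrays[0]
            if arr.ndim == 3:  # T, Y, X -> single channel
                data = arr[..., np.newaxis]
            elif arr.ndim == 4:  # T, C, Y, X
                data = np.moveaxis(arr, 1, 3)
            else:
                raise ValueError(f"unsupported TIFF shape {arr.shape}")
        else:
            if len({a.shape for a in arrays}) != 1:
                raise ValueError("per-channel TIFFs must share a shape")
            data = np.stack(arrays, axis=-1)
        interval = frame_interval_s if frame_interval_s is not None else meta_interval
        pixel = pixel_size_um if pixel_size_um is not None else meta_pixel
        if interval is None or pixel is None:
            raise ValueError(
                "frame_interval_s and pixel_size_um must be given when the TIFF carries no metadata"
            )
        return cls(np.asarray(data, dtype=float), float(interval), float(pixel))
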