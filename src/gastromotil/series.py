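"""Dynamic image series container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ImageSeries:
    """A T x H x W grayscale dynamic series with physical calibration.

    ``pixel_size_mm`` converts pixel to physical coordinates
    (mm = px * pixel_size_mm); ``frame_interval_s`` is the time between
    successive frames, so frame t (0-based) was acquired at t * frame_interval_s.
    """

    data: np.ndarray
    pixel_size_mm: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("series data must be a (T, H, W) array")
        if self.pixel_size_mm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def copy(self) -> "ImageSeries":
        return ImageSeries(self.data.copy(), self.pixel_size_mm, self.frame_interval_s)
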