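"""In-memory container for registered multi-channel time-lapse images."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EmbryoImageSeries:
    """A time-indexed set of multi-channel (optionally z-stacked) frames.

    ``data`` has axis order (T, C, Z, Y, X); single-slice data uses Z=1.
    ``pixel_size`` is um/pixel in Y and X, ``time_resolution`` seconds between
    frames, ``z_step`` um between slices.
    """

    data: np.ndarray
    pixel_size: float
    time_resolution: float = 30.0
    z_step: float = 2.0
    channel_names: tuple[str, ...] = ("nuclear", "signal")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"expected TCZYX data, got ndim={self.data.ndim}")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match axis C")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_z(self) -> int:
        return self.data.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) * self.time_resolution

    def frame(self, t: int, channel: int | str, z: int = 0) -> np.ndarray:
        if isinstance(channel, str):
            channel = self.channel_names.index(channel)
        return self.data[t, channel, z]
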