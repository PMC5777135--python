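"""Shared in-memory containers used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class Movie:
    """A single-channel imaging time series.

    Parameters
    ----------
    data
        Intensity stack of shape ``(T, H, W)``; finite and non-negative.
    frame_rate_hz
        Acquisition rate in Hz.
    protocol
        Optional :class:`~tectastim.preprocessing.StimulationProtocol` the
        movie was acquired (or simulated) under.
    provenance
        ``"synthetic"`` or ``"acquired"``.
    """

    data: np.ndarray
    frame_rate_hz: float
    protocol: Optional[object] = None
    provenance: str = "acquired"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be (T, H, W); got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("movie must contain at least one frame")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.all(np.isfinite(self.data)):
                raise ValueError("movie intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("movie intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.data.shape[1]), int(self.data.shape[2])
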