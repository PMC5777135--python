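"""Stimulation-frame exclusion, rigid drift correction and averaging.

The stimulation light (sculpted by the SLM) saturates every imaging frame it
overlaps, so those frames are deleted outright before any analysis.  For the
standard acquisition (350 frames at 5 Hz, stimulation at frames 50/150/250)
this leaves frames 1-50, 77-150, 177-250, 277-350 for long (5000 ms) pulses
and 1-50, 53-150, 153-250, 253-350 for short (100 ms) pulses.  All frame
indices in protocols, reports and serialized files are 1-based; array
positions inside this package are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import Movie

PULSE_MS = {"short": 100.0, "long": 5000.0}

# Number of frames deleted after each event frame.  Derived so that the
# retained sets reproduce the published frame lists for both pulse kinds
# (event frame f: short pulses delete {f+1, f+2}, long pulses {f+1 .. f+26}).
EXCLUDED_SPAN = {"short": 2, "long": 26}


@dataclass(frozen=True)
class StimulationProtocol:
    """Event timing plus the derived retained/excluded frame bookkeeping.

    ``event_frames`` and ``retained_frames`` are 1-based original frame
    indices.  The event frame itself is always retained; exclusion starts at
    the frame after it.
    """

    n_frames: int
    event_frames: tuple[int, ...]
    pulse_kind: str
    pulse_ms: float
    retained_frames: tuple[int, ...]

    def __post_init__(self) -> None:
        retained = self.retained_frames
        if any(b <= a for a, b in zip(retained, retained[1:])):
            raise ValueError("retained_frames must be strictly increasing")
        if retained and (retained[0] < 1 or retained[-1] > self.n_frames):
            raise ValueError("retained_frames out of range")

    # -- frame map ---------------------------------------------------------
    @property
    def excluded_frames(self) -> tuple[int, ...]:
        retained = set(self.retained_frames)
        return tuple(f for f in range(1, self.n_frames + 1) if f not in retained)

    @property
    def n_retained(self) -> int:
        return len(self.retained_frames)

    def to_retained(self, original_frame: int) -> int:
        """1-based position of an original frame in the reduced movie."""
        idx = np.searchsorted(self.retained_frames, original_frame)
        if idx >= len(self.retained_frames) or self.retained_frames[idx] != original_frame:
            raise KeyError(f"frame {original_frame} is not retained")
        return int(idx) + 1

    def to_original(self, retained_position: int) -> int:
        """Original 1-based frame index for a 1-based retained position."""
        if not 1 <= retained_position <= len(self.retained_frames):
            raise KeyError(f"retained position {retained_position} out of range")
        return self.retained_frames[retained_position - 1]

    def first_retained_after(self, frame: int) -> int:
        """First retained original frame strictly after ``frame``."""
        idx = np.searchsorted(self.retained_frames, frame, side="right")
        if idx >= len(self.retained_frames):
            raise ValueError(f"no retained frame after frame {frame}")
        return self.retained_frames[idx]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "event_frames": list(self.event_frames),
            "pulse_kind": self.pulse_kind,
            "pulse_ms": self.pulse_ms,
            "retained_frames": list(self.retained_frames),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationProtocol":
        return cls(
            n_frames=int(d["n_frames"]),
            event_frames=tuple(int(f) for f in d["event_frames"]),
            pulse_kind=str(d["pulse_kind"]),
            pulse_ms=float(d["pulse_ms"]),
            retained_frames=tuple(int(f) for f in d["retained_frames"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StimulationProtocol":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_protocol(
    pulse_kind: str,
    event_frames: Sequence[int] = (50, 150, 250),
    n_frames: int = 350,
    pulse_ms: Optional[float] = None,
) -> StimulationProtocol:
    """Construct the protocol and its retained/excluded frame sets.

    Raises
    ------
    ValueError
        If events are unordered, out of range, or their exclusion windows
        overlap the next event.
    """
    if pulse_kind not in EXCLUDED_SPAN:
        raise ValueError(f"pulse_kind must be one of {sorted(EXCLUDED_SPAN)}, got {pulse_kind!r}")
    events = tuple(int(f) for f in event_frames)
    if any(b <= a for a, b in zip(events, events[1:])):
        raise ValueError("event_frames must be strictly increasing")
    if events and (events[0] < 1 or events[-1] > n_frames):
        raise ValueError(f"event_frames must lie within [1, {n_frames}]")
    span = EXCLUDED_SPAN[pulse_kind]
    for a, b in zip(events, events[1:]):
        if b <= a + span:
            raise ValueError(f"exclusion window of event {a} overlaps event {b}")
    excluded: set[int] = set()
    for f in events:
        excluded.update(range(f + 1, min(f + span, n_frames) + 1))
    retained = tuple(f for f in range(1, n_frames + 1) if f not in excluded)
    return StimulationProtocol(
        n_frames=n_frames,
        event_frames=events,
        pulse_kind=pulse_kind,
        pulse_ms=PULSE_MS[pulse_kind] if pulse_ms is None else float(pulse_ms),
        retained_frames=retained,
    )


def exclude_stim_frames(movie: Movie, protocol: StimulationProtocol) -> tuple[Movie, np.ndarray]:
    """Delete SLM-active frames; return the reduced movie and its frame map.

    The frame map is the array of retained 1-based original frame indices:
    position ``i`` (0-based) of the reduced movie came from original frame
    ``frame_map[i]``.
    """
    if movie.n_frames != protocol.n_frames:
        raise ValueError(
            f"protocol was built for {protocol.n_frames} frames, movie has {movie.n_frames}"
        )
    frame_map = np.asarray(protocol.retained_frames, dtype=int)
    reduced = Movie(
        data=movie.data[frame_map - 1],
        frame_rate_hz=movie.frame_rate_hz,
        protocol=protocol,
        provenance=movie.provenance,
    )
    return reduced, frame_map


@dataclass
class RegisteredMovie:
    """Drift-corrected stack with the integer shifts that were applied."""

    data: np.ndarray
    shifts: np.ndarray          # (T, 2) applied (dy, dx) per frame
    reference: np.ndarray       # the 2-D template frames were aligned to
    frame_rate_hz: float
    description: str = "mean of leading retained frames"

    @property
    def estimated_drift(self) -> np.ndarray:
        """Per-frame drift of the specimen (negative of the applied shift)."""
        return -self.shifts


def _translate(frame: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(frame, fill)
    h, w = frame.shape
    src_r = slice(max(-dy, 0), h - max(dy, 0))
    src_c = slice(max(-dx, 0), w - max(dx, 0))
    dst_r = slice(max(dy, 0), h - max(-dy, 0))
    dst_c = slice(max(dx, 0), w - max(-dx, 0))
    out[dst_r, dst_c] = frame[src_r, src_c]
    return out


def register_translation(
    movie: Movie,
    search_radius: int = 10,
    n_reference_frames: int = 50,
    reference: Optional[np.ndarray] = None,
) -> RegisteredMovie:
    """Align every frame to a reference by integer-pixel translation.

    The reference defaults to the mean of the first ``n_reference_frames``
    frames (pre-stimulation frames are artifact-free).  For each frame the
    shift within ``±search_radius`` pixels maximizing the (mean-subtracted)
    cross-correlation with the reference is applied; out-of-frame pixels are
    filled with the frame's median intensity.
    """
    data = np.asarray(movie.data, dtype=np.float64)
    if data.shape[0] < 2:
        raise ValueError("registration requires at least two frames")
    t, h, w = data.shape
    if search_radius < 0 or 2 * search_radius + 1 > min(h, w):
        raise ValueError("search_radius out of range for this frame size")
    if reference is None:
        reference = data[: min(n_reference_frames, t)].mean(axis=0)
    reference = np.asarray(reference, dtype=np.float64)
    ref0 = reference - reference.mean()
    if not ref0.any():
        raise ValueError("registration reference has zero variance (blank image)")
    f_ref = np.fft.rfft2(ref0)

    offsets = np.arange(-search_radius, search_radius + 1)
    row_idx = offsets % h
    col_idx = offsets % w

    out = np.empty_like(data)
    shifts = np.zeros((t, 2), dtype=int)
    for i in range(t):
        frame = data[i]
        f0 = frame - frame.mean()
        # circular cross-correlation c[s] = sum_x ref0[x + s] * f0[x];
        # the maximizing s is the shift applied to the frame.
        cc = np.fft.irfft2(f_ref * np.conj(np.fft.rfft2(f0)), s=(h, w))
        window = cc[np.ix_(row_idx, col_idx)]
        flat = int(np.argmax(window))          # row-major => deterministic ties
        dy = int(offsets[flat // len(offsets)])
        dx = int(offsets[flat % len(offsets)])
        shifts[i] = (dy, dx)
        out[i] = _translate(frame, dy, dx, fill=float(np.median(frame)))
    return RegisteredMovie(
        data=out,
        shifts=shifts,
        reference=reference,
        frame_rate_hz=movie.frame_rate_hz,
    )


def average_projection(movie) -> np.ndarray:
    """Per-pixel mean over time of a movie or a (T, H, W) array."""
    data = np.asarray(movie.data if not isinstance(movie, np.ndarray) and hasattr(movie, "data") else movie)
    if data.ndim != 3 or data.shape[0] < 1:
        raise ValueError("average_projection expects a non-empty (T, H, W) stack")
    return data.mean(axis=0, dtype=np.float64)
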