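"""Ground-truthed synthetic SPIM calcium-imaging movies.

Emulates the functional acquisition this pipeline targets: 70 s single-plane
movies at 5 Hz (350 frames) of nuclear-localized GCaMP somata in the tectal
periventricular layer, with optogenetic stimulation events at frames
50/150/250 whose SLM illumination saturates the overlapping frames.  Planted
response classes:

``visual_excited``
    a calcium transient at the onset of every stimulation flash (a direct
    visual response to the blue light);
``inhibited``
    fluorescence suppressed during long-pulse stimulation, followed by a
    rebound transient whose amplitude decays by ``habituation_factor`` at
    each successive event;
``silent``
    spontaneous activity only.

Each cell additionally carries sparse spontaneous transients and a slow
independent baseline modulation (bleaching / physiological drift), so that
distinct cells never produce numerically identical traces.  Rigid drift is
injected as an integer-pixel translation stepped at each stimulation event.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.draw import disk as _draw_disk

from .core import Movie
from .preprocessing import StimulationProtocol

CLASS_NAMES = ("visual_excited", "inhibited", "silent")

_MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated movie.

    Amplitudes are in percent change over baseline fluorescence of the cell
    (the same scale ΔF/F is reported on); intensities are 16-bit gray levels.
    """

    height_px: int = 128
    width_px: int = 128
    frame_rate_hz: float = 5.0
    duration_s: float = 70.0
    n_cells: int = 100
    cell_radius_px: int = 3
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"visual_excited": 0.25, "inhibited": 0.08, "silent": 0.67}
    )
    spontaneous_rate_hz: float = 0.005
    spontaneous_amplitude: float = 30.0
    kernel_rise_s: float = 0.5
    kernel_decay_s: float = 3.0
    inhibition_depth: float = 0.8
    rebound_amplitude: float = 100.0
    habituation_factor: float = 0.7
    visual_amplitude: float = 100.0
    cell_brightness: float = 100.0
    background_level: float = 0.0
    baseline_drift_pct: float = 5.0
    activity_noise_pct: float = 5.0
    noise_sd: float = 3.0
    shot_noise: bool = False
    drift_px_per_event: int = 1
    artifact_level: float = 60000.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate_hz * self.duration_s))

    def validate(self) -> None:
        for name in ("height_px", "width_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "frame_rate_hz", "duration_s", "kernel_rise_s", "kernel_decay_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "n_cells", "cell_radius_px", "spontaneous_rate_hz", "spontaneous_amplitude",
            "rebound_amplitude", "visual_amplitude", "cell_brightness",
            "background_level", "baseline_drift_pct", "activity_noise_pct",
            "noise_sd", "artifact_level",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.inhibition_depth <= 1.0:
            raise ValueError("inhibition_depth must lie in [0, 1]")
        if not 0.0 < self.habituation_factor <= 1.0:
            raise ValueError("habituation_factor must lie in (0, 1]")
        if self.drift_px_per_event < 0:
            raise ValueError("drift_px_per_event must be non-negative")
        unknown = set(self.class_fractions) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"class_fractions has unknown classes: {sorted(unknown)}")
        if any(v < 0 for v in self.class_fractions.values()):
            raise ValueError("class_fractions must be non-negative")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")


@dataclass
class CellRecord:
    cell_id: int                 # matches the label in the ground-truth mask
    row: int
    col: int
    radius: int
    cell_class: str
    response_flags: tuple[bool, ...]   # one per stimulation event
    spike_frames: tuple[int, ...]      # 1-based, includes planted responses

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "row": self.row,
            "col": self.col,
            "radius": self.radius,
            "cell_class": self.cell_class,
            "response_flags": list(self.response_flags),
            "spike_frames": list(self.spike_frames),
        }


@dataclass
class GroundTruth:
    """Everything planted in a synthetic movie."""

    cells: list[CellRecord]
    shifts: np.ndarray           # (n_frames, 2) true (dy, dx) drift per frame
    frame_shape: tuple[int, int]

    def cells_of_class(self, name: str) -> list[CellRecord]:
        return [c for c in self.cells if c.cell_class == name]

    def label_mask(self) -> np.ndarray:
        """Planted discs at their drift-free reference positions."""
        mask = np.zeros(self.frame_shape, dtype=np.int32)
        for cell in self.cells:
            rr, cc = _draw_disk((cell.row, cell.col), cell.radius + 0.5, shape=self.frame_shape)
            mask[rr, cc] = cell.cell_id
        return mask

    def to_dict(self) -> dict:
        return {
            "frame_shape": list(self.frame_shape),
            "shifts": self.shifts.tolist(),
            "cells": [c.to_dict() for c in self.cells],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        cells = [
            CellRecord(
                cell_id=int(c["cell_id"]), row=int(c["row"]), col=int(c["col"]),
                radius=int(c["radius"]), cell_class=str(c["cell_class"]),
                response_flags=tuple(bool(f) for f in c["response_flags"]),
                spike_frames=tuple(int(f) for f in c["spike_frames"]),
            )
            for c in d["cells"]
        ]
        return cls(
            cells=cells,
            shifts=np.asarray(d["shifts"], dtype=int),
            frame_shape=tuple(d["frame_shape"]),
        )


# ---------------------------------------------------------------------------
# GCaMP kernel
# ---------------------------------------------------------------------------

def _kernel_values(lags_s: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials kernel, peak-normalized to 1, zero for lag<0."""
    lags = np.asarray(lags_s, dtype=np.float64)
    out = np.zeros_like(lags)
    pos = lags >= 0
    lp = lags[pos]
    if rise_s <= 0:
        if math.isinf(decay_s):
            out[pos] = 1.0
        else:
            out[pos] = np.exp(-lp / decay_s)
    elif math.isinf(decay_s):
        out[pos] = 1.0 - np.exp(-lp / rise_s)
    elif abs(decay_s - rise_s) < 1e-12:
        # alpha function limit; peak 1 at lag == rise_s
        out[pos] = (lp / rise_s) * np.exp(1.0 - lp / rise_s)
    else:
        if decay_s < rise_s:
            raise ValueError("kernel_decay_s must be >= kernel_rise_s")
        t_peak = rise_s * decay_s / (decay_s - rise_s) * math.log(decay_s / rise_s)
        peak = math.exp(-t_peak / decay_s) - math.exp(-t_peak / rise_s)
        out[pos] = (np.exp(-lp / decay_s) - np.exp(-lp / rise_s)) / peak
    return out


def spikes_to_fluorescence(
    spike_frames: Sequence[int],
    kernel_rise_s: float,
    kernel_decay_s: float,
    frame_rate_hz: float,
    n_frames: int,
    amplitudes: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Sum of peak-normalized GCaMP kernels placed at 1-based spike frames.

    ``amplitudes`` scales each spike's kernel (default 1).  The returned
    trace is non-negative and has length ``n_frames``.
    """
    spike_frames = [int(s) for s in spike_frames]
    if any(s < 1 or s > n_frames for s in spike_frames):
        raise ValueError(f"spike frames must lie within [1, {n_frames}]")
    if amplitudes is None:
        amplitudes = [1.0] * len(spike_frames)
    if len(amplitudes) != len(spike_frames):
        raise ValueError("amplitudes must match spike_frames in length")
    trace = np.zeros(n_frames, dtype=np.float64)
    times = np.arange(n_frames, dtype=np.float64) / frame_rate_hz
    for s, a in zip(spike_frames, amplitudes):
        trace += a * _kernel_values(times - (s - 1) / frame_rate_hz, kernel_rise_s, kernel_decay_s)
    return trace


# ---------------------------------------------------------------------------
# Movie generation
# ---------------------------------------------------------------------------

def _class_counts(n_cells: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of cells to classes."""
    raw = {k: fractions.get(k, 0.0) * n_cells for k in CLASS_NAMES}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n_cells - sum(counts.values())
    for k in sorted(CLASS_NAMES, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _place_cells(
    rng: np.random.Generator, config: SimulationConfig, margin: int
) -> list[tuple[int, int]]:
    r = config.cell_radius_px
    lo_r, hi_r = r + margin, config.height_px - 1 - r - margin
    lo_c, hi_c = r + margin, config.width_px - 1 - r - margin
    if hi_r < lo_r or hi_c < lo_c:
        raise ValueError("height_px/width_px too small for cell_radius_px and drift margin")
    min_sep2 = (2 * r + 2) ** 2   # keeps discs disjoint with a 1-px gap
    centers: list[tuple[int, int]] = []
    for i in range(config.n_cells):
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            row = int(rng.integers(lo_r, hi_r + 1))
            col = int(rng.integers(lo_c, hi_c + 1))
            if all((row - r0) ** 2 + (col - c0) ** 2 >= min_sep2 for r0, c0 in centers):
                centers.append((row, col))
                break
        else:
            raise ValueError(
                f"n_cells: failed to place cell {i + 1}/{config.n_cells} without overlap"
            )
    return centers


def _suppression_factor(
    config: SimulationConfig, protocol: StimulationProtocol
) -> np.ndarray:
    """Multiplicative fluorescence factor modelling sustained inhibition.

    During each stimulation window fluorescence relaxes toward
    ``1 - inhibition_depth`` with the indicator decay time; after stimulus
    offset it recovers to 1 with the (faster) rise time.
    """
    n = config.n_frames
    factor = np.ones(n, dtype=np.float64)
    times = np.arange(n, dtype=np.float64) / config.frame_rate_hz
    stim_frames = max(1, int(round(protocol.pulse_ms / 1000.0 * config.frame_rate_hz)))
    for e in protocol.event_frames:
        onset, offset = e, min(e + stim_frames, n)          # 1-based frame span
        t_on, t_off = times[onset - 1], times[offset - 1]
        during = slice(onset, offset)                       # frames e+1 .. e+stim
        factor[during] *= 1.0 - config.inhibition_depth * (
            1.0 - np.exp(-(times[during] - t_on) / config.kernel_decay_s)
        )
        depth_end = config.inhibition_depth * (1.0 - math.exp(-(t_off - t_on) / config.kernel_decay_s))
        after = slice(offset, n)
        factor[after] *= 1.0 - depth_end * np.exp(-(times[after] - t_off) / config.kernel_rise_s)
    return factor


def _cell_trace(
    rng: np.random.Generator,
    config: SimulationConfig,
    protocol: StimulationProtocol,
    cell_class: str,
) -> tuple[np.ndarray, tuple[int, ...], tuple[bool, ...]]:
    """Relative-fluorescence trace (baseline 1.0) plus planted spikes/flags."""
    n, rate = config.n_frames, config.frame_rate_hz
    kw = dict(
        kernel_rise_s=config.kernel_rise_s,
        kernel_decay_s=config.kernel_decay_s,
        frame_rate_hz=rate,
        n_frames=n,
    )
    # spontaneous events (all classes)
    n_spont = rng.poisson(config.spontaneous_rate_hz * config.duration_s)
    spont_frames = sorted(int(f) for f in rng.integers(1, n + 1, size=n_spont))
    spikes = list(spont_frames)
    amps = [config.spontaneous_amplitude] * len(spont_frames)

    n_events = len(protocol.event_frames)
    flags = tuple([False] * n_events)
    if cell_class == "visual_excited":
        for e in protocol.event_frames:
            spikes.append(min(e + 1, n))        # onset of the stimulation flash
            amps.append(config.visual_amplitude)
        flags = tuple([True] * n_events)
    elif cell_class == "inhibited":
        for k, e in enumerate(protocol.event_frames):
            spikes.append(protocol.first_retained_after(e))
            amps.append(config.rebound_amplitude * config.habituation_factor ** k)
        flags = tuple([True] * n_events)

    transients = spikes_to_fluorescence(spikes, amplitudes=amps, **kw) / 100.0

    # cell-specific ongoing variability, normalized to exact SDs so every
    # cell carries an independent trace component: a slow baseline drift
    # (bleaching / physiology, ~10 s timescale) that moves whole event
    # windows coherently, plus fast low-amplitude activity noise (~0.4 s)
    def _smoothed(sd_pct: float, sigma_s: float) -> np.ndarray:
        if sd_pct <= 0:
            return np.zeros(n)
        x = gaussian_filter1d(rng.standard_normal(n), sigma=sigma_s * rate, mode="reflect")
        sd = x.std()
        return x * (sd_pct / 100.0 / sd) if sd > 0 else x

    drift = _smoothed(config.baseline_drift_pct, 10.0) + _smoothed(
        config.activity_noise_pct, 0.4
    )

    rel = 1.0 + transients + drift
    if cell_class == "inhibited":
        rel = rel * _suppression_factor(config, protocol)
    order = np.argsort(spikes)
    return np.clip(rel, 0.0, None), tuple(spikes[i] for i in order), flags


def generate_movie(
    config: SimulationConfig, protocol: StimulationProtocol
) -> tuple[Movie, GroundTruth]:
    """Render a synthetic movie and its complete ground truth.

    The returned movie has exactly ``round(frame_rate_hz * duration_s)``
    16-bit frames; frames in the protocol's excluded set are overwritten
    with ``artifact_level`` (saturated SLM reflections).
    """
    config.validate()
    n = config.n_frames
    if protocol.n_frames != n:
        raise ValueError(
            f"duration_s/frame_rate_hz: protocol covers {protocol.n_frames} frames, "
            f"config implies {n}"
        )
    if protocol.event_frames and max(protocol.event_frames) > n:
        raise ValueError("event_frames: events outside movie length")
    rng = np.random.default_rng(config.seed)
    n_events = len(protocol.event_frames)
    margin = config.drift_px_per_event * n_events

    centers = _place_cells(rng, config, margin)
    counts = _class_counts(config.n_cells, dict(config.class_fractions))
    labels = [k for k in CLASS_NAMES for _ in range(counts[k])]
    rng.shuffle(labels)

    # rigid drift: one integer step per stimulation event
    shifts = np.zeros((n, 2), dtype=int)
    d = config.drift_px_per_event
    step_total = np.zeros(2, dtype=int)
    for e in protocol.event_frames:
        step = rng.integers(-d, d + 1, size=2) if d > 0 else np.zeros(2, dtype=int)
        step_total = step_total + step
        shifts[e:] = step_total          # frames e+1 .. n (0-based slice from e)

    data = np.full((n, config.height_px, config.width_px), config.background_level, dtype=np.float64)
    cells: list[CellRecord] = []
    shape = (config.height_px, config.width_px)

    # epochs of constant shift, split at event frames
    bounds = [0] + [e for e in protocol.event_frames] + [n]
    for i, ((row, col), cls) in enumerate(zip(centers, labels)):
        rel, spikes, flags = _cell_trace(rng, config, protocol, cls)
        intensity = config.cell_brightness * rel
        rr, cc = _draw_disk((row, col), config.cell_radius_px + 0.5, shape=shape)
        for b0, b1 in zip(bounds, bounds[1:]):
            if b1 <= b0:
                continue
            dy, dx = shifts[b0]
            data[np.arange(b0, b1)[:, None], rr[None, :] + dy, cc[None, :] + dx] += (
                intensity[b0:b1, None]
            )
        cells.append(
            CellRecord(
                cell_id=i + 1, row=row, col=col, radius=config.cell_radius_px,
                cell_class=cls, response_flags=flags, spike_frames=spikes,
            )
        )

    if config.shot_noise:
        data = rng.poisson(np.clip(data, 0.0, None)).astype(np.float64)
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)

    excluded = np.asarray(protocol.excluded_frames, dtype=int)
    if excluded.size:
        data[excluded - 1] = config.artifact_level

    data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    movie = Movie(data=data, frame_rate_hz=config.frame_rate_hz,
                  protocol=protocol, provenance="synthetic")
    return movie, GroundTruth(cells=cells, shifts=shifts, frame_shape=shape)


@dataclass
class CohortMember:
    movie: Movie
    ground_truth: GroundTruth
    group: str                   # "chr2" | "control"
    larva_id: str


def control_config(config: SimulationConfig) -> SimulationConfig:
    """Same conditions, but zero inhibited cells (moved to the silent class)."""
    fr = dict(config.class_fractions)
    fr["silent"] = fr.get("silent", 0.0) + fr.get("inhibited", 0.0)
    fr["inhibited"] = 0.0
    return replace(config, class_fractions=fr)


def generate_cohort(
    n_chr2: int,
    n_control: int,
    config: SimulationConfig,
    protocol: StimulationProtocol,
    seed: int,
) -> list[CohortMember]:
    """Simulate a ChR2+ vs sibling-control cohort.

    Control movies share every condition (including artifact frames and the
    visual-excited fraction) but contain zero planted inhibited cells.
    Per-movie seeds are derived deterministically from ``seed``.
    """
    if n_chr2 < 1 or n_control < 1:
        raise ValueError("n_chr2 and n_control must both be >= 1")
    states = np.random.SeedSequence(seed).generate_state(n_chr2 + n_control)
    members: list[CohortMember] = []
    ctrl_cfg = control_config(config)
    for i in range(n_chr2 + n_control):
        group = "chr2" if i < n_chr2 else "control"
        base = config if group == "chr2" else ctrl_cfg
        cfg = replace(base, seed=int(states[i] % (2**31)))
        movie, gt = generate_movie(cfg, protocol)
        members.append(CohortMember(movie=movie, ground_truth=gt, group=group,
                                    larva_id=f"{group}_{i + 1:02d}"))
    return members
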