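"""Per-ROI trace extraction, ΔF/F, duplicate removal and event classification.

The classification follows the stimulus-locked template-correlation rule:
for each ROI and each stimulation event a 10-point window is taken (the 4
retained time points up to and including the event frame, plus the first 6
retained time points after the deleted stimulation block), and correlated
against model event profiles.  An ROI is called excited or inhibited only
if, for some template, the minimum Pearson r across all three events
exceeds ``r_min`` (0.6) and the maximum two-tailed p stays below ``p_max``
(0.001).  With 10-point windows the p criterion is the binding one: on 8
degrees of freedom p < 0.001 requires |r| > ~0.872.

Three model profiles are shipped: ``excited`` (transient at stimulus
onset), ``inhibited_rebound`` (suppression followed by a rebound transient)
and ``inhibited_flat`` (suppression with recovery but no rebound); both
inhibited profiles map to the final label ``inhibited``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .preprocessing import StimulationProtocol

logger = logging.getLogger(__name__)

PRE_POINTS = 4
POST_POINTS = 6
WINDOW_LEN = PRE_POINTS + POST_POINTS

TEMPLATE_CLASSES = ("excited", "inhibited_rebound", "inhibited_flat")
#: final label each template class maps to
TEMPLATE_LABELS = {
    "excited": "excited",
    "inhibited_rebound": "inhibited",
    "inhibited_flat": "inhibited",
}


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

@dataclass
class TraceSet:
    """Per-ROI raw and percent ΔF/F traces on the retained-frame timebase."""

    roi_ids: np.ndarray                  # (n,)
    raw: np.ndarray                      # (n, T) mean gray value per frame
    frame_map: np.ndarray                # retained 1-based original frames (T,)
    f0: Optional[np.ndarray] = None      # (n,) baseline per ROI
    dff: Optional[np.ndarray] = None     # (n, T) percent change
    flagged: dict = field(default_factory=dict)   # roi_id -> reason

    def index_of(self, roi_id: int) -> int:
        idx = np.flatnonzero(self.roi_ids == roi_id)
        if idx.size != 1:
            raise KeyError(f"roi_id {roi_id} not in trace set")
        return int(idx[0])


def extract_traces(movie_data, mask) -> TraceSet:
    """Mean gray value of each ROI's pixels at every time point."""
    is_arr = isinstance(movie_data, np.ndarray)
    data = np.asarray(movie_data if is_arr else getattr(movie_data, "data", movie_data))
    labels = np.asarray(mask.labels if hasattr(mask, "labels") else mask)
    if data.ndim != 3:
        raise ValueError("expected a (T, H, W) stack")
    if data.shape[1:] != labels.shape:
        raise ValueError(
            f"mask shape {labels.shape} does not match frames {data.shape[1:]}"
        )
    n_rois = int(labels.max())
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n_rois + 1)[1:]
    present = counts > 0
    raw = np.empty((n_rois, data.shape[0]), dtype=np.float64)
    for t in range(data.shape[0]):
        sums = np.bincount(flat, weights=data[t].ravel().astype(np.float64),
                           minlength=n_rois + 1)[1:]
        raw[:, t] = np.divide(sums, counts, out=np.zeros(n_rois), where=present)
    frame_map = (
        np.asarray(movie_data.protocol.retained_frames, dtype=int)
        if getattr(movie_data, "protocol", None) is not None
        and len(movie_data.protocol.retained_frames) == data.shape[0]
        else np.arange(1, data.shape[0] + 1)
    )
    return TraceSet(roi_ids=np.arange(1, n_rois + 1)[present],
                    raw=raw[present], frame_map=frame_map)


def compute_dff(traceset: TraceSet, n_baseline: int = 10) -> TraceSet:
    """Percent change ΔF/F = ((FI − F0) / F0) × 100.

    F0 is the mean of the first ``n_baseline`` retained time points.  ROIs
    with F0 ≤ 0 are flagged, logged and excluded from the returned set.
    """
    if traceset.raw.shape[1] < n_baseline:
        raise ValueError(f"need at least {n_baseline} frames to compute a baseline")
    f0 = traceset.raw[:, :n_baseline].mean(axis=1)
    good = f0 > 0
    flagged = dict(traceset.flagged)
    for roi in traceset.roi_ids[~good]:
        flagged[int(roi)] = "non-positive baseline F0"
        logger.warning("ROI %d excluded: non-positive baseline F0", roi)
    raw = traceset.raw[good]
    dff = (raw - f0[good, None]) / f0[good, None] * 100.0
    return TraceSet(roi_ids=traceset.roi_ids[good], raw=raw,
                    frame_map=traceset.frame_map, f0=f0[good], dff=dff,
                    flagged=flagged)


def remove_duplicate_rois(
    traceset: TraceSet, r_thresh: float = 0.97
) -> tuple[np.ndarray, dict]:
    """Drop ROIs whose ΔF/F correlates above ``r_thresh`` with a kept ROI.

    ROIs are visited in ascending id order; the lowest id of each correlated
    cluster survives.  Returns ``(retained_ids, drop_log)`` where the log
    maps each dropped id to the retained id it duplicated.
    """
    if traceset.dff is None:
        raise ValueError("compute_dff must run before duplicate removal")
    n = len(traceset.roi_ids)
    if n == 0:
        return traceset.roi_ids.copy(), {}
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(traceset.dff) if n > 1 else np.ones((1, 1))
    corr = np.nan_to_num(corr, nan=0.0)   # constant traces duplicate nothing
    kept: list[int] = []
    drop_log: dict[int, int] = {}
    for i in range(n):
        dup = next((j for j in kept if corr[i, j] > r_thresh), None)
        if dup is None:
            kept.append(i)
        else:
            drop_log[int(traceset.roi_ids[i])] = int(traceset.roi_ids[dup])
    return traceset.roi_ids[np.asarray(kept, dtype=int)], drop_log


# ---------------------------------------------------------------------------
# Event windows
# ---------------------------------------------------------------------------

def event_window_positions(
    protocol: StimulationProtocol,
    pre_points: int = PRE_POINTS,
    post_points: int = POST_POINTS,
) -> np.ndarray:
    """(n_events, pre+post) 0-based positions into the retained timebase.

    Each window covers the ``pre_points`` retained frames ending at the
    event frame plus the first ``post_points`` retained frames after the
    deleted stimulation block.
    """
    windows = []
    for e in protocol.event_frames:
        p = protocol.to_retained(e) - 1          # 0-based retained position
        if p < pre_points - 1 or p + post_points >= protocol.n_retained:
            raise ValueError(
                f"event at frame {e}: fewer than {pre_points} retained frames "
                f"before or {post_points} after"
            )
        windows.append(np.arange(p - pre_points + 1, p + post_points + 1))
    return np.asarray(windows, dtype=int)


def event_windows(trace: np.ndarray, protocol: StimulationProtocol) -> np.ndarray:
    """Slice one retained-timebase trace into per-event 10-point windows."""
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1 or trace.shape[0] != protocol.n_retained:
        raise ValueError("trace must be 1-D on the retained-frame timebase")
    return trace[event_window_positions(protocol)]


# ---------------------------------------------------------------------------
# Correlation and templates
# ---------------------------------------------------------------------------

def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with its two-tailed p from the t-transform (df n−2)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("inputs must be equal-length 1-D vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class TemplateProfile:
    """A 10-point model event shape (4 pre- + 6 post-stimulus points)."""

    values: np.ndarray
    class_tag: str
    n_events_averaged: int
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (WINDOW_LEN,):
            raise ValueError(f"template must have exactly {WINDOW_LEN} points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("template values must be finite")
        if np.ptp(self.values) == 0:
            raise ValueError("template is constant; correlation undefined")
        if self.class_tag not in TEMPLATE_CLASSES:
            raise ValueError(f"unknown template class {self.class_tag!r}")

    def to_dict(self) -> dict:
        return {
            "values": self.values.tolist(),
            "class_tag": self.class_tag,
            "n_events_averaged": self.n_events_averaged,
            "source": self.source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TemplateProfile":
        return cls(values=np.asarray(d["values"], dtype=np.float64),
                   class_tag=str(d["class_tag"]),
                   n_events_averaged=int(d["n_events_averaged"]),
                   source=str(d.get("source", "")))


def save_templates(templates: Sequence[TemplateProfile], path) -> None:
    with open(path, "w") as fh:
        json.dump([t.to_dict() for t in templates], fh, indent=1)


def load_templates(path) -> list[TemplateProfile]:
    with open(path) as fh:
        return [TemplateProfile.from_dict(d) for d in json.load(fh)]


def build_templates(
    labeled_windows: Sequence[tuple[np.ndarray, str]],
    n_target: int = 50,
) -> list[TemplateProfile]:
    """Average labeled event windows into one model profile per class.

    ``labeled_windows`` is a sequence of ``(10-vector, class_tag)`` pairs;
    at most ``n_target`` windows per class contribute (in input order).
    A class whose mean window is constant is rejected.
    """
    by_class: dict[str, list[np.ndarray]] = {}
    for values, tag in labeled_windows:
        if tag not in TEMPLATE_CLASSES:
            raise ValueError(f"unknown template class {tag!r}")
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (WINDOW_LEN,):
            raise ValueError(f"windows must have exactly {WINDOW_LEN} points")
        bucket = by_class.setdefault(tag, [])
        if len(bucket) < n_target:
            bucket.append(values)
    if not by_class:
        raise ValueError("no labeled windows supplied")
    templates = []
    for tag, windows in by_class.items():
        mean = np.mean(windows, axis=0)
        if np.ptp(mean) == 0:
            raise ValueError(f"template for class {tag!r} is constant (degenerate)")
        templates.append(TemplateProfile(values=mean, class_tag=tag,
                                         n_events_averaged=len(windows),
                                         source="averaged labeled windows"))
    return templates


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class RoiClassification:
    roi_id: int
    r: dict                       # class_tag -> (n_events,) Pearson r
    p: dict                       # class_tag -> (n_events,) two-tailed p
    min_r: dict                   # class_tag -> min r across events
    max_p: dict                   # class_tag -> max p across events
    label: str                    # excited | inhibited | unclassified
    matched_template: Optional[str] = None
    reason: Optional[str] = None


def classify_roi(
    windows: np.ndarray,
    templates: Sequence[TemplateProfile],
    r_min: float = 0.6,
    p_max: float = 0.001,
    roi_id: int = 0,
) -> RoiClassification:
    """Label one ROI from its per-event windows by the joint criterion.

    A template qualifies iff min r over all events > ``r_min`` AND max p
    over all events < ``p_max`` (strict inequalities).  Among qualifying
    templates the one with the largest min r wins; its class determines the
    final label.  Constant windows make the ROI unclassifiable.
    """
    windows = np.asarray(windows, dtype=np.float64)
    if windows.ndim != 2 or windows.shape[1] != WINDOW_LEN:
        raise ValueError(f"windows must be (n_events, {WINDOW_LEN})")
    if not templates:
        raise ValueError("at least one template required")
    if any(np.ptp(w) == 0 for w in windows):
        return RoiClassification(roi_id=roi_id, r={}, p={}, min_r={}, max_p={},
                                 label="unclassified", reason="constant window")
    r: dict = {}
    p: dict = {}
    for tpl in templates:
        rs, ps = zip(*(pearson_with_p(w, tpl.values) for w in windows))
        r[tpl.class_tag] = np.asarray(rs)
        p[tpl.class_tag] = np.asarray(ps)
    min_r = {tag: float(v.min()) for tag, v in r.items()}
    max_p = {tag: float(v.max()) for tag, v in p.items()}
    qualifying = [tag for tag in r if min_r[tag] > r_min and max_p[tag] < p_max]
    if qualifying:
        best = max(qualifying, key=lambda tag: min_r[tag])
        label, matched = TEMPLATE_LABELS[best], best
    else:
        label, matched = "unclassified", None
    return RoiClassification(roi_id=roi_id, r=r, p=p, min_r=min_r, max_p=max_p,
                             label=label, matched_template=matched)


def classify_traceset(
    traceset: TraceSet,
    protocol: StimulationProtocol,
    templates: Sequence[TemplateProfile],
    roi_ids: Optional[Sequence[int]] = None,
    r_min: float = 0.6,
    p_max: float = 0.001,
) -> list[RoiClassification]:
    """Classify every (retained) ROI of a ΔF/F trace set."""
    if traceset.dff is None:
        raise ValueError("compute_dff must run before classification")
    positions = event_window_positions(protocol)
    ids = traceset.roi_ids if roi_ids is None else np.asarray(list(roi_ids))
    out = []
    for roi in ids:
        windows = traceset.dff[traceset.index_of(int(roi))][positions]
        out.append(classify_roi(windows, templates, r_min=r_min, p_max=p_max,
                                roi_id=int(roi)))
    return out


# ---------------------------------------------------------------------------
# Rebound quantification
# ---------------------------------------------------------------------------

def rebound_metrics(
    windows: np.ndarray, pre_len: int = PRE_POINTS
) -> tuple[np.ndarray, float]:
    """Per-event rebound amplitude and the habituation index.

    The amplitude at event k is the maximum of the post-stimulus points
    minus the mean of the pre-stimulus points (ΔF/F %); the habituation
    index is ``(amp_1 − amp_last) / |amp_1|``, NaN when amp_1 is 0.
    """
    windows = np.asarray(windows, dtype=np.float64)
    if windows.ndim != 2 or windows.shape[1] <= pre_len:
        raise ValueError("windows must be (n_events, pre+post) with post points present")
    amplitudes = windows[:, pre_len:].max(axis=1) - windows[:, :pre_len].mean(axis=1)
    if amplitudes[0] == 0:
        return amplitudes, float("nan")
    index = (amplitudes[0] - amplitudes[-1]) / abs(amplitudes[0])
    return amplitudes, float(index)


# ---------------------------------------------------------------------------
# Reference templates from simulated training movies
# ---------------------------------------------------------------------------

def make_reference_templates(
    config,
    protocol: StimulationProtocol,
    n_movies: int = 5,
    signals_per_movie: int = 10,
    seed: int = 0,
) -> list[TemplateProfile]:
    """Build the three model profiles from dedicated training simulations.

    Per class, ``signals_per_movie`` event windows are collected from each
    of ``n_movies`` independently seeded movies (ground-truth cell
    identities select the contributing cells) and averaged — 50 signals
    over five movies at the defaults.  The flat-inhibited profile comes
    from movies whose planted rebound amplitude is zero.
    """
    from dataclasses import replace as _replace

    from .preprocessing import average_projection, exclude_stim_frames, register_translation
    from .synthetic import generate_movie

    states = np.random.SeedSequence(seed).generate_state(2 * n_movies)
    labeled: list[tuple[np.ndarray, str]] = []
    positions = event_window_positions(protocol)

    def harvest(cfg, wanted: dict[str, str]) -> None:
        movie, gt = generate_movie(cfg, protocol)
        reduced, _ = exclude_stim_frames(movie, protocol)
        registered = register_translation(reduced)
        ts = compute_dff(extract_traces(registered.data, gt.label_mask()))
        ts = _attach_protocol_framemap(ts, protocol)
        taken: dict[str, int] = {tag: 0 for tag in wanted.values()}
        for cell in gt.cells:
            tag = wanted.get(cell.cell_class)
            if tag is None or taken[tag] >= signals_per_movie:
                continue
            try:
                idx = ts.index_of(cell.cell_id)
            except KeyError:
                continue
            for window in ts.dff[idx][positions]:
                if taken[tag] >= signals_per_movie:
                    break
                labeled.append((window, tag))
                taken[tag] += 1

    for i in range(n_movies):
        cfg = _replace(config, seed=int(states[2 * i] % (2**31)))
        harvest(cfg, {"visual_excited": "excited", "inhibited": "inhibited_rebound"})
        flat_cfg = _replace(config, rebound_amplitude=0.0,
                            seed=int(states[2 * i + 1] % (2**31)))
        harvest(flat_cfg, {"inhibited": "inhibited_flat"})

    templates = build_templates(labeled, n_target=n_movies * signals_per_movie)
    for tpl in templates:
        tpl.source = f"simulated training movies (n={n_movies}, seed={seed})"
    return templates


def _attach_protocol_framemap(ts: TraceSet, protocol: StimulationProtocol) -> TraceSet:
    if ts.raw.shape[1] == protocol.n_retained:
        return replace(ts, frame_map=np.asarray(protocol.retained_frames, dtype=int))
    return ts
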