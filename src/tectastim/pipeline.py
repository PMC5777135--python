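"""End-to-end orchestration: movie -> per-ROI labels -> cohort comparison."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import GroupComparison, LarvaSummary, compare_groups, summarize_counts
from .core import Movie
from .preprocessing import (
    StimulationProtocol,
    average_projection,
    exclude_stim_frames,
    register_translation,
)
from .response import (
    RoiClassification,
    TemplateProfile,
    TraceSet,
    classify_traceset,
    compute_dff,
    extract_traces,
    remove_duplicate_rois,
)
from .segmentation import LabelMask, crop_to_region, morphological_segment
from .synthetic import CohortMember, SimulationConfig, generate_cohort


@dataclass
class MovieAnalysis:
    """Everything the single-movie pipeline produced."""

    mask: LabelMask
    traceset: TraceSet
    retained_ids: np.ndarray
    drop_log: dict
    classifications: list[RoiClassification]
    shifts: np.ndarray

    @property
    def labels(self) -> dict[int, str]:
        return {c.roi_id: c.label for c in self.classifications}

    def count(self, label: str) -> int:
        return sum(1 for c in self.classifications if c.label == label)


def analyze_movie(
    movie: Movie,
    protocol: StimulationProtocol,
    templates: Sequence[TemplateProfile],
    tolerance: float = 18.0,
    min_area_px: int = 4,
    crop: Optional[tuple[int, int, int, int]] = None,
    mask: Optional[LabelMask] = None,
    dup_r_thresh: float = 0.97,
    r_min: float = 0.6,
    p_max: float = 0.001,
) -> MovieAnalysis:
    """Run the full stimulus-locked analysis on one movie.

    Frame exclusion -> rigid registration -> average projection ->
    (optional crop) -> watershed segmentation (or an imported ``mask``) ->
    trace extraction -> ΔF/F -> duplicate removal -> template
    classification of every retained ROI.
    """
    reduced, _ = exclude_stim_frames(movie, protocol)
    registered = register_translation(reduced)
    if mask is None:
        projection = average_projection(registered.data)
        if crop is not None:
            projection, _ = crop_to_region(projection, crop)
        mask = morphological_segment(projection, tolerance=tolerance,
                                     min_area_px=min_area_px)
    data = registered.data
    if crop is not None:
        r0, c0, r1, c1 = crop
        data = data[:, r0:r1, c0:c1]
    ts = extract_traces(data, mask)
    ts.frame_map = np.asarray(protocol.retained_frames, dtype=int)
    ts = compute_dff(ts)
    retained_ids, drop_log = remove_duplicate_rois(ts, r_thresh=dup_r_thresh)
    classifications = classify_traceset(ts, protocol, templates,
                                        roi_ids=retained_ids,
                                        r_min=r_min, p_max=p_max)
    return MovieAnalysis(mask=mask, traceset=ts, retained_ids=retained_ids,
                         drop_log=drop_log, classifications=classifications,
                         shifts=registered.shifts)


@dataclass
class CohortResult:
    members: list[CohortMember]
    analyses: list[MovieAnalysis]
    summaries: list[LarvaSummary]
    comparison: GroupComparison


def run_cohort(
    n_chr2: int,
    n_control: int,
    config: SimulationConfig,
    protocol: StimulationProtocol,
    templates: Sequence[TemplateProfile],
    seed: int,
    metric: str = "inhibited",
    alpha: float = 0.05,
) -> CohortResult:
    """Simulate a cohort, analyze every movie and compare the groups."""
    members = generate_cohort(n_chr2, n_control, config, protocol, seed)
    analyses = [analyze_movie(m.movie, protocol, templates) for m in members]
    summaries = [
        summarize_counts(a.classifications, m.larva_id, m.group, protocol.pulse_kind)
        for m, a in zip(members, analyses)
    ]
    comparison = compare_groups(summaries, metric=metric, alpha=alpha)
    return CohortResult(members=members, analyses=analyses,
                        summaries=summaries, comparison=comparison)
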