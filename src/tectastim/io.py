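"""File I/O: multi-page TIFF movies, label masks, traces and reports."""

from __future__ import annotations

import json
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import Movie
from .preprocessing import StimulationProtocol
from .segmentation import LabelMask, imported_mask


def save_movie_tiff(path, movie: Movie) -> None:
    """Write a movie as a 16-bit grayscale multi-page TIFF."""
    data = np.clip(np.rint(np.asarray(movie.data, dtype=np.float64)), 0, 65535)
    tifffile.imwrite(path, data.astype(np.uint16), photometric="minisblack")


def load_movie_tiff(path, frame_rate_hz: float = 5.0,
                    protocol: Optional[StimulationProtocol] = None,
                    provenance: str = "acquired") -> Movie:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return Movie(data=data, frame_rate_hz=frame_rate_hz,
                 protocol=protocol, provenance=provenance)


def save_label_mask(path, mask: LabelMask) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.uint16), photometric="minisblack")


def load_label_mask(path) -> LabelMask:
    return imported_mask(tifffile.imread(path).astype(np.int32))


def traces_to_frame(traceset, wide: bool = True) -> pd.DataFrame:
    """ΔF/F traces as a DataFrame, wide (roi x frame) or long format."""
    if traceset.dff is None:
        raise ValueError("trace set has no ΔF/F yet")
    wide_df = pd.DataFrame(traceset.dff, index=pd.Index(traceset.roi_ids, name="roi_id"),
                           columns=pd.Index(traceset.frame_map, name="original_frame"))
    if wide:
        return wide_df
    return wide_df.stack().rename("dff").reset_index()


def classifications_to_frame(classifications) -> pd.DataFrame:
    """Per-ROI labels with per-event r/p columns for every template."""
    rows = []
    for c in classifications:
        row: dict = {"roi_id": c.roi_id, "label": c.label,
                     "matched_template": c.matched_template}
        for tag, rs in c.r.items():
            for k, r in enumerate(rs, start=1):
                row[f"r_{tag}_event{k}"] = r
                row[f"p_{tag}_event{k}"] = c.p[tag][k - 1]
            row[f"min_r_{tag}"] = c.min_r[tag]
            row[f"max_p_{tag}"] = c.max_p[tag]
        rows.append(row)
    return pd.DataFrame(rows)


def save_summaries_csv(path, summaries) -> None:
    pd.DataFrame([s.to_dict() for s in summaries]).to_csv(path, index=False)


def load_summaries_csv(path):
    from .cohort import LarvaSummary

    df = pd.read_csv(path)
    return [
        LarvaSummary(
            larva_id=str(r.larva_id), group=str(r.group),
            n_rois_total=int(r.n_rois_total), n_excited=int(r.n_excited),
            n_inhibited=int(r.n_inhibited), pulse_kind=str(r.pulse_kind),
        )
        for r in df.itertuples()
    ]


def save_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
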