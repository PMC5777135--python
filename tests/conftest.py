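import dataclasses

import numpy as np
import pytest

import tectastim as ts


@pytest.fixture(scope="session")
def long_protocol():
    return ts.build_protocol("long")


@pytest.fixture(scope="session")
def short_protocol():
    return ts.build_protocol("short")


@pytest.fixture(scope="session")
def default_config():
    return ts.SimulationConfig()


@pytest.fixture(scope="session")
def small_config():
    """Reduced scene for structural tests that do not need the full field."""
    return ts.SimulationConfig(height_px=64, width_px=64, n_cells=12, seed=5)


@pytest.fixture(scope="session")
def templates(default_config, long_protocol):
    """Reference model profiles built once from training simulations."""
    return ts.make_reference_templates(default_config, long_protocol, seed=99)


@pytest.fixture(scope="session")
def recovery_case(default_config, long_protocol, templates):
    """A long-pulse movie with 10 planted inhibited cells, fully analyzed."""
    config = dataclasses.replace(
        default_config,
        class_fractions={"visual_excited": 0.25, "inhibited": 0.10, "silent": 0.65},
        seed=101,
    )
    movie, truth = ts.generate_movie(config, long_protocol)
    analysis = ts.analyze_movie(movie, long_protocol, templates)
    return config, movie, truth, analysis


@pytest.fixture(scope="session")
def overlap_recovered():
    """Callable: was a planted cell recovered with the wanted label?

    A cell counts as recovered when any segmented ROI overlapping its planted
    disc carries the wanted final label (oversegmented fragments of one cell
    are merged by the duplicate filter, so the surviving fragment speaks for
    the cell).
    """

    def _recovered(truth, analysis, cell, wanted_label):
        gt_mask = truth.label_mask()
        rois = set(np.unique(analysis.mask.labels[gt_mask == cell.cell_id])) - {0}
        labels = analysis.labels
        return any(labels.get(int(r)) == wanted_label for r in rois)

    return _recovered
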