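import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import tectastim as ts
from tectastim.core import Movie
from tectastim.response import TraceSet


def _traceset(raw, n_frames=None):
    raw = np.asarray(raw, dtype=np.float64)
    return TraceSet(
        roi_ids=np.arange(1, raw.shape[0] + 1),
        raw=raw,
        frame_map=np.arange(1, raw.shape[1] + 1),
    )


def _window_with_exact_r(template, r, seed=0):
    """A 10-point vector with sample Pearson r to ``template`` exactly r."""
    z = (template - template.mean()) / template.std()
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(template.size)
    u -= u.mean()
    u -= (u @ z) / (z @ z) * z          # orthogonal to z and to the constant
    u /= u.std()
    return r * z + np.sqrt(1 - r**2) * u


class TestExtractTraces:
    def test_single_pixel_roi_equals_pixel_series(self):
        rng = np.random.default_rng(1)
        data = rng.random((20, 5, 5))
        mask = np.zeros((5, 5), dtype=np.int32)
        mask[2, 3] = 1
        traces = ts.extract_traces(data, mask)
        np.testing.assert_allclose(traces.raw[0], data[:, 2, 3], atol=1e-12)

    def test_constant_movie_gives_constant_traces(self):
        mask = np.zeros((4, 4), dtype=np.int32)
        mask[:2] = 1
        mask[2:] = 2
        traces = ts.extract_traces(np.full((6, 4, 4), 3.25), mask)
        np.testing.assert_allclose(traces.raw, 3.25)

    def test_matches_brute_force_label_means(self):
        rng = np.random.default_rng(2)
        data = rng.random((15, 8, 9))
        mask = rng.integers(0, 4, size=(8, 9)).astype(np.int32)
        traces = ts.extract_traces(data, mask)
        for i, roi in enumerate(traces.roi_ids):
            pix = np.argwhere(mask == roi)
            brute = np.array([data[t][tuple(pix.T)].mean() for t in range(15)])
            np.testing.assert_allclose(traces.raw[i], brute, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ts.extract_traces(np.zeros((3, 4, 4)), np.zeros((5, 5), dtype=np.int32))


class TestComputeDff:
    def test_constant_trace_gives_zero(self):
        out = ts.compute_dff(_traceset(np.full((1, 20), 100.0)))
        np.testing.assert_allclose(out.dff, 0.0)

    def test_fifty_percent_step(self):
        raw = np.concatenate([np.full(10, 100.0), np.full(10, 150.0)])
        out = ts.compute_dff(_traceset(raw[None]))
        np.testing.assert_allclose(out.dff[0, 10:], 50.0)

    def test_hand_computed_baseline(self):
        raw = np.concatenate([np.arange(95.0, 105.0), [199.0]])  # F0 = 99.5
        out = ts.compute_dff(_traceset(raw[None]))
        assert out.f0[0] == pytest.approx(99.5)
        assert out.dff[0, -1] == pytest.approx(100.0)

    def test_non_positive_baseline_flagged_and_excluded(self):
        raw = np.vstack([np.full(20, 50.0), np.zeros(20)])
        out = ts.compute_dff(_traceset(raw))
        assert list(out.roi_ids) == [1]
        assert out.flagged == {2: "non-positive baseline F0"}

    @given(
        st.integers(0, 2**31 - 1).map(np.random.default_rng),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_printed_formula_elementwise(self, rng):
        raw = rng.uniform(10.0, 200.0, size=(3, 30))
        out = ts.compute_dff(_traceset(raw))
        for i in range(3):
            f0 = raw[i, :10].sum() / 10.0
            np.testing.assert_allclose(out.dff[i], (raw[i] - f0) / f0 * 100.0, atol=1e-12)


class TestRemoveDuplicates:
    def test_identical_traces_keep_lowest_id(self):
        rng = np.random.default_rng(3)
        trace = rng.random(50) * 20 + 100
        tset = ts.compute_dff(_traceset(np.vstack([trace, trace])))
        retained, drop_log = ts.remove_duplicate_rois(tset)
        assert list(retained) == [1]
        assert drop_log == {2: 1}

    def test_independent_noise_traces_all_retained(self):
        rng = np.random.default_rng(4)
        raw = rng.normal(100.0, 5.0, size=(12, 272))
        tset = ts.compute_dff(_traceset(raw))
        retained, drop_log = ts.remove_duplicate_rois(tset)
        assert len(retained) == 12 and not drop_log

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        shared = rng.normal(0, 10, size=100)
        raw = 100 + shared + rng.normal(0, 2.0, size=(6, 100))
        tset = ts.compute_dff(_traceset(raw))
        kept = [
            len(ts.remove_duplicate_rois(tset, r_thresh=t)[0]) for t in (0.99, 0.97, 0.5)
        ]
        assert kept[0] >= kept[1] >= kept[2]

    def test_idempotent_on_retained_set(self):
        rng = np.random.default_rng(6)
        shared = rng.normal(0, 10, size=80)
        raw = 100 + shared + rng.normal(0, 1.0, size=(5, 80))
        tset = ts.compute_dff(_traceset(raw))
        retained, _ = ts.remove_duplicate_rois(tset)
        idx = [tset.index_of(int(r)) for r in retained]
        sub = TraceSet(roi_ids=retained, raw=tset.raw[idx], frame_map=tset.frame_map,
                       f0=tset.f0[idx], dff=tset.dff[idx])
        again, log = ts.remove_duplicate_rois(sub)
        assert list(again) == list(retained) and not log


class TestEventWindows:
    def test_long_pulse_window_original_frames(self, long_protocol):
        positions = ts.event_window_positions(long_protocol)
        original = np.asarray(long_protocol.retained_frames)[positions[0]]
        np.testing.assert_array_equal(original, [47, 48, 49, 50, 77, 78, 79, 80, 81, 82])

    def test_short_pulse_window_original_frames(self, short_protocol):
        positions = ts.event_window_positions(short_protocol)
        original = np.asarray(short_protocol.retained_frames)[positions[1]]
        np.testing.assert_array_equal(
            original, [147, 148, 149, 150, 153, 154, 155, 156, 157, 158]
        )

    def test_protocol_without_exclusions(self):
        protocol = ts.StimulationProtocol(
            n_frames=40, event_frames=(20,), pulse_kind="short", pulse_ms=100.0,
            retained_frames=tuple(range(1, 41)),
        )
        positions = ts.event_window_positions(protocol)
        np.testing.assert_array_equal(
            np.asarray(protocol.retained_frames)[positions[0]], list(range(17, 27))
        )

    def test_insufficient_frames_error_names_event(self):
        protocol = ts.build_protocol("short", (2,), 40)
        with pytest.raises(ValueError, match="frame 2"):
            ts.event_window_positions(protocol)

    def test_event_windows_slices_trace(self, long_protocol):
        trace = np.arange(long_protocol.n_retained, dtype=float)
        windows = ts.event_windows(trace, long_protocol)
        assert windows.shape == (3, 10)
        np.testing.assert_array_equal(windows[0], np.arange(46, 56))


class TestPearsonWithP:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = ts.pearson_with_p(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_anticorrelation(self):
        x = np.arange(10.0)
        r, _ = ts.pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_r06_n10_pvalue_matches_t_oracle(self):
        template = np.arange(10.0)
        window = _window_with_exact_r(template, 0.6)
        r, p = ts.pearson_with_p(window, template)
        assert r == pytest.approx(0.6, abs=1e-12)
        t = 0.6 * np.sqrt(8) / np.sqrt(1 - 0.36)
        assert p == pytest.approx(2 * stats.t.sf(t, df=8), rel=1e-10)
        assert p == pytest.approx(0.0667, abs=5e-4)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x, y = rng.standard_normal((2, 10))
            r, p = ts.pearson_with_p(x, y)
            xm, ym = x - x.mean(), y - y.mean()
            r_brute = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
            t = r_brute * np.sqrt(8 / (1 - r_brute**2))
            p_brute = 2 * stats.t.sf(abs(t), df=8)
            assert r == pytest.approx(r_brute, abs=1e-12)
            assert p == pytest.approx(p_brute, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ts.pearson_with_p(np.ones(10), np.arange(10.0))


class TestTemplates:
    def test_identical_windows_average_to_the_window(self):
        w = np.sin(np.arange(10.0))
        (tpl,) = ts.build_templates([(w, "excited")] * 50)
        np.testing.assert_allclose(tpl.values, w, atol=1e-12)
        assert tpl.n_events_averaged == 50

    def test_cancelling_windows_rejected_as_degenerate(self):
        w = np.sin(np.arange(10.0))
        with pytest.raises(ValueError, match="constant"):
            ts.build_templates([(w, "excited"), (-w, "excited")])

    def test_averaging_respects_standard_error_bound(self):
        rng = np.random.default_rng(8)
        shape = np.array([0, 0, 0, 0, -25, 15, 45, 60, 70, 75], dtype=float)
        sigma = 5.0
        windows = [(shape + rng.normal(0, sigma, 10), "inhibited_rebound") for _ in range(50)]
        (tpl,) = ts.build_templates(windows)
        assert np.all(np.abs(tpl.values - shape) <= 3 * sigma / np.sqrt(50))

    def test_json_roundtrip(self, tmp_path, templates):
        from tectastim.response import load_templates, save_templates

        path = tmp_path / "templates.json"
        save_templates(templates, path)
        loaded = load_templates(path)
        assert [t.class_tag for t in loaded] == [t.class_tag for t in templates]
        for a, b in zip(loaded, templates):
            np.testing.assert_allclose(a.values, b.values)

    def test_reference_templates_have_all_three_classes(self, templates):
        assert {t.class_tag for t in templates} == {
            "excited", "inhibited_rebound", "inhibited_flat"
        }
        for t in templates:
            assert t.n_events_averaged == 50


class TestClassifyRoi:
    def test_windows_equal_to_template_are_labeled(self, templates):
        inhibited = next(t for t in templates if t.class_tag == "inhibited_rebound")
        result = ts.classify_roi(np.tile(inhibited.values, (3, 1)), templates)
        assert result.label == "inhibited"
        assert result.matched_template == "inhibited_rebound"
        assert result.min_r["inhibited_rebound"] == pytest.approx(1.0)

    def test_r_passing_but_p_failing_is_unclassified(self, templates):
        # min r = 0.7 across events clears the 0.6 bar, but p(r=0.7, n=10)
        # is ~0.024 >> 0.001, so the joint criterion must reject
        tpl = templates[0]
        windows = np.stack([
            _window_with_exact_r(tpl.values, 0.7, seed=s) for s in range(3)
        ])
        result = ts.classify_roi(windows, [tpl])
        assert result.min_r[tpl.class_tag] == pytest.approx(0.7, abs=1e-9)
        assert result.max_p[tpl.class_tag] > 0.001
        assert result.label == "unclassified"

    @given(a=st.floats(-50, 50), b=st.floats(0.1, 20))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_rescaling_invariance(self, a, b, templates):
        inhibited = next(t for t in templates if t.class_tag == "inhibited_rebound")
        windows = np.tile(inhibited.values, (3, 1))
        base = ts.classify_roi(windows, templates)
        scaled = ts.classify_roi(a + b * windows, templates)
        assert scaled.label == base.label
        for tag in base.min_r:
            assert scaled.min_r[tag] == pytest.approx(base.min_r[tag], abs=1e-9)

    def test_constant_window_is_unclassifiable(self, templates):
        windows = np.zeros((3, 10))
        result = ts.classify_roi(windows, templates)
        assert result.label == "unclassified"
        assert result.reason == "constant window"


class TestReboundMetrics:
    def test_flat_windows_report_missing_index(self):
        amplitudes, index = ts.rebound_metrics(np.zeros((3, 10)))
        np.testing.assert_array_equal(amplitudes, 0.0)
        assert np.isnan(index)

    def test_planted_amplitudes_give_half_index(self):
        windows = np.zeros((3, 10))
        windows[0, 6] = 10.0
        windows[1, 6] = 7.0
        windows[2, 6] = 5.0
        amplitudes, index = ts.rebound_metrics(windows)
        np.testing.assert_allclose(amplitudes, [10.0, 7.0, 5.0])
        assert index == pytest.approx(0.5)

    def test_habituation_recovery_on_noiseless_cells(self, long_protocol):
        config = ts.SimulationConfig(
            height_px=64, width_px=64, n_cells=6,
            class_fractions={"visual_excited": 0.0, "inhibited": 1.0, "silent": 0.0},
            spontaneous_rate_hz=0.0, noise_sd=0.0, baseline_drift_pct=0.0,
            activity_noise_pct=0.0, drift_px_per_event=0, habituation_factor=0.7,
            seed=12,
        )
        movie, truth = ts.generate_movie(config, long_protocol)
        reduced, _ = ts.exclude_stim_frames(movie, long_protocol)
        tset = ts.compute_dff(ts.extract_traces(reduced.data, truth.label_mask()))
        positions = ts.event_window_positions(long_protocol)
        indices = [ts.rebound_metrics(row[positions])[1] for row in tset.dff]
        assert abs(np.median(indices) - (1 - 0.7**2)) <= 0.15
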