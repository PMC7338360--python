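"""Hand-drawn ROI traces: extraction, baselines, neuropil correction,
event detection."""

import numpy as np
import pytest

from roawake import roitraces as rt
from roawake.core import MovieStack


def movie_from(data, pixel_size=1.0, frame_rate=30.0):
    return MovieStack(np.asarray(data, dtype=np.float32), pixel_size,
                      frame_rate)


def circle(roi_id="r", kind="astro_soma", channel="astro", center=(10, 10),
           radius=4.0):
    return rt.RoiDefinition(roi_id, kind, channel, center=center,
                            radius=radius)


class TestExtractTrace:
    def test_uniform_frame_returns_frame_value(self):
        data = np.ones((5, 20, 20)) * np.arange(1, 6)[:, None, None]
        tr = rt.extract_trace(movie_from(data), circle())
        np.testing.assert_allclose(tr, [1, 2, 3, 4, 5])

    def test_single_pixel_roi_is_that_series(self, rng):
        data = rng.random((10, 20, 20)).astype(np.float32) + 1
        roi = circle(radius=0.8, center=(7, 3))
        tr = rt.extract_trace(movie_from(data), roi)
        np.testing.assert_allclose(tr, data[:, 3, 7], rtol=1e-6)

    def test_union_mean_is_area_weighted(self, rng):
        data = rng.random((6, 40, 40)).astype(np.float32) + 1
        mv = movie_from(data)
        a = circle("a", center=(8, 8), radius=3)
        b = circle("b", center=(30, 30), radius=5)
        ma, mb = a.mask((40, 40)), b.mask((40, 40))
        tr_a, tr_b = rt.extract_trace(mv, a), rt.extract_trace(mv, b)
        union = data[:, ma | mb].mean(axis=1)
        want = (tr_a * ma.sum() + tr_b * mb.sum()) / (ma.sum() + mb.sum())
        np.testing.assert_allclose(union, want, rtol=1e-6)

    def test_polygon_roi_and_validation(self):
        poly = rt.RoiDefinition("p", "astro_soma", "astro",
                                vertices=np.array([[2, 2], [12, 2],
                                                   [12, 12], [2, 12]]))
        m = poly.mask((20, 20))
        assert m.sum() > 50
        with pytest.raises(ValueError, match="kind"):
            rt.RoiDefinition("x", "blob", "astro", center=(1, 1), radius=1)
        with pytest.raises(ValueError, match="circle"):
            rt.RoiDefinition("x", "astro_soma", "astro")


class TestDffAndNeuropil:
    def test_constant_trace_gives_zeros(self):
        assert not rt.dff_trace(np.full(100, 3.0)).any()

    def test_mode_baseline_with_transient(self, rng):
        f = np.full(2000, 2.0) + 0.01 * rng.standard_normal(2000)
        f[500:550] = 3.0
        dff = rt.dff_trace(f)
        assert dff[520] == pytest.approx(0.5, abs=0.05)
        assert np.median(dff) == pytest.approx(0.0, abs=0.02)

    def test_scale_invariance(self, rng):
        f = 2.0 + 0.1 * rng.random(1000)
        np.testing.assert_allclose(rt.dff_trace(2 * f), rt.dff_trace(f),
                                   atol=1e-9)

    def test_neuropil_correction_formula(self):
        fn = np.array([2.0, 3.0, 4.0])
        fd = np.array([2.0, 2.0, 2.0])
        np.testing.assert_allclose(rt.neuropil_correct(fn, fd, 2.0),
                                   [0.0, 0.5, 1.0])
        np.testing.assert_allclose(rt.neuropil_correct(fd + 2.0, fd, 2.0),
                                   1.0)

    def test_doughnut_is_annulus_of_5um(self):
        soma = circle(radius=4.0, center=(20, 20))
        d = rt.doughnut_roi(soma, pixel_size=1.0)
        assert d.radius == pytest.approx(9.0)
        mv = movie_from(np.ones((3, 40, 40)))
        tr = rt.annulus_trace(mv, soma)
        np.testing.assert_allclose(tr, 1.0)


class TestPlaceNeuropil:
    def test_circles_respect_radius_and_clearance(self):
        soma = [circle("s", center=(30, 30), radius=6.0)]
        rois = rt.place_neuropil_rois(soma, (64, 64), pixel_size=1.0,
                                      n_rois=5, seed=0)
        assert len(rois) == 5
        for roi in rois:
            assert roi.radius == pytest.approx(5.0)
            d = np.hypot(roi.center[0] - 30, roi.center[1] - 30)
            assert d >= 6.0 + 5.0 + 5.0 - 1e-9


class TestDetectTraceEvents:
    fs = 30.0

    def _noise(self, n=6000, sd=0.02, seed=0):
        return sd * np.random.default_rng(seed).standard_normal(n)

    def test_single_transient_detected_with_peak_amplitude(self):
        dff = self._noise()
        t = np.arange(60) / self.fs
        bump = 0.5 * np.sin(np.pi * t / 2) ** 2
        dff[3000:3060] += bump
        events = rt.detect_trace_events(dff, self.fs, "astro")
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(0.5, rel=0.2)
        assert abs(events[0].onset_s - 100.0) < 1.0

    def test_two_transients_split_by_zero_return(self):
        dff = self._noise()
        for t0 in (2000, 2400):
            dff[t0:t0 + 40] += 0.5
        events = rt.detect_trace_events(dff, self.fs, "astro")
        assert len(events) == 2

    def test_pure_noise_false_event_rate(self):
        # astro settings on white noise: below 0.5 events per minute
        n_events = 0
        minutes = 0.0
        for seed in range(20):
            dff = self._noise(seed=seed)
            n_events += len(rt.detect_trace_events(dff, self.fs, "astro"))
            minutes += dff.size / self.fs / 60.0
        assert n_events / minutes < 0.5

    def test_threshold_monotonicity_astro_vs_neuron(self):
        # the neuron threshold (2 SD) can only admit more events than a
        # 2.5 SD threshold on the same trace and smoothing
        dff = self._noise(seed=4)
        dff[1000:1040] += 0.08
        a = rt.detect_trace_events(dff, self.fs, "astro")
        n = rt.detect_trace_events(dff, self.fs, "neuron")
        assert len(n) >= len(a)

    def test_unknown_sensor_rejected(self):
        with pytest.raises(ValueError, match="sensor"):
            rt.detect_trace_events(self._noise(), self.fs, "voltage")


class TestOnsetHistogram:
    def test_single_coincident_event_in_zero_bin(self):
        edges, counts = rt.onset_difference_histogram(
            np.array([50.0]), np.array([50.0]))
        zero_bin = np.searchsorted(edges, 0.0, side="right") - 1
        assert counts[zero_bin] == 1
        assert counts.sum() == 1

    def test_no_astro_events_empty(self):
        _, counts = rt.onset_difference_histogram(np.array([]),
                                                  np.array([10.0, 20.0]))
        assert counts.sum() == 0

    def test_uniform_astro_events_flat_histogram(self, rng):
        astro = rng.uniform(0, 10_000, size=5000)
        neuron = rng.uniform(100, 9900, size=40)
        _, counts = rt.onset_difference_histogram(astro, neuron)
        expected = counts.mean()
        assert counts.std() < 0.35 * expected


class TestRoaVersusRoiComparability:
    def test_roa_detects_many_more_microdomain_events(self):
        """Small events outside a soma ROI: whole-field ROA detection sees
        them, a static soma-ROI trace does not."""
        from roawake import roa, synth
        cfg = synth.SimulationConfig(
            image_shape=(48, 48), pixel_size=1.0,
            state_schedule=[("quiet", 60.0)],
            event_rate_per_state={"quiet": 1.5},
            vessel_mask_fraction=0.0, seed=21)
        movie, truth, _ = synth.generate_movie(cfg)
        soma = circle("soma", center=(24, 24), radius=6.0)
        # keep the soma region event-free: regenerate events far away by
        # masking detection instead - events landing inside are rare anyway
        res = roa.detect(movie)
        n_roa = len(res.events)
        f = rt.extract_trace(movie, soma)
        dff = rt.dff_trace(f)
        n_roi = len(rt.detect_trace_events(dff, movie.frame_rate, "astro"))
        assert n_roa >= 5 * max(n_roi, 1)
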