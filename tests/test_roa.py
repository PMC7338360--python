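"""The detection chain, step by step, against analytic and brute-force
oracles."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from roawake import roa
from roawake.core import MovieStack


def movie_from(data, pixel_size=1.0, frame_rate=30.0):
    return MovieStack(np.asarray(data, dtype=np.float32), pixel_size,
                      frame_rate)


def noise_movie(shape=(600, 32, 32), baseline=100.0, sigma=5.0, seed=0,
                frame_rate=30.0, pixel_size=1.0):
    rng = np.random.default_rng(seed)
    data = baseline + sigma * rng.standard_normal(shape).astype(np.float32)
    return MovieStack(data, pixel_size, frame_rate)


class TestSpatialSmooth:
    def test_sigma_zero_is_identity(self, rng):
        mv = noise_movie((10, 16, 16), seed=3)
        out = roa.spatial_smooth(mv, 0.0)
        np.testing.assert_array_equal(out.data, mv.data)

    def test_impulse_matches_separable_gaussian_kernel(self):
        frame = np.zeros((1, 33, 33))
        frame[0, 16, 16] = 1.0
        out = roa.spatial_smooth(movie_from(np.repeat(frame, 2, axis=0)),
                                 2.0)
        imp = np.zeros(33)
        imp[16] = 1.0
        k1d = gaussian_filter1d(imp, 2.0)
        np.testing.assert_allclose(out.data[0], np.outer(k1d, k1d),
                                   atol=1e-6)

    def test_constant_frame_unchanged_and_sum_preserved(self, rng):
        mv = movie_from(np.full((3, 32, 32), 7.0))
        out = roa.spatial_smooth(mv, 2.0)
        np.testing.assert_allclose(out.data, 7.0, rtol=1e-5)
        blob = noise_movie((3, 64, 64), baseline=50, sigma=1, seed=1)
        sm = roa.spatial_smooth(blob, 2.0)
        assert sm.data[0].sum() == pytest.approx(blob.data[0].sum(),
                                                 rel=1e-3)


class TestBaselineAndDff:
    def test_constant_movie_baseline(self):
        mv = movie_from(np.full((100, 4, 4), 3.0))
        f0, _ = roa.compute_baseline(mv, 1.0)
        np.testing.assert_allclose(f0, 3.0, atol=0.05)

    def test_mode_picks_majority_level(self, rng):
        data = np.full((1000, 2, 2), 1.0, dtype=np.float32)
        data[900:] = 3.0  # a 10% block at the high level
        data += 0.001 * rng.standard_normal(data.shape).astype(np.float32)
        f0, _ = roa.compute_baseline(movie_from(data), 0.2)
        np.testing.assert_allclose(f0, 1.0, atol=0.1)

    def test_window_must_fit_recording(self):
        mv = movie_from(np.ones((10, 2, 2)))
        with pytest.raises(ValueError):
            roa.compute_baseline(mv, 10.0)

    @pytest.mark.parametrize("f, f0, want", [(2.0, 2.0, 0.0),
                                             (4.0, 2.0, 1.0),
                                             (12.0, 10.0, 0.2)])
    def test_dff_arithmetic(self, f, f0, want):
        mv = movie_from(np.full((5, 2, 2), f))
        s = roa.compute_dff(mv, np.full((2, 2), f0))
        np.testing.assert_allclose(s, want, rtol=1e-6)

    def test_nonpositive_baseline_is_floored(self):
        mv = movie_from(np.full((5, 2, 2), 1.0))
        f0 = np.array([[1.0, 1.0], [0.0, -2.0]])
        s = roa.compute_dff(mv, f0)
        assert np.isfinite(s).all()


class TestEstimateNoise:
    def test_sigma_recovers_scaled_noise_sd(self, rng):
        sigma0 = 0.37
        s = sigma0 * rng.standard_normal((3000, 8, 8))
        noise, _ = roa.estimate_noise(s, frame_rate=30.0,
                                      baseline_window_s=1.0)
        # SD(S_HP) = sigma0 * sqrt(1 - 1/L); the map divides by sqrt(L)
        want = sigma0 * np.sqrt(1 - 1 / 30) / np.sqrt(30)
        np.testing.assert_allclose(noise.sigma, want, rtol=0.10)

    def test_constant_series_yields_zero_sigma(self):
        noise, _ = roa.estimate_noise(np.zeros((100, 3, 3)), 30.0, 1.0)
        assert (noise.sigma == 0).all()
        assert noise.n_degenerate == 9

    def test_scale_equivariance(self, rng):
        s = rng.standard_normal((500, 4, 4))
        n1, _ = roa.estimate_noise(s, 30.0, 1.0)
        n2, _ = roa.estimate_noise(2 * s, 30.0, 1.0)
        np.testing.assert_allclose(n2.sigma, 2 * n1.sigma, rtol=1e-9)


class TestDetrend:
    def test_linear_ramp_removed_in_interior(self):
        t = np.arange(900, dtype=float)
        slope = 0.01
        s = np.tile(t[:, None, None], (1, 2, 2)) * slope
        out = roa.detrend(s, frame_rate=30.0, drift_window_s=10.0)
        # an even window length (300 frames) centres on a half sample, so
        # the residual is exactly half a frame's worth of slope
        assert np.abs(out[200:-200]).max() <= 0.5 * slope + 1e-9

    def test_constant_maps_to_zero(self):
        out = roa.detrend(np.full((400, 2, 2), 5.0), 30.0, 10.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_frequency_response_matches_closed_form(self):
        # |1 - Dirichlet(f)| with Dirichlet(f) = sin(pi f L/fs)/(L sin(pi f/fs))
        fs, L = 30.0, 300
        t = np.arange(18000) / fs
        for f in (0.02, 2.0):
            x = np.sin(2 * np.pi * f * t)[:, None, None]
            y = roa.detrend(x, fs, 10.0)[3000:-3000, 0, 0]
            gain = y.std() * np.sqrt(2)
            dirich = np.sin(np.pi * f * L / fs) / (
                L * np.sin(np.pi * f / fs))
            assert gain == pytest.approx(abs(1 - dirich), abs=0.02)
        # the slow component is suppressed, the fast one passed
        slow = np.sin(2 * np.pi * 0.02 * t)[:, None, None]
        fast = np.sin(2 * np.pi * 2.0 * t)[:, None, None]
        g_slow = roa.detrend(slow, fs, 10.0)[3000:-3000].std()
        g_fast = roa.detrend(fast, fs, 10.0)[3000:-3000].std()
        assert g_fast > 10 * g_slow


class TestThreshold:
    def test_empty_when_everything_below(self):
        s_bp = np.zeros((50, 4, 4))
        noise = roa.NoiseMap(np.ones((4, 4)))
        mask = roa.threshold_activity(s_bp, noise, k=5.0)
        assert not mask.active.any()

    def test_gaussian_tail_exceedance(self, rng):
        # strict one-sided k=5 exceedance on N(0, sigma) is ~2.9e-7
        s = rng.standard_normal((1000, 100, 100))
        noise = roa.NoiseMap(np.ones((100, 100)))
        mask = roa.threshold_activity(s, noise, k=5.0)
        assert mask.active.mean() < 1e-4

    def test_monotone_in_k_and_ignore_mask(self, rng):
        s = rng.standard_normal((60, 8, 8))
        noise = roa.NoiseMap(0.3 * np.ones((8, 8)))
        ignore = np.zeros((8, 8), dtype=bool)
        ignore[:2] = True
        m4 = roa.threshold_activity(s, noise, 1.0, ignore)
        m5 = roa.threshold_activity(s, noise, 1.5, ignore)
        assert (m5.active <= m4.active).all()
        assert not m4.active[:, ignore].any()

    def test_rejects_bad_k(self, rng):
        with pytest.raises(ValueError):
            roa.threshold_activity(np.zeros((5, 2, 2)),
                                   roa.NoiseMap(np.ones((2, 2))), k=0.0)


def flood_fill_components(active, connectivity):
    """Brute-force oracle: BFS over the voxel adjacency graph."""
    offsets = []
    for dt in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dt, dy, dx) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dt) + abs(dy) + abs(dx) != 1:
                    continue
                offsets.append((dt, dy, dx))
    labels = np.zeros(active.shape, dtype=int)
    nxt = 0
    T, H, W = active.shape
    for idx in zip(*np.nonzero(active)):
        if labels[idx]:
            continue
        nxt += 1
        stack = [idx]
        labels[idx] = nxt
        while stack:
            t, y, x = stack.pop()
            for dt, dy, dx in offsets:
                u, v, w = t + dt, y + dy, x + dx
                if 0 <= u < T and 0 <= v < H and 0 <= w < W \
                        and active[u, v, w] and not labels[u, v, w]:
                    labels[u, v, w] = nxt
                    stack.append((u, v, w))
    return labels


class TestExtractRoas:
    def test_single_voxel_descriptor_arithmetic(self):
        active = np.zeros((10, 5, 5), dtype=bool)
        active[4, 2, 3] = True
        evs = roa.extract_roas(roa.ActivityMask(active), 1.0, 30.0)
        assert len(evs) == 1
        ev = evs[0]
        assert ev.start_frame == 4
        assert ev.duration_s == pytest.approx(1 / 30)
        assert ev.footprint_area_um2 == pytest.approx(1.0)
        assert ev.volume_um2s == pytest.approx(1 / 30)

    def test_face_adjacent_voxels_in_time_merge_either_way(self):
        active = np.zeros((6, 3, 3), dtype=bool)
        active[2, 1, 1] = active[3, 1, 1] = True
        for conn in (6, 26):
            evs = roa.extract_roas(roa.ActivityMask(active), 1.0, 30.0,
                                   connectivity=conn)
            assert len(evs) == 1
            assert evs[0].duration_s == pytest.approx(2 / 30)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle_on_random_masks(self, connectivity):
        rng = np.random.default_rng(17)
        for _ in range(100):
            active = rng.random((20, 16, 16)) < 0.08
            evs = roa.extract_roas(roa.ActivityMask(active), 1.0, 30.0,
                                   connectivity=connectivity)
            oracle = flood_fill_components(active, connectivity)
            assert len(evs) == oracle.max()
            # identical partition: component size multisets agree
            sizes = sorted(np.bincount(oracle.ravel())[1:].tolist())
            assert sorted(e.n_voxels for e in evs) == sizes

    def test_voxel_conservation(self, rng):
        active = rng.random((30, 12, 12)) < 0.1
        evs = roa.extract_roas(roa.ActivityMask(active), 1.0, 30.0)
        assert sum(e.n_voxels for e in evs) == int(active.sum())

    def test_max_instant_extent_mode(self):
        active = np.zeros((4, 4, 4), dtype=bool)
        active[0, 0, :3] = True    # 3 px frame 0
        active[1, 0, :2] = True    # 2 px frame 1 (overlapping column)
        evs = roa.extract_roas(roa.ActivityMask(active), 1.0, 1.0,
                               extent_mode="max_instant")
        assert evs[0].footprint_area_um2 == pytest.approx(3.0)
        evs2 = roa.extract_roas(roa.ActivityMask(active), 1.0, 1.0)
        assert evs2[0].footprint_area_um2 == pytest.approx(3.0)


class TestDetect:
    def test_end_to_end_determinism(self):
        mv = noise_movie((400, 24, 24), seed=8)
        r1 = roa.detect(mv)
        r2 = roa.detect(mv)
        assert [e.bbox for e in r1.events] == [e.bbox for e in r2.events]
        assert np.array_equal(r1.mask.active, r2.mask.active)

    def test_noiseless_single_event_recovered(self):
        from roawake import synth
        cfg = synth.SimulationConfig(
            image_shape=(32, 32), pixel_size=1.0,
            state_schedule=[("quiet", 30.0)],
            event_rate_per_state={"quiet": 0.0}, noise_sigma=0.0,
            drift_amplitude=0.0, vessel_mask_fraction=0.0, seed=0)
        movie, _, _ = synth.generate_movie(cfg)
        data = movie.data.copy()
        # one hand-placed blob event well inside the valid frame range
        t0, dur = 450, 30
        yy, xx = np.mgrid[-6:7, -6:7]
        blob = np.exp(-(yy ** 2 + xx ** 2) / (2 * 2.0 ** 2))
        prof = np.linspace(1, 0.2, dur)
        data[t0:t0 + dur, 10:23, 10:23] += \
            (50 * blob)[None] * prof[:, None, None].astype(np.float32)
        res = roa.detect(MovieStack(data, 1.0, 30.0))
        assert len(res.events) == 1
        ev = res.events[0]
        # the centred 1 s moving average lets the detection lead the true
        # onset by up to half a window
        assert abs(ev.start_frame - t0) <= 15
        assert ev.bbox[2] <= 16 <= ev.bbox[3]
        assert ev.bbox[4] <= 16 <= ev.bbox[5]

    def test_event_count_monotone_in_k(self, small_session):
        mv = small_session.movie
        vessels = small_session.vessel_mask
        n4 = len(roa.detect(mv, roa.RoaParams(k=4.0), vessels).events)
        n5 = len(roa.detect(mv, roa.RoaParams(k=5.0), vessels).events)
        a4 = roa.detect(mv, roa.RoaParams(k=4.0), vessels).mask.active.sum()
        a5 = roa.detect(mv, roa.RoaParams(k=5.0), vessels).mask.active.sum()
        assert a5 <= a4
        assert n5 <= n4 + 5  # fragment merging can shift counts slightly

    def test_edge_margin_frames_are_inactive(self):
        mv = noise_movie((400, 16, 16), seed=2)
        res = roa.detect(mv)
        m0, m1 = res.mask.edge_margin_frames
        assert m0 > 0 and m1 > 0
        assert not res.mask.active[:m0].any()
        assert not res.mask.active[-m1:].any()
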