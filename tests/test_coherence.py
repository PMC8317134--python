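"""Segment grid, cross-spectra and imaginary-coherency estimator."""

import numpy as np
import pytest

import betabalance as bb
from betabalance.coherence import (SegmentSchedule, cross_spectra,
                                   independence_bias_bound, ipc,
                                   ipc_window_means, segment_grid)

from conftest import make_epochs

FS = 1000.0


class TestSegmentGrid:
    def test_pre_window_has_six_canonical_centres(self):
        pre, _ = segment_grid()
        np.testing.assert_allclose(pre, [-388, -312, -236, -160, -84, -8])

    def test_post_window_has_five_canonical_centres(self):
        _, post = segment_grid()
        np.testing.assert_allclose(post, [144, 220, 296, 372, 448])

    def test_window_without_grid_member_is_empty(self):
        _, post = segment_grid(post_win_ms=(0.0, 50.0))
        assert post.size == 0

    def test_advance_is_76_samples_with_nominal_76_8_ms(self):
        sched = SegmentSchedule()
        assert sched.step_samples == 76
        assert sched.nominal_step_ms(FS) == pytest.approx(76.8)

    def test_frequency_resolution_is_1_3_hz(self):
        assert SegmentSchedule().freq_resolution_hz(FS) == pytest.approx(
            1.302, abs=5e-4)


class TestCrossSpectra:
    def test_identical_channels_have_equal_cross_and_auto_spectra(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 5, 3000))
        e = make_epochs(np.concatenate([x, x]), labels=["Cz", "AFz"])
        cs = cross_spectra(e, "Cz", "AFz", [-8.0])
        np.testing.assert_allclose(np.real(cs.sxy), cs.sxx, rtol=1e-10)
        np.testing.assert_allclose(np.imag(cs.sxy), 0.0, atol=1e-10)

    def test_pure_tone_concentrates_at_nearest_bin(self):
        t = (np.arange(3000) - 1000) / FS
        x = np.sin(2 * np.pi * 20.0 * t)
        e = make_epochs(np.tile(x, (2, 1, 1)), labels=["Cz", "AFz"])
        cs = cross_spectra(e, "Cz", "AFz", [144.0])
        peak_bin = np.argmax(np.abs(cs.sxy[0]))
        assert cs.frequencies[peak_bin] == pytest.approx(20.0, abs=0.66)

    def test_out_of_bounds_segment_names_its_centre(self):
        rng = np.random.default_rng(0)
        e = make_epochs(rng.standard_normal((2, 3, 3000)), labels=["Cz", "AFz"])
        with pytest.raises(ValueError, match="1900"):
            cross_spectra(e, "Cz", "AFz", [1900.0])


class TestIPC:
    def test_zero_lag_identical_channels_below_bias_bound(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((1, 22, 3000))
        e = make_epochs(np.concatenate([x, x]), labels=["Cz", "AFz"])
        _, pre, post = bb.pair_ipc(e, "Cz", "AFz")
        bound = independence_bias_bound(22)
        assert pre <= bound and post <= bound

    def test_zero_lag_common_source_mixture_below_bias_bound(self):
        # volume-conduction null: a common source mixed with zero lag into both
        # channels must not raise band IPC above the independence bias bound
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((2, 22, 3000))
        common = rng.standard_normal((22, 3000))
        e = make_epochs(np.stack([a + 0.9 * common, b + 0.6 * common]),
                        labels=["Cz", "AFz"])
        _, pre, post = bb.pair_ipc(e, "Cz", "AFz")
        bound = independence_bias_bound(22)
        assert pre <= bound and post <= bound

    def test_independent_channels_at_1000_trials_below_0_05(self):
        cfg = bb.SyntheticEEGConfig(n_trials=1000, seed=3)
        e, _ = bb.gen_epochs(cfg)
        _, pre, post = bb.pair_ipc(e, "AFz", "Cz")
        assert pre < 0.05 and post < 0.05

    def test_scale_invariance(self):
        cfg = bb.SyntheticEEGConfig(coupling_gain=0.7, seed=4)
        e, _ = bb.gen_epochs(cfg)
        _, pre1, post1 = bb.pair_ipc(e, "AFz", "Cz")
        e.data[0] *= 123.0
        e.data[1] *= 0.007
        _, pre2, post2 = bb.pair_ipc(e, "AFz", "Cz")
        assert abs(pre1 - pre2) < 1e-9 and abs(post1 - post2) < 1e-9

    def test_symmetry_in_channel_order(self):
        cfg = bb.SyntheticEEGConfig(coupling_gain=0.7, seed=5)
        e, _ = bb.gen_epochs(cfg)
        _, preA, postA = bb.pair_ipc(e, "AFz", "Cz")
        _, preB, postB = bb.pair_ipc(e, "Cz", "AFz")
        assert preA == pytest.approx(preB, abs=1e-12)
        assert postA == pytest.approx(postB, abs=1e-12)

    def test_lagged_coupling_raises_post_window_ipc(self):
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            e, _ = bb.gen_epochs(bb.SyntheticEEGConfig(coupling_gain=0.8,
                                                       seed=seed))
            _, pre, post = bb.pair_ipc(e, "AFz", "Cz")
            hits += post > pre
        assert hits >= 0.95 * n_runs

    def test_single_trial_rejected(self):
        rng = np.random.default_rng(0)
        e = make_epochs(rng.standard_normal((2, 1, 3000)), labels=["Cz", "AFz"])
        cs = cross_spectra(e, "Cz", "AFz", [-8.0])
        with pytest.raises(ValueError):
            ipc(cs)

    def test_estimator_consistency_with_trials(self):
        # SE of the band estimate shrinks toward the long-run value
        cfg = bb.SyntheticEEGConfig(coupling_gain=0.8, seed=6)
        vals = {}
        for n in (50, 800):
            e, _ = bb.gen_epochs(
                bb.SyntheticEEGConfig(coupling_gain=0.8, n_trials=n, seed=6))
            _, _, vals[n] = bb.pair_ipc(e, "AFz", "Cz")
        ref = bb.oracle_ipc(cfg, n_trials=6000, batch_size=2000)
        assert abs(vals[800] - ref) < abs(vals[50] - ref) + 0.02
        assert abs(vals[800] - ref) < 0.04


class TestWindowMeans:
    def _series(self, band_values, centers):
        freqs = np.fft.rfftfreq(768, 1 / FS)
        band = (freqs >= 13) & (freqs <= 30)
        ipc_map = np.zeros((freqs.size, len(centers)))
        ipc_map[band] = np.asarray(band_values)[None, :]
        return bb.IPCSeries(frequencies=freqs, centers_ms=np.asarray(centers),
                            ipc=ipc_map, band_series=np.asarray(band_values,
                                                                dtype=float),
                            pair="AFz-Cz")

    def test_constant_series(self):
        pre_c, post_c = segment_grid()
        centers = np.concatenate([pre_c, post_c])
        s = self._series(np.full(centers.size, 0.3), centers)
        pre, post = ipc_window_means(s, pre_c, post_c)
        assert pre == pytest.approx(0.3) and post == pytest.approx(0.3)

    def test_index_series_arithmetic(self):
        pre_c, post_c = segment_grid()
        centers = np.concatenate([pre_c, post_c])
        s = self._series(np.arange(centers.size, dtype=float), centers)
        pre, post = ipc_window_means(s, pre_c, post_c)
        assert pre == pytest.approx(np.mean(np.arange(6)))
        assert post == pytest.approx(np.mean(np.arange(6, 11)))

    def test_missing_centre_is_error(self):
        pre_c, post_c = segment_grid()
        s = self._series(np.zeros(pre_c.size), pre_c)
        with pytest.raises(ValueError):
            ipc_window_means(s, pre_c, post_c)
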