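"""Synthetic generator: fixture fidelity, determinism, injections, responder."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import betabalance as bb
from betabalance.synthetic_data import (BEHAVIOR_COLUMNS, SyntheticEEGConfig,
                                        gen_behavior, gen_epochs,
                                        logistic_responder,
                                        paper_behavior_fixture,
                                        paper_table1_raw)


class TestPaperFixture:
    def test_fifteen_retained_participants(self):
        fix = paper_behavior_fixture()
        assert len(fix) == 15
        assert list(fix.columns) == BEHAVIOR_COLUMNS

    def test_row_c01_values(self):
        row = paper_behavior_fixture().set_index("id").loc["C01"]
        assert row["tug_single"] == pytest.approx(6.8)
        assert row["tug_dual"] == pytest.approx(6.78)
        assert row["step_threshold"] == pytest.approx(18)

    def test_row_c03_interference_seconds(self):
        row = paper_behavior_fixture().set_index("id").loc["C03"]
        assert row["dti_s"] == pytest.approx(-3.3)

    def test_interference_identities_hold(self):
        fix = paper_behavior_fixture()
        np.testing.assert_allclose(fix["dti_s"],
                                   -(fix["tug_dual"] - fix["tug_single"]),
                                   atol=1e-9)
        np.testing.assert_allclose(fix["dti_pct"],
                                   100 * fix["dti_s"] / fix["tug_single"],
                                   atol=1e-9)

    def test_eleven_female(self):
        assert (paper_table1_raw()["gender"] == "F").sum() == 11


class TestGenBehavior:
    CORR = np.array([[1.0, 0.38, 0.47], [0.38, 1.0, 0.76], [0.47, 0.76, 1.0]])

    def test_planted_correlation_recovered_at_large_n(self):
        t = gen_behavior(10_000, self.CORR, seed=1)
        r = sps.pearsonr(t["dti_pct"], t["step_threshold"])[0]
        assert r == pytest.approx(0.76, abs=0.02)

    def test_independent_target_gives_near_zero_r(self):
        n = 2000
        t = gen_behavior(n, np.eye(3), seed=2)
        assert abs(sps.pearsonr(t["dti_pct"], t["step_threshold"])[0]) < 3 / np.sqrt(n)

    def test_same_seed_identical_tables(self):
        a = gen_behavior(50, self.CORR, seed=3)
        b = gen_behavior(50, self.CORR, seed=3)
        assert a.equals(b)

    def test_interference_identities_and_ranges(self):
        t = gen_behavior(500, self.CORR, seed=4)
        np.testing.assert_allclose(t["dti_s"], -(t["tug_dual"] - t["tug_single"]),
                                   atol=1e-9)
        np.testing.assert_allclose(t["dti_pct"], 100 * t["dti_s"] / t["tug_single"],
                                   atol=1e-9)
        assert t["minibest"].between(0, 28).all()
        assert t["step_threshold"].between(6, 18).all()
        assert (t["tug_single"] > 0).all() and (t["tug_dual"] > 0).all()

    def test_non_psd_matrix_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError):
            gen_behavior(10, bad, seed=0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            gen_behavior(2, self.CORR, seed=0)


class TestGenEpochs:
    def test_fixed_seed_bitwise_identical(self):
        cfg = SyntheticEEGConfig(burst_gain_db=6.0, coupling_gain=0.5, seed=8)
        a, _ = gen_epochs(cfg)
        b, _ = gen_epochs(cfg)
        assert np.array_equal(a.data, b.data)

    def test_shapes_and_labels(self):
        e, truth = gen_epochs(SyntheticEEGConfig(seed=0))
        assert e.data.shape == (3, 22, 3000)
        assert e.labels == ["AFz", "Cz", "CPz"]
        assert e.onset_index == 1000
        assert truth.seed == 0

    def test_burst_confined_to_window(self):
        cfg = SyntheticEEGConfig(burst_gain_db=6.0, seed=3)
        with_burst, _ = gen_epochs(cfg)
        without, _ = gen_epochs(SyntheticEEGConfig(burst_gain_db=0.0, seed=3))
        t1, s1 = bb.beta_series(bb.ersp(with_burst, "Cz"))
        _, s0 = bb.beta_series(bb.ersp(without, "Cz"))
        lo, hi = cfg.burst_window_ms
        outside = (t1 < lo - 150) | (t1 > hi + 150)
        assert np.abs((s1 - s0)[outside]).max() < 1.0

    def test_line_noise_injection_and_removal(self):
        from betabalance.preprocess import ContinuousEEG, notch_60

        e, _ = gen_epochs(SyntheticEEGConfig(line_noise_amp=20.0, seed=5))
        trial = e.data[:, 0, :]
        spec = np.abs(np.fft.rfft(trial[1]))
        freqs = np.fft.rfftfreq(trial.shape[-1], 1 / e.fs)
        bin60 = np.argmin(np.abs(freqs - 60))
        assert spec[bin60] > 10 * np.median(spec)
        cleaned = notch_60(ContinuousEEG(data=trial, labels=e.labels, fs=e.fs))
        spec_c = np.abs(np.fft.rfft(cleaned.data[1]))
        assert spec_c[bin60] < 0.05 * spec[bin60]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticEEGConfig(burst_window_ms=(1500.0, 2500.0))
        with pytest.raises(ValueError):
            SyntheticEEGConfig(coupling_partner="Oz")
        with pytest.raises(ValueError):
            SyntheticEEGConfig(labels=("A", "B", "C"))
        with pytest.raises(ValueError):
            SyntheticEEGConfig(coupling_gain=-1.0)

    def test_background_spectrum_slopes_down(self):
        e, _ = gen_epochs(SyntheticEEGConfig(seed=9))
        spec = np.mean(np.abs(np.fft.rfft(e.data[0], axis=-1)) ** 2, axis=0)
        freqs = np.fft.rfftfreq(3000, 1e-3)
        low = spec[(freqs >= 2) & (freqs < 8)].mean()
        high = spec[(freqs >= 32) & (freqs < 128)].mean()
        assert low > 4 * high


class TestLogisticResponder:
    def test_midpoint_probability_is_half(self):
        resp = logistic_responder(12.0, 1.0, seed=0)
        frac = np.mean([resp(12.0) for _ in range(20_000)])
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_closed_form_at_one_slope_above(self):
        resp = logistic_responder(12.0, 1.0, seed=1)
        frac = np.mean([resp(13.0) for _ in range(10_000)])
        assert frac == pytest.approx(1 / (1 + np.exp(-1)), abs=0.01)

    def test_steep_slope_approaches_hard_threshold(self):
        resp = logistic_responder(12.0, 1e-9, seed=2)
        assert all(resp(12.001) for _ in range(100))
        assert not any(resp(11.999) for _ in range(100))

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            logistic_responder(12.0, 0.0, seed=0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_deterministic_stream_per_seed(self, seed):
        a = [logistic_responder(10.0, 2.0, seed)(m) for m in (8, 9, 10, 11, 12)]
        b = [logistic_responder(10.0, 2.0, seed)(m) for m in (8, 9, 10, 11, 12)]
        assert a == b
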