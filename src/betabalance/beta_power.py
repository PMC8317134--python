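"""Morlet-wavelet event-related spectral perturbation (ERSP) and beta summaries.

The decomposition follows the perturbation-EEG convention: 10 linearly spaced
frequencies from 12 to 50 Hz, a tapered complex Morlet wavelet whose cycle
count grows linearly from 3 at 12 Hz to 6 at 50 Hz, truncated to a 256 ms
support, with power sampled on a 14 ms grid and expressed as 10*log10(uV^2).
Beta power is the mean of the ERSP rows at the four sampled frequencies
nearest 16, 20, 24 and 29 Hz (16.22, 20.44, 24.67, 28.89 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import EEGEpochs

#: analysis frequencies, Hz (10 linearly spaced values over 12-50 Hz)
FREQS_HZ = np.linspace(12.0, 50.0, 10)
#: wavelet cycle count at each frequency: 3 at 12 Hz rising linearly to 6 at 50 Hz
CYCLES = 3.0 + 3.0 * (FREQS_HZ - 12.0) / 38.0
#: sliding-window support, ms
SUPPORT_MS = 256.0
#: output time grid step, ms
GRID_STEP_MS = 14.0
#: ERSP row indices averaged to index the beta band (16.22-28.89 Hz)
BETA_ROW_SLICE = slice(1, 5)

BASELINE_WINDOW_MS = (-500.0, 0.0)    # half-open [start, stop)
WINDOW_OVERALL_MS = (100.0, 500.0)    # inclusive
WINDOW_EARLY_MS = (100.0, 300.0)
WINDOW_LATE_MS = (300.0, 500.0)


@dataclass
class ERSPMap:
    """Frequency x time power map in dB for one channel."""

    frequencies: np.ndarray   # Hz
    times_ms: np.ndarray      # uniform 14 ms grid
    power_db: np.ndarray      # (n_freqs, n_times)
    channel: str

    def __post_init__(self) -> None:
        if self.power_db.shape != (self.frequencies.size, self.times_ms.size):
            raise ValueError("power map shape mismatch")
        if not np.all(np.isfinite(self.power_db)):
            raise ValueError("non-finite power values")


@dataclass
class BetaPowerSummary:
    """Baseline beta power and baseline-subtracted peaks per analysis window."""

    baseline_db: float
    peak_overall_db: float   # max change over 100-500 ms
    peak_early_db: float     # max change over 100-300 ms
    peak_late_db: float      # max change over 300-500 ms


def morlet_wavelet(freq_hz: float, cycles: float, fs: float,
                   n_samples: int | None = None) -> np.ndarray:
    """Complex Morlet wavelet truncated/tapered to an ``n_samples`` support.

    The Gaussian envelope has standard deviation cycles / (2*pi*f) seconds.
    Normalised so a unit-amplitude sinusoid at ``freq_hz`` yields unit power
    (0 dB).
    """
    if n_samples is None:
        n_samples = int(round(SUPPORT_MS / 1000.0 * fs))
    t = (np.arange(n_samples) - (n_samples - 1) / 2.0) / fs
    sigma = cycles / (2.0 * np.pi * freq_hz)
    envelope = np.exp(-(t ** 2) / (2.0 * sigma ** 2))
    w = envelope * np.exp(2j * np.pi * freq_hz * t)
    return w * (2.0 / envelope.sum())


def _grid_sample_indices(e: EEGEpochs, n_taps: int) -> np.ndarray:
    """Sample indices of the 14 ms output grid, restricted to centres whose
    full wavelet support lies inside the epoch (no padding)."""
    half_lo = n_taps // 2          # samples needed before the centre
    half_hi = n_taps - half_lo - 1  # samples needed after
    step = GRID_STEP_MS / 1000.0 * e.fs
    n_lo = int(np.ceil((half_lo - e.onset_index) / step))
    n_hi = int(np.floor((e.n_samples - 1 - half_hi - e.onset_index) / step))
    if n_hi < n_lo:
        raise ValueError("epoch too short for the wavelet support")
    k = np.arange(n_lo, n_hi + 1)
    return e.onset_index + np.round(k * step).astype(int)


def ersp(e: EEGEpochs, channel: str) -> ERSPMap:
    """Trial-averaged wavelet power map for one channel, in dB.

    Per trial and frequency the signal is convolved with the tapered Morlet
    wavelet; squared magnitudes are averaged across trials and sampled on the
    14 ms grid.  The output grid is restricted to times where the 256 ms
    support fits inside the epoch, so the pre-perturbation baseline is free of
    edge artifacts.
    """
    ci = e.channel_index(channel)
    if e.n_trials < 1:
        raise ValueError("no kept trials")
    x = e.data[ci]                      # (n_trials, n_samples)
    n_taps = int(round(SUPPORT_MS / 1000.0 * e.fs))
    centres = _grid_sample_indices(e, n_taps)
    half_lo = n_taps // 2
    power = np.empty((FREQS_HZ.size, centres.size))
    for fi, (f, c) in enumerate(zip(FREQS_HZ, CYCLES)):
        w = morlet_wavelet(f, c, e.fs, n_taps)
        # full convolution with the reversed conjugate wavelet makes
        # full[:, n + n_taps - 1 - half_lo] the inner product centred at n
        full = signal.fftconvolve(x, np.conj(w)[::-1][None, :], axes=1)
        coef = full[:, centres + (n_taps - 1 - half_lo)]
        power[fi] = np.mean(np.abs(coef) ** 2, axis=0)
    times_ms = (centres - e.onset_index) / e.fs * 1000.0
    return ERSPMap(frequencies=FREQS_HZ.copy(), times_ms=times_ms,
                   power_db=10.0 * np.log10(power), channel=channel)


def beta_series(m: ERSPMap) -> tuple[np.ndarray, np.ndarray]:
    """Beta-band power time course: mean of the ERSP rows at the 2nd-5th
    sampled frequencies.  Returns (times_ms, series_db)."""
    return m.times_ms.copy(), m.power_db[BETA_ROW_SLICE].mean(axis=0)


def beta_summary(times_ms: np.ndarray, series_db: np.ndarray,
                 baseline_ms: tuple[float, float] = BASELINE_WINDOW_MS,
                 windows_ms: tuple[tuple[float, float], ...] = (
                     WINDOW_OVERALL_MS, WINDOW_EARLY_MS, WINDOW_LATE_MS),
                 ) -> BetaPowerSummary:
    """Scalar baseline (mean over −500 to 0 ms) and baseline-subtracted peaks.

    Peaks are pointwise maxima on the 14 ms grid, no interpolation.  Window
    bounds are inclusive; the baseline window is half-open at 0.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    series_db = np.asarray(series_db, dtype=float)
    base_mask = (times_ms >= baseline_ms[0]) & (times_ms < baseline_ms[1])
    if not base_mask.any():
        raise ValueError("series does not cover the baseline window")
    baseline = float(series_db[base_mask].mean())
    peaks = []
    for lo, hi in windows_ms:
        mask = (times_ms >= lo) & (times_ms <= hi)
        if not mask.any():
            raise ValueError(f"series does not cover window [{lo}, {hi}] ms")
        peaks.append(float((series_db[mask] - baseline).max()))
    return BetaPowerSummary(baseline_db=baseline, peak_overall_db=peaks[0],
                            peak_early_db=peaks[1], peak_late_db=peaks[2])


def channel_beta_summary(e: EEGEpochs, channel: str = "Cz") -> BetaPowerSummary:
    """Convenience: ERSP -> beta series -> summary for one channel."""
    t, s = beta_series(ersp(e, channel))
    return beta_summary(t, s)
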