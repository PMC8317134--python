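"""Segment-based imaginary part of coherency (IPC) between electrode pairs.

IPC is the magnitude of the imaginary component of the normalised trial-
ensemble cross-spectrum.  Because a zero-lag (volume-conducted) common source
produces a purely real coherency, IPC is insensitive to it — the reason this
conservative estimator is used for closely spaced midline electrodes.

Segments are 768 samples long with 0.9 overlap.  The advance is rounded down
to 76 samples (the nominal 76.8 ms advance is carried in metadata) and the
grid is anchored so that −8 ms is the final pre-perturbation segment centre;
this reproduces the canonical centres −388…−8 ms (six pre-perturbation
segments) and 144…448 ms (five post-perturbation segments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocess import EEGEpochs

BETA_BAND_HZ = (13.0, 30.0)
PRE_WINDOW_MS = (-400.0, 0.0)    # half-open [start, stop)
POST_WINDOW_MS = (100.0, 500.0)  # inclusive


@dataclass
class SegmentSchedule:
    """Segment length / overlap schedule for time-resolved cross-spectra."""

    seg_len: int = 768
    overlap: float = 0.9
    anchor_ms: float = -8.0

    def __post_init__(self) -> None:
        if not 0 < self.overlap < 1:
            raise ValueError("overlap must be in (0, 1)")
        if self.seg_len < 2:
            raise ValueError("seg_len must be >= 2")

    @property
    def step_samples(self) -> int:
        """Integer segment advance (768 x 0.1 = 76.8 -> 76 samples)."""
        return int(self.seg_len * (1.0 - self.overlap))

    def step_ms(self, fs: float) -> float:
        return self.step_samples / fs * 1000.0

    def nominal_step_ms(self, fs: float) -> float:
        """Un-rounded advance (76.8 ms at 1 kHz), reported in metadata."""
        return self.seg_len * (1.0 - self.overlap) / fs * 1000.0

    def freq_resolution_hz(self, fs: float) -> float:
        return fs / self.seg_len


@dataclass
class CrossSpectra:
    """Trial-averaged auto/cross spectra on the segment grid."""

    frequencies: np.ndarray        # Hz, resolution fs / seg_len
    centers_ms: np.ndarray
    sxx: np.ndarray                # (n_centers, n_bins), real
    syy: np.ndarray
    sxy: np.ndarray                # complex
    n_trials: int
    pair: tuple[str, str]


@dataclass
class IPCSeries:
    """|Im(coherency)| per (frequency bin, segment centre) plus the beta-band mean."""

    frequencies: np.ndarray
    centers_ms: np.ndarray
    ipc: np.ndarray                # (n_bins, n_centers), values in [0, 1]
    band_series: np.ndarray        # per-centre mean over 13-30 Hz bins
    pair: str
    meta: dict = field(default_factory=dict)


def segment_grid(pre_win_ms: tuple[float, float] = PRE_WINDOW_MS,
                 post_win_ms: tuple[float, float] = POST_WINDOW_MS,
                 sched: SegmentSchedule | None = None,
                 fs: float = 1000.0) -> tuple[np.ndarray, np.ndarray]:
    """Segment centres inside the pre ([−400, 0) ms, half-open) and post
    ([100, 500] ms, inclusive) windows.

    The grid is anchor + k * step for integer k.  Empty intersections return
    empty arrays.
    """
    sched = sched or SegmentSchedule()
    step = sched.step_ms(fs)
    lo = min(pre_win_ms[0], post_win_ms[0]) - step
    hi = max(pre_win_ms[1], post_win_ms[1]) + step
    k_lo = int(np.floor((lo - sched.anchor_ms) / step))
    k_hi = int(np.ceil((hi - sched.anchor_ms) / step))
    grid = sched.anchor_ms + np.arange(k_lo, k_hi + 1) * step
    pre = grid[(grid >= pre_win_ms[0]) & (grid < pre_win_ms[1])]
    post = grid[(grid >= post_win_ms[0]) & (grid <= post_win_ms[1])]
    return pre, post


def cross_spectra(e: EEGEpochs, ch_a: str, ch_b: str,
                  centers_ms, sched: SegmentSchedule | None = None) -> CrossSpectra:
    """Hann-tapered per-centre spectra averaged across trials.

    Each segment spans centre ± seg_len/2 (half-open on the right) and is
    demeaned before tapering.  The expectation in the coherency quotient is
    the trial ensemble, preserving per-centre time resolution.
    """
    sched = sched or SegmentSchedule()
    ia, ib = e.channel_index(ch_a), e.channel_index(ch_b)
    centers_ms = np.atleast_1d(np.asarray(centers_ms, dtype=float))
    taper = signal.windows.hann(sched.seg_len, sym=False)
    half = sched.seg_len // 2
    freqs = np.fft.rfftfreq(sched.seg_len, d=1.0 / e.fs)
    sxx = np.empty((centers_ms.size, freqs.size))
    syy = np.empty_like(sxx)
    sxy = np.empty((centers_ms.size, freqs.size), dtype=complex)
    for k, c_ms in enumerate(centers_ms):
        c = e.onset_index + int(round(c_ms / 1000.0 * e.fs))
        start, stop = c - half, c + (sched.seg_len - half)
        if start < 0 or stop > e.n_samples:
            raise ValueError(f"segment centred at {c_ms} ms exceeds epoch bounds")
        seg_a = e.data[ia, :, start:stop]
        seg_b = e.data[ib, :, start:stop]
        seg_a = (seg_a - seg_a.mean(axis=1, keepdims=True)) * taper
        seg_b = (seg_b - seg_b.mean(axis=1, keepdims=True)) * taper
        fa = np.fft.rfft(seg_a, axis=1)
        fb = np.fft.rfft(seg_b, axis=1)
        sxx[k] = np.mean(np.abs(fa) ** 2, axis=0)
        syy[k] = np.mean(np.abs(fb) ** 2, axis=0)
        sxy[k] = np.mean(fa * np.conj(fb), axis=0)
    return CrossSpectra(frequencies=freqs, centers_ms=centers_ms, sxx=sxx,
                        syy=syy, sxy=sxy, n_trials=e.n_trials, pair=(ch_a, ch_b))


def ipc(spectra: CrossSpectra, band_hz: tuple[float, float] = BETA_BAND_HZ) -> IPCSeries:
    """|Im(Sxy / sqrt(Sxx * Syy))| per bin/centre, with the beta-band mean.

    The band comprises every bin whose centre frequency lies in
    [13, 30] Hz inclusive.
    """
    if spectra.n_trials < 2:
        raise ValueError("IPC requires trial-averaged spectra from >= 2 trials")
    denom = spectra.sxx * spectra.syy
    if np.any(denom <= 0):
        raise ValueError("zero auto-spectrum encountered")
    coherency = spectra.sxy / np.sqrt(denom)
    values = np.abs(np.imag(coherency)).T          # (n_bins, n_centers)
    band = (spectra.frequencies >= band_hz[0]) & (spectra.frequencies <= band_hz[1])
    if not band.any():
        raise ValueError("no frequency bin inside the requested band")
    sched = SegmentSchedule()
    return IPCSeries(
        frequencies=spectra.frequencies.copy(),
        centers_ms=spectra.centers_ms.copy(),
        ipc=values,
        band_series=values[band].mean(axis=0),
        pair=f"{spectra.pair[0]}-{spectra.pair[1]}",
        meta={
            "band_hz": list(band_hz),
            "n_trials": spectra.n_trials,
            "freq_resolution_hz": float(spectra.frequencies[1] - spectra.frequencies[0]),
            "nominal_step_ms": sched.nominal_step_ms(1000.0),
            "step_samples": sched.step_samples,
        },
    )


def ipc_window_means(s: IPCSeries, pre_centers_ms, post_centers_ms) -> tuple[float, float]:
    """Mean band IPC over the six pre- and five post-perturbation centres."""
    def _mean(centers):
        centers = np.atleast_1d(np.asarray(centers, dtype=float))
        vals = []
        for c in centers:
            hits = np.isclose(s.centers_ms, c)
            if not hits.any():
                raise ValueError(f"centre {c} ms missing from the series")
            vals.append(s.band_series[hits][0])
        return float(np.mean(vals))

    return _mean(pre_centers_ms), _mean(post_centers_ms)


def independence_bias_bound(n_trials: int) -> float:
    """Upper bound used for independence/zero-lag nulls: 1/sqrt(n) + 0.05.

    The |Im coherency| estimator is positively biased at finite trial counts;
    under independence its magnitude scales like 1/sqrt(n_trials).
    """
    return 1.0 / np.sqrt(n_trials) + 0.05


def pair_ipc(e: EEGEpochs, ch_a: str, ch_b: str,
             sched: SegmentSchedule | None = None) -> tuple[IPCSeries, float, float]:
    """Convenience: spectra on the full pre+post grid -> IPC -> window means."""
    sched = sched or SegmentSchedule()
    pre, post = segment_grid(sched=sched, fs=e.fs)
    spectra = cross_spectra(e, ch_a, ch_b, np.concatenate([pre, post]), sched)
    series = ipc(spectra)
    pre_ipc, post_ipc = ipc_window_means(series, pre, post)
    return series, pre_ipc, post_ipc
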