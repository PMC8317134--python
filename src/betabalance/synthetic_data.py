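"""Synthetic perturbation-EEG epochs and behavioral tables with known ground truth.

The generator emulates the study conditions every downstream stage expects:
three midline channels (AFz, Cz, CPz) epoched −1 to 2 s around perturbation
onset at 1,000 Hz, a 1/f background, an injectable non-phase-locked beta-band
power burst at Cz (calibrated empirically against the generator's own band-
power measurement), an injectable phase-lagged shared beta source between Cz
and a partner channel (the volume-conduction null uses the zero-lag switch),
optional 60 Hz line noise, and behavioral tables with a planted correlation
structure.  The printed participant table of the source study ships as a
packaged CSV fixture.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, special

from . import coherence
from .preprocess import EEGEpochs

#: behavior-table CSV dialect (exact column order)
BEHAVIOR_COLUMNS = ["id", "age", "minibest", "tug_single", "tug_dual",
                    "dti_s", "dti_pct", "step_threshold"]

#: standardized perturbation protocol constants (platform translation)
PERTURBATION_MAGNITUDE_CM = 7.5
PERTURBATION_VELOCITY_CM_S = 16.0
PERTURBATION_ACCEL_G = 0.12
PERTURBATIONS_DELIVERED = 24

_BG_STD_UV = 10.0       # background RMS, a realistic scalp-EEG scale
_RAMP_MS = 50.0         # raised-cosine onset ramp of the shared source


@dataclass
class SyntheticEEGConfig:
    """Ground-truth parameters for one synthetic participant's epochs."""

    n_channels: int = 3
    labels: tuple[str, ...] = ("AFz", "Cz", "CPz")
    n_trials: int = 22
    fs: float = 1000.0
    epoch_span: tuple[float, float] = (-1.0, 2.0)
    background_exponent: float = 1.0
    burst_gain_db: float = 0.0
    burst_window_ms: tuple[float, float] = (100.0, 500.0)
    coupling_gain: float = 0.0
    coupling_partner: str = "AFz"
    coupling_lag_ms: float = 12.5     # quarter period at 20 Hz
    coupling_source_rel: float = 1.0  # shared-source amplitude at Cz, relative
                                      # to the background beta-band RMS
    line_noise_amp: float = 0.0
    seed: int = 0
    # perturbation protocol metadata
    magnitude_cm: float = PERTURBATION_MAGNITUDE_CM
    velocity_cm_s: float = PERTURBATION_VELOCITY_CM_S
    accel_g: float = PERTURBATION_ACCEL_G

    def __post_init__(self) -> None:
        if self.n_channels < 3 or len(self.labels) != self.n_channels:
            raise ValueError("need >= 3 channels with matching labels")
        for required in ("AFz", "Cz", "CPz"):
            if required not in self.labels:
                raise ValueError(f"labels must include {required!r}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.epoch_span[0] < 0 < self.epoch_span[1]:
            raise ValueError("epoch span must straddle the onset")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.coupling_gain < 0:
            raise ValueError("coupling_gain must be >= 0")
        span_ms = (self.epoch_span[0] * 1000.0, self.epoch_span[1] * 1000.0)
        if not (span_ms[0] <= self.burst_window_ms[0] < self.burst_window_ms[1] <= span_ms[1]):
            raise ValueError("burst window outside the epoch span")
        if self.coupling_partner not in self.labels:
            raise ValueError(f"unknown channel label {self.coupling_partner!r}")


@dataclass
class SyntheticTruth:
    """What was injected, for parameter-recovery tests."""

    burst_gain_db: dict[str, float]
    coupling: dict[tuple[str, str], tuple[float, float]]  # pair -> (gain, lag ms)
    seed: int
    burst_scale: float = 0.0
    oracle_ipc: dict[tuple[str, str], float] = field(default_factory=dict)


def _one_over_f(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                fs: float, exponent: float) -> np.ndarray:
    """1/f^exponent (power) noise via spectral shaping, unit RMS."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal(shape + (n_samples,))
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * amp, n=n_samples, axis=-1)
    shaped /= shaped.std(axis=-1, keepdims=True)
    return shaped


def _beta_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                fs: float) -> np.ndarray:
    """Band-limited (13-30 Hz) Gaussian noise, unit RMS."""
    sos = signal.butter(4, coherence.BETA_BAND_HZ, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(shape + (n_samples,)), axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _beta_wavelet_coefs(x: np.ndarray, fs: float, onset: int) -> tuple[np.ndarray, np.ndarray]:
    """Wavelet coefficients of the beta-band analysis rows on the output grid.

    Returns (times_ms, coefs) with coefs shaped (n_beta_freqs, n_trials,
    n_grid).  This is the measurement the generator calibrates against — the
    same wavelets, grid and band rows the downstream power stage uses.
    """
    from . import beta_power

    n_samples = x.shape[-1]
    n_taps = int(round(beta_power.SUPPORT_MS / 1000.0 * fs))
    shim = EEGEpochs(data=np.zeros((1, 1, n_samples)), labels=["_"], fs=fs,
                     span_s=(-onset / fs, (n_samples - onset) / fs),
                     onset_index=onset)
    centres = beta_power._grid_sample_indices(shim, n_taps)
    half_lo = n_taps // 2
    beta_freqs = beta_power.FREQS_HZ[beta_power.BETA_ROW_SLICE]
    beta_cycles = beta_power.CYCLES[beta_power.BETA_ROW_SLICE]
    coefs = np.empty((beta_freqs.size,) + x.shape[:-1] + (centres.size,), dtype=complex)
    for fi, (f, c) in enumerate(zip(beta_freqs, beta_cycles)):
        w = beta_power.morlet_wavelet(f, c, fs, n_taps)
        full = signal.fftconvolve(x, np.conj(w)[::-1][None, :], axes=-1)
        coefs[fi] = full[..., centres + (n_taps - 1 - half_lo)]
    times_ms = (centres - onset) / fs * 1000.0
    return times_ms, coefs


def _fractional_delay(x: np.ndarray, delay_samples: float) -> np.ndarray:
    """Delay along the last axis by a possibly fractional number of samples
    (circular, applied in the frequency domain; the wrap-around lies in the
    epoch edges, outside every analysis window)."""
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n)
    shift = np.exp(-2j * np.pi * freqs * delay_samples)
    return np.fft.irfft(np.fft.rfft(x, axis=-1) * shift, n=n, axis=-1)


def gen_epochs(cfg: SyntheticEEGConfig) -> tuple[EEGEpochs, SyntheticTruth]:
    """Generate one synthetic participant's epochs plus the injected truth.

    Background: independent per-channel 1/f noise.  Burst: 13-30 Hz noise under
    a raised-cosine (Hann) envelope over the burst window, scaled by bisection
    so the measured peak beta-power rise at Cz matches ``burst_gain_db``.
    Shared source: one beta-band signal added to Cz and, delayed by
    ``coupling_lag_ms`` and scaled by ``coupling_gain``, to the partner
    channel, active only post-onset.  Bit-reproducible per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round((cfg.epoch_span[1] - cfg.epoch_span[0]) * cfg.fs))
    onset = int(round(-cfg.epoch_span[0] * cfg.fs))
    t_ms = (np.arange(n_samples) - onset) / cfg.fs * 1000.0

    data = _BG_STD_UV * _one_over_f(
        rng, (cfg.n_channels, cfg.n_trials), n_samples, cfg.fs, cfg.background_exponent)
    cz = cfg.labels.index("Cz")

    truth = SyntheticTruth(
        burst_gain_db={lab: 0.0 for lab in cfg.labels},
        coupling={}, seed=cfg.seed)

    # shared beta source (drawn before the burst so draws stay seed-stable
    # whether or not the burst is active)
    if cfg.coupling_gain > 0:
        source = _beta_noise(rng, (cfg.n_trials,), n_samples, cfg.fs)
        lag_samples = cfg.coupling_lag_ms / 1000.0 * cfg.fs
        delayed = _fractional_delay(source, lag_samples)
        env = np.zeros(n_samples)
        post = t_ms >= 0
        env[post] = 1.0
        ramp_n = int(round(_RAMP_MS / 1000.0 * cfg.fs))
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        first_post = np.argmax(post)
        env[first_post:first_post + ramp_n] = ramp
        beta_rms = _beta_band_rms(data[cz], cfg.fs)
        amp = cfg.coupling_source_rel * beta_rms
        data[cz] += amp * env * source
        partner = cfg.labels.index(cfg.coupling_partner)
        data[partner] += cfg.coupling_gain * amp * env * delayed
        truth.coupling[("Cz", cfg.coupling_partner)] = (cfg.coupling_gain,
                                                        cfg.coupling_lag_ms)

    if cfg.burst_gain_db != 0.0:
        scale = _inject_burst(data[cz], cfg, t_ms, rng)
        truth.burst_gain_db["Cz"] = cfg.burst_gain_db
        truth.burst_scale = scale

    if cfg.line_noise_amp > 0:
        phase = rng.uniform(0, 2 * np.pi, size=cfg.n_trials)
        line = cfg.line_noise_amp * np.sin(
            2 * np.pi * 60.0 * t_ms[None, :] / 1000.0 + phase[:, None])
        data += line[None, :, :]

    epochs = EEGEpochs(data=data, labels=list(cfg.labels), fs=cfg.fs,
                       span_s=cfg.epoch_span, onset_index=onset)
    return epochs, truth


def _beta_band_rms(x: np.ndarray, fs: float) -> float:
    sos = signal.butter(4, coherence.BETA_BAND_HZ, btype="bandpass", fs=fs, output="sos")
    return float(signal.sosfiltfilt(sos, x, axis=-1).std())


def _inject_burst(cz_data: np.ndarray, cfg: SyntheticEEGConfig, t_ms: np.ndarray,
                  rng: np.random.Generator) -> float:
    """Add the calibrated beta burst to Cz in place; return the found scale.

    Calibration loop: bisect the burst amplitude until the beta-power time
    course measured with the analysis wavelets shows a peak rise over the
    burst window of ``burst_gain_db`` dB relative to the pre-perturbation
    baseline (to 0.005 dB).  Because power is quadratic in the amplitude, the
    wavelet transforms of background and burst are taken once and recombined
    per candidate amplitude.
    """
    lo_ms, hi_ms = cfg.burst_window_ms
    env = np.zeros_like(t_ms)
    in_win = (t_ms >= lo_ms) & (t_ms <= hi_ms)
    phase = (t_ms[in_win] - lo_ms) / (hi_ms - lo_ms)
    env[in_win] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    burst = env[None, :] * _beta_noise(rng, (cz_data.shape[0],), t_ms.size, cfg.fs)

    onset = int(np.argmin(np.abs(t_ms)))
    grid_ms, ca = _beta_wavelet_coefs(cz_data, cfg.fs, onset)
    _, cb = _beta_wavelet_coefs(burst, cfg.fs, onset)
    base_mask = (grid_ms >= -500.0) & (grid_ms < 0.0)
    win_mask = (grid_ms >= lo_ms) & (grid_ms <= hi_ms)
    pa = np.mean(np.abs(ca) ** 2, axis=1)        # (n_freqs, n_grid)
    pab = np.mean(np.real(ca * np.conj(cb)), axis=1)
    pb = np.mean(np.abs(cb) ** 2, axis=1)

    def measured_gain(scale: float) -> float:
        series = np.mean(10.0 * np.log10(pa + 2 * scale * pab + scale ** 2 * pb),
                         axis=0)
        return series[win_mask].max() - series[base_mask].mean()

    target = cfg.burst_gain_db
    lo, hi = 0.0, _BG_STD_UV
    while measured_gain(hi) < target:
        hi *= 2.0
        if hi > 1e4 * _BG_STD_UV:
            raise RuntimeError("burst calibration failed to bracket the target")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if measured_gain(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6 or abs(measured_gain(0.5 * (lo + hi)) - target) < 0.005:
            break
    scale = 0.5 * (lo + hi)
    cz_data += scale * burst
    return scale


# -- behavioral tables -------------------------------------------------------

def paper_table1_raw() -> pd.DataFrame:
    """The packaged participant-characteristics fixture, exactly as printed
    (15 retained participants; the printed dual-task interference column is in
    seconds)."""
    with importlib.resources.files("betabalance.data").joinpath(
            "table1_participants.csv").open() as fh:
        return pd.read_csv(fh)


def paper_behavior_fixture() -> pd.DataFrame:
    """Fixture participants in the behavior-table dialect.

    ``dti_pct`` is recomputed from the TUG columns; the recomputed ``dti_s``
    agrees with the printed interference column to the printed precision.
    """
    raw = paper_table1_raw()
    dti_s = -(raw["tug_dual"] - raw["tug_single"])
    if not np.allclose(dti_s, raw["dti_s_printed"], atol=5e-3):
        raise AssertionError("fixture inconsistent with printed interference column")
    out = pd.DataFrame({
        "id": raw["id"],
        "age": raw["age"],
        "minibest": raw["minibest"].astype(int),
        "tug_single": raw["tug_single"],
        "tug_dual": raw["tug_dual"],
        "dti_s": dti_s,
        "dti_pct": dti_s / raw["tug_single"] * 100.0,
        "step_threshold": raw["step_threshold"],
    })
    return out[BEHAVIOR_COLUMNS]


def _corr_factor(target_corr: np.ndarray) -> np.ndarray:
    c = np.asarray(target_corr, dtype=float)
    if c.shape != (3, 3) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
        raise ValueError("target_corr must be symmetric 3x3 with unit diagonal")
    vals, vecs = np.linalg.eigh(c)
    if vals.min() < -1e-10:
        raise ValueError("target_corr is not positive semi-definite")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def gen_behavior(n: int, target_corr, seed: int = 0) -> pd.DataFrame:
    """Behavior table with a planted correlation structure.

    A latent trivariate normal over (minibest, dti_pct, step_threshold) is
    mapped to marginal scales matching the fixture group rows; ``tug_dual`` is
    derived from the drawn ``dti_pct`` so the interference identities hold
    exactly.  Deterministic per seed.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    factor = _corr_factor(target_corr)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 3)) @ factor.T
    fix = paper_behavior_fixture()

    minibest = np.clip(np.round(fix["minibest"].mean() + fix["minibest"].std() * z[:, 0]),
                       0, 28).astype(int)
    dti_pct = fix["dti_pct"].mean() + fix["dti_pct"].std() * z[:, 1]
    # sd tightened below the fixture's so the [6, 18] cm clamp is rarely active
    # and the planted correlation survives the transform
    step_threshold = np.clip(12.0 + 2.5 * z[:, 2], 6.0, 18.0)
    tug_single = np.clip(rng.normal(8.5, 1.8, size=n), 3.0, None)
    tug_dual = tug_single * (1.0 - dti_pct / 100.0)
    dti_s = -(tug_dual - tug_single)
    age = np.clip(np.round(rng.normal(69.0, 8.0, size=n)), 50, 95).astype(int)

    return pd.DataFrame({
        "id": [f"S{i + 1:04d}" for i in range(n)],
        "age": age,
        "minibest": minibest,
        "tug_single": tug_single,
        "tug_dual": tug_dual,
        "dti_s": dti_s,
        "dti_pct": dti_pct,
        "step_threshold": step_threshold,
    })[BEHAVIOR_COLUMNS]


def write_behavior_csv(table: pd.DataFrame, path) -> None:
    table[BEHAVIOR_COLUMNS].to_csv(path, index=False)


def read_behavior_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"behavior CSV missing columns {missing}")
    return table[BEHAVIOR_COLUMNS]


# -- step-response process ---------------------------------------------------

def logistic_responder(theta: float, slope: float, seed: int = 0):
    """Stand-in for a participant in the staircase: queried at magnitude m,
    steps with probability 1 / (1 + exp(-(m - theta)/slope)).

    Deterministic stream per seed.  ``slope -> 0`` approaches a hard threshold
    at ``theta``.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    rng = np.random.default_rng(seed)

    def respond(magnitude_cm: float) -> bool:
        p = special.expit((magnitude_cm - theta) / slope)
        return bool(rng.random() < p)

    return respond


# -- long-run oracle ---------------------------------------------------------

def oracle_ipc(cfg: SyntheticEEGConfig, n_trials: int = 100_000,
               batch_size: int = 2_000) -> float:
    """Long-run post-window band IPC for the configured coupled pair.

    The oracle is the same segment-grid estimator run at a very large trial
    count: auto/cross spectra are accumulated over independent batches of the
    configured generator and the coherency quotient is formed at the end.
    Populates (and returns) the value SyntheticTruth carries for that pair.
    """
    sched = coherence.SegmentSchedule()
    _, post = coherence.segment_grid(sched=sched, fs=cfg.fs)
    sxx = syy = sxy = None
    total = 0
    n_batches = int(np.ceil(n_trials / batch_size))
    for b in range(n_batches):
        nb = min(batch_size, n_trials - total)
        sub = replace(cfg, n_trials=nb, seed=int((cfg.seed * 1_000_003 + b) % 2**31))
        epochs, _ = gen_epochs(sub)
        cs = coherence.cross_spectra(epochs, "Cz", cfg.coupling_partner, post, sched)
        if sxx is None:
            sxx, syy, sxy = nb * cs.sxx, nb * cs.syy, nb * cs.sxy
        else:
            sxx += nb * cs.sxx
            syy += nb * cs.syy
            sxy += nb * cs.sxy
        total += nb
    merged = coherence.CrossSpectra(
        frequencies=np.fft.rfftfreq(sched.seg_len, 1.0 / cfg.fs),
        centers_ms=post, sxx=sxx / total, syy=syy / total, sxy=sxy / total,
        n_trials=total, pair=("Cz", cfg.coupling_partner))
    series = coherence.ipc(merged)
    return float(series.band_series.mean())
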