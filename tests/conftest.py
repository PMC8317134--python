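import numpy as np
import pytest

from betabalance.preprocess import ContinuousEEG, EEGEpochs

FS = 1000.0


def make_epochs(data: np.ndarray, labels=None, fs: float = FS,
                span_s=(-1.0, 2.0)) -> EEGEpochs:
    """Wrap a (channels, trials, samples) array in an EEGEpochs container."""
    if labels is None:
        labels = ["Cz", "AFz", "CPz"][: data.shape[0]]
    onset = int(round(-span_s[0] * fs))
    return EEGEpochs(data=data, labels=labels, fs=fs, span_s=span_s,
                     onset_index=onset)


def sinusoid_epochs(freq_hz: float, amp_pre: float = 1.0, amp_post: float = 1.0,
                    n_trials: int = 1, fs: float = FS) -> EEGEpochs:
    """Single-channel epochs holding a sinusoid whose amplitude switches at onset."""
    n = int(3 * fs)
    onset = int(fs)
    t = (np.arange(n) - onset) / fs
    amp = np.where(t >= 0, amp_post, amp_pre)
    x = amp * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(x, (1, n_trials, 1))
    return make_epochs(data, labels=["Cz"], fs=fs)


@pytest.fixture
def white_noise_continuous():
    rng = np.random.default_rng(11)
    n = 40_000
    return ContinuousEEG(data=rng.standard_normal((1, n)), labels=["Cz"], fs=FS)
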