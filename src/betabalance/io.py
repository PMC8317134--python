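"""Epoch store and optional ingestion of standard EEG formats.

The native epoch store is deliberately minimal: a raw little-endian 32-bit
float array (channels x trials x samples) next to a JSON sidecar holding the
labels, sampling rate, onset index, shape and generator seed.  BrainVision and
EDF recordings are ingested through :mod:`mne` and mapped onto
:class:`~betabalance.preprocess.ContinuousEEG`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import ContinuousEEG, EEGEpochs

_DTYPE = "<f4"


def save_epochs(e: EEGEpochs, prefix: str | Path, seed: int | None = None) -> tuple[Path, Path]:
    """Write ``<prefix>.f32`` (raw floats) and ``<prefix>.json`` (sidecar)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bin_path = prefix.with_suffix(".f32")
    meta_path = prefix.with_suffix(".json")
    np.ascontiguousarray(e.data, dtype=_DTYPE).tofile(bin_path)
    meta = {
        "labels": list(e.labels),
        "fs": e.fs,
        "t0_index": e.onset_index,
        "shape": list(e.data.shape),
        "span_s": list(e.span_s),
        "trial_indices": e.trial_indices.tolist(),
        "seed": seed,
        "dtype": _DTYPE,
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return bin_path, meta_path


def load_epochs(prefix: str | Path) -> EEGEpochs:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    shape = tuple(meta["shape"])
    data = np.fromfile(prefix.with_suffix(".f32"), dtype=meta.get("dtype", _DTYPE))
    if data.size != int(np.prod(shape)):
        raise ValueError(f"binary payload size {data.size} does not match shape {shape}")
    return EEGEpochs(
        data=data.reshape(shape).astype(float),
        labels=list(meta["labels"]),
        fs=float(meta["fs"]),
        span_s=tuple(meta["span_s"]),
        onset_index=int(meta["t0_index"]),
        trial_indices=np.asarray(meta["trial_indices"], dtype=int),
    )


def _from_raw(raw, stim_events: list[tuple[int, str]] | None = None) -> ContinuousEEG:
    data = raw.get_data(units="uV") if hasattr(raw, "get_data") else raw.get_data()
    events: list[tuple[int, str]] = stim_events or []
    if not events:
        try:
            import mne

            ann_events, ann_ids = mne.events_from_annotations(raw, verbose="error")
            inv = {v: k for k, v in ann_ids.items()}
            events = [(int(s), inv[int(code)]) for s, _, code in ann_events]
        except Exception:
            events = []
    return ContinuousEEG(data=np.asarray(data), labels=list(raw.ch_names),
                         fs=float(raw.info["sfreq"]), events=events)


def read_brainvision(vhdr_path: str | Path) -> ContinuousEEG:
    """Read a BrainVision .vhdr/.vmrk/.eeg triplet, markers becoming events."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    return _from_raw(raw)


def read_edf(edf_path: str | Path) -> ContinuousEEG:
    """Read an EDF recording, annotations becoming events."""
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    return _from_raw(raw)
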