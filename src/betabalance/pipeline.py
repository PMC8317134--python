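"""Configuration and end-to-end orchestration of the analysis stages.

``run_full`` chains synthetic-data generation (or ingestion of stored epochs
and behavior CSVs), beta-power and coherence quantification, and the
statistical battery, writing every artifact as CSV with a provenance JSON
sufficient to re-run bit-identically.  The default configuration reproduces
every protocol constant of the source analysis; ``validate_config`` lists any
deviation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beta_power, coherence, io, stats, synthetic_data
from .behavior import StaircaseConfig
from .coherence import SegmentSchedule
from .synthetic_data import SyntheticEEGConfig

log = logging.getLogger("betabalance")

DEFAULT_PAIRS = (("AFz", "Cz"), ("CPz", "Cz"))


@dataclass
class PipelineConfig:
    """Full analysis configuration; the defaults ARE the protocol constants."""

    # inputs (None -> simulate)
    epochs_dir: str | None = None
    behavior_csv: str | None = None
    behavior_source: str = "fixture"        # "fixture" | "simulate" | "csv"
    out_dir: str = "results"
    # selections
    channel: str = "Cz"
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    # synthetic cohort
    n_eeg_participants: int = 15
    eeg: SyntheticEEGConfig = field(default_factory=SyntheticEEGConfig)
    behavior_target_corr: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.38, 0.47), (0.38, 1.0, 0.76), (0.47, 0.76, 1.0))
    n_behavior_participants: int = 15
    # analysis constants
    schedule: SegmentSchedule = field(default_factory=SegmentSchedule)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    baseline_ms: tuple[float, float] = beta_power.BASELINE_WINDOW_MS
    window_overall_ms: tuple[float, float] = beta_power.WINDOW_OVERALL_MS
    window_early_ms: tuple[float, float] = beta_power.WINDOW_EARLY_MS
    window_late_ms: tuple[float, float] = beta_power.WINDOW_LATE_MS
    pre_window_ms: tuple[float, float] = coherence.PRE_WINDOW_MS
    post_window_ms: tuple[float, float] = coherence.POST_WINDOW_MS
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML or JSON config document; absent keys keep their defaults."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    base = PipelineConfig()
    nested = {"eeg": SyntheticEEGConfig, "schedule": SegmentSchedule,
              "staircase": StaircaseConfig}
    kwargs = {}
    for key, value in doc.items():
        if key in nested and isinstance(value, dict):
            sub = dataclasses.asdict(getattr(base, key))
            sub.update(value)
            for k in list(sub):
                if isinstance(sub[k], list):
                    sub[k] = tuple(sub[k])
            kwargs[key] = nested[key](**sub)
        elif isinstance(value, list):
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        else:
            kwargs[key] = value
    return replace(base, **kwargs)


def validate_config(config: PipelineConfig) -> dict:
    """Report every deviation from the protocol defaults; raise on invariant
    violations (the nested dataclasses validate themselves on construction)."""
    reference = PipelineConfig()
    deviations = []
    skip = {"epochs_dir", "behavior_csv", "behavior_source", "out_dir", "seed",
            "log_level", "n_eeg_participants", "n_behavior_participants"}
    ref_d, cfg_d = reference.to_dict(), config.to_dict()
    for key in ref_d:
        if key in skip:
            continue
        if cfg_d[key] != ref_d[key]:
            deviations.append({"field": key, "value": cfg_d[key],
                               "default": ref_d[key]})
    return {"deviations": deviations, "valid": True}


def _participant_metrics(config: PipelineConfig, epochs, pid: str) -> dict:
    summary = beta_power.channel_beta_summary(epochs, config.channel)
    row = {
        "id": pid,
        "beta_baseline": summary.baseline_db,
        "beta_peak_overall": summary.peak_overall_db,
        "beta_peak_early": summary.peak_early_db,
        "beta_peak_late": summary.peak_late_db,
    }
    for ch_a, ch_b in config.pairs:
        _, pre_ipc, post_ipc = coherence.pair_ipc(epochs, ch_a, ch_b, config.schedule)
        row[f"ipc_{ch_a}-{ch_b}_pre"] = pre_ipc
        row[f"ipc_{ch_a}-{ch_b}_post"] = post_ipc
    return row


def _write_ersp_csv(m: beta_power.ERSPMap, path: Path) -> None:
    frame = pd.DataFrame(m.power_db.T, columns=[f"{f:.2f}Hz" for f in m.frequencies])
    frame.insert(0, "time_ms", m.times_ms)
    frame.to_csv(path, index=False)


def _write_ipc_csv(s: coherence.IPCSeries, path: Path) -> None:
    frame = pd.DataFrame(s.ipc.T, columns=[f"{f:.3f}Hz" for f in s.frequencies])
    frame.insert(0, "center_ms", s.centers_ms)
    frame["band_mean"] = s.band_series
    frame.to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps(s.meta, indent=1))


def run_full(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle; returns artifact paths.

    Deterministic given inputs and seeds.  Stage failures propagate annotated
    with the stage name.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                log.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done in %.3f s", name, timings[name])

        return _Stage()

    with stage("behavior"):
        if config.behavior_source == "csv":
            if not config.behavior_csv:
                raise ValueError("behavior_source='csv' requires behavior_csv")
            behavior = synthetic_data.read_behavior_csv(config.behavior_csv)
        elif config.behavior_source == "simulate":
            behavior = synthetic_data.gen_behavior(
                config.n_behavior_participants,
                np.asarray(config.behavior_target_corr), seed=config.seed)
        else:
            behavior = synthetic_data.paper_behavior_fixture()
        path = out / "behavior.csv"
        synthetic_data.write_behavior_csv(behavior, path)
        artifacts["behavior"] = str(path)

    with stage("behavior_stats"):
        beh_corr = stats.behavior_correlations(behavior)
        beh_corr.to_csv(out / "behavior_correlations.csv", index=False)
        artifacts["behavior_correlations"] = str(out / "behavior_correlations.csv")
        diag = stats.normality_diagnostics(behavior)
        diag.to_csv(out / "normality_diagnostics.csv", index=False)
        artifacts["normality_diagnostics"] = str(out / "normality_diagnostics.csv")

    run_eeg = config.epochs_dir is not None or config.behavior_source != "csv"
    neural = None
    if config.epochs_dir is not None:
        with stage("eeg_load"):
            epoch_sets = []
            for meta in sorted(Path(config.epochs_dir).glob("*.json")):
                pid = meta.stem
                epoch_sets.append((pid, io.load_epochs(meta.with_suffix(""))))
    elif run_eeg:
        with stage("eeg_simulate"):
            epoch_sets = []
            ids = list(behavior["id"][:config.n_eeg_participants])
            for i, pid in enumerate(ids):
                cfg_i = replace(config.eeg, seed=int((config.seed + 1) * 10_007 + i))
                epochs, _ = synthetic_data.gen_epochs(cfg_i)
                epoch_sets.append((pid, epochs))
    if run_eeg and epoch_sets:
        with stage("eeg_metrics"):
            neural = pd.DataFrame([
                _participant_metrics(config, epochs, pid)
                for pid, epochs in epoch_sets])
            neural.to_csv(out / "neural.csv", index=False)
            artifacts["neural"] = str(out / "neural.csv")
        with stage("eeg_example_maps"):
            pid, epochs = epoch_sets[0]
            _write_ersp_csv(beta_power.ersp(epochs, config.channel),
                            out / f"ersp_{config.channel}_{pid}.csv")
            artifacts["ersp_example"] = str(out / f"ersp_{config.channel}_{pid}.csv")
            for ch_a, ch_b in config.pairs:
                series, _, _ = coherence.pair_ipc(epochs, ch_a, ch_b, config.schedule)
                _write_ipc_csv(series, out / f"ipc_{ch_a}-{ch_b}_{pid}.csv")
                artifacts[f"ipc_{ch_a}-{ch_b}"] = str(out / f"ipc_{ch_a}-{ch_b}_{pid}.csv")
        with stage("paired_tests"):
            rows = []
            t, p, n = stats.paired_t(neural["beta_peak_overall"] + neural["beta_baseline"],
                                     neural["beta_baseline"])
            rows.append({"test": "beta post vs baseline", "t": t, "p": p, "n": n})
            for ch_a, ch_b in config.pairs:
                t, p, n = stats.paired_t(neural[f"ipc_{ch_a}-{ch_b}_post"],
                                         neural[f"ipc_{ch_a}-{ch_b}_pre"])
                rows.append({"test": f"IPC {ch_a}-{ch_b} post vs pre", "t": t,
                             "p": p, "n": n})
            pd.DataFrame(rows).to_csv(out / "paired_tests.csv", index=False)
            artifacts["paired_tests"] = str(out / "paired_tests.csv")
        with stage("correlation_battery"):
            battery = stats.correlation_battery(behavior, neural)
            battery.to_csv(out / "stats_battery.csv", index=False)
            artifacts["stats_battery"] = str(out / "stats_battery.csv")

    with stage("provenance"):
        prov = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "constants": {
                "ersp_freqs_hz": beta_power.FREQS_HZ.tolist(),
                "ersp_grid_ms": beta_power.GRID_STEP_MS,
                "ersp_support_ms": beta_power.SUPPORT_MS,
                "wavelet_cycles": beta_power.CYCLES.tolist(),
                "seg_len": config.schedule.seg_len,
                "overlap": config.schedule.overlap,
                "step_samples": config.schedule.step_samples,
                "nominal_step_ms": config.schedule.nominal_step_ms(config.eeg.fs),
                "freq_resolution_hz": config.schedule.freq_resolution_hz(config.eeg.fs),
                "beta_band_hz": list(coherence.BETA_BAND_HZ),
            },
            "timings_s": timings,
            "artifacts": artifacts,
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=1, default=str))
        artifacts["provenance"] = str(out / "provenance.json")
    return artifacts
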