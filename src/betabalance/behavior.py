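"""Behavioral balance metrics: dual-task interference, miniBEST total, and the
adaptive reactive-step-threshold staircase.

Dual-task interference (DTI) compares Timed-Up-and-Go durations with and
without a concurrent serial-subtraction task; negative values mean the dual
task was slower.  The staircase emulates the platform protocol: forward
perturbations start at 8 cm, scale up by 1 cm after three consecutive
feet-in-place (no-step) trials, hold for a 10-trial block once a step occurs,
scale down by 0.5 cm after five consecutive steps within a held block, and
terminate at the held magnitude where stepping occurs on roughly half the
trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def dti(tug_single: float, tug_dual: float) -> tuple[float, float]:
    """Dual-task interference in seconds and percent.

    dti_s = −(dual − single); dti_pct = −(dual − single)/single × 100.
    Both are negative when the dual-task condition is slower.
    """
    if tug_single <= 0 or tug_dual <= 0:
        raise ValueError("TUG times must be positive")
    dti_s = -(tug_dual - tug_single)
    return dti_s, 100.0 * dti_s / tug_single


def minibest_total(items, bilateral_pairs=()) -> int:
    """Total miniBEST score: bilateral items contribute min(left, right).

    ``items`` are single-rated item scores in {0, 1, 2}; ``bilateral_pairs``
    are (left, right) tuples for items rated per leg.  The 14-item instrument
    has a maximum of 28.
    """
    total = 0
    for score in items:
        if score not in (0, 1, 2):
            raise ValueError(f"item score {score!r} outside 0-2")
        total += score
    for left, right in bilateral_pairs:
        if left not in (0, 1, 2) or right not in (0, 1, 2):
            raise ValueError(f"bilateral scores ({left}, {right}) outside 0-2")
        total += min(left, right)
    return total


@dataclass
class StaircaseConfig:
    """Protocol constants of the reactive-step-threshold staircase."""

    start_magnitude: float = 8.0    # cm
    up_step: float = 1.0            # cm after ascend_after consecutive no-steps
    down_step: float = 0.5          # cm after descend_after consecutive steps
    ascend_after: int = 3
    hold_block: int = 10            # trials per held block
    descend_after: int = 5
    magnitude_floor: float = 1.0
    magnitude_ceiling: float = 25.0
    max_trials: int = 120

    def __post_init__(self) -> None:
        if min(self.up_step, self.down_step) <= 0:
            raise ValueError("step sizes must be positive")
        if not self.magnitude_floor < self.start_magnitude <= self.magnitude_ceiling:
            raise ValueError("need floor < start <= ceiling")


@dataclass
class StaircaseResult:
    trace: list[tuple[int, float, bool]]          # (trial, magnitude cm, step?)
    block_stats: dict[float, tuple[int, float]]   # magnitude -> (n, step fraction)
    threshold_cm: float
    converged: bool
    notes: str = ""

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace, columns=["trial", "magnitude_cm", "step"])


def run_staircase(responder, cfg: StaircaseConfig | None = None) -> StaircaseResult:
    """Run the adaptive protocol against a step-response process.

    Ascend phase: after ``ascend_after`` consecutive no-step trials the
    magnitude rises by ``up_step``; the first step response opens a held block
    of ``hold_block`` further trials at that magnitude.  Within a block,
    ``descend_after`` consecutive steps lower the magnitude by ``down_step``
    and open a new block.  A block completing with step fraction in
    [0.3, 0.7] terminates the run (threshold = its magnitude, converged).
    Otherwise the protocol resumes ascending, until ``max_trials``.

    Without a qualifying block the threshold falls back to the midpoint
    between the highest held magnitude with step fraction < 0.5 and the lowest
    with fraction > 0.5 (``converged=False``); ties on either side resolve to
    the lower magnitude.
    """
    cfg = cfg or StaircaseConfig()
    trace: list[tuple[int, float, bool]] = []
    block_trials: dict[float, list[bool]] = {}
    magnitude = cfg.start_magnitude
    trial = 0
    state = "ascend"
    consec_nostep = 0
    block: list[bool] = []
    consec_step = 0
    threshold = np.nan
    converged = False
    notes = "max_trials reached"

    def clamp(m: float) -> float:
        return float(min(max(m, cfg.magnitude_floor), cfg.magnitude_ceiling))

    while trial < cfg.max_trials:
        stepped = bool(responder(magnitude))
        trace.append((trial, magnitude, stepped))
        trial += 1
        if state == "ascend":
            if stepped:
                # hold at this level for hold_block further trials
                state = "block"
                block = []
                consec_step = 0
                block_trials.setdefault(magnitude, [])
            else:
                consec_nostep += 1
                if consec_nostep >= cfg.ascend_after:
                    magnitude = clamp(magnitude + cfg.up_step)
                    consec_nostep = 0
        else:  # held block
            block.append(stepped)
            block_trials.setdefault(magnitude, []).append(stepped)
            consec_step = consec_step + 1 if stepped else 0
            if consec_step >= cfg.descend_after:
                magnitude = clamp(magnitude - cfg.down_step)
                block = []
                consec_step = 0
                block_trials.setdefault(magnitude, [])
            elif len(block) >= cfg.hold_block:
                frac = float(np.mean(block))
                if 0.3 <= frac <= 0.7:
                    threshold = magnitude
                    converged = True
                    notes = "block step fraction within [0.3, 0.7]"
                    break
                state = "ascend"
                consec_nostep = 0

    block_stats = {m: (len(v), float(np.mean(v)) if v else np.nan)
                   for m, v in block_trials.items()}
    if not converged:
        threshold = _bracket_threshold(block_stats)
        if np.isnan(threshold):
            notes = "no held blocks before the trial cap"
    return StaircaseResult(trace=trace, block_stats=block_stats,
                           threshold_cm=float(threshold), converged=converged,
                           notes=notes)


def _bracket_threshold(block_stats: dict[float, tuple[int, float]]) -> float:
    rated = {m: frac for m, (n, frac) in block_stats.items()
             if n > 0 and not np.isnan(frac)}
    if not rated:
        return np.nan
    below = [m for m, f in rated.items() if f < 0.5]
    above = [m for m, f in rated.items() if f > 0.5]
    if below and above:
        return 0.5 * (max(below) + min(above))
    if below:
        return max(below)
    if above:
        return min(above)
    # every rated magnitude sits exactly at 0.5: closest to 0.5 is a tie,
    # the lower magnitude wins
    return min(rated)


def staircase_trace_csv(result: StaircaseResult, path) -> None:
    result.trace_frame().to_csv(path, index=False)
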