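#!/usr/bin/env python
"""Imaginary coherency: volume-conduction null and lagged-coupling recovery.

Contrasts three prefrontal-motor (AFz-Cz) scenarios at the default trial
count: independent channels, a zero-lag shared source (pure volume
conduction), and a quarter-cycle-lagged shared source.  Only the lagged
source should raise post-perturbation band IPC above the independence bias
bound.  Writes results/ipc_scenarios.csv.
"""

from pathlib import Path

import pandas as pd

import betabalance as bb

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    scenarios = {
        "independent": dict(coupling_gain=0.0),
        "zero_lag_shared": dict(coupling_gain=0.8, coupling_lag_ms=0.0),
        "quarter_cycle_lag": dict(coupling_gain=0.8, coupling_lag_ms=12.5),
    }
    rows = []
    for name, kw in scenarios.items():
        cfg = bb.SyntheticEEGConfig(seed=17, **kw)
        epochs, _ = bb.gen_epochs(cfg)
        _, pre, post = bb.pair_ipc(epochs, "AFz", "Cz")
        rows.append({"scenario": name, "pre_ipc": pre, "post_ipc": post,
                     "bias_bound": bb.independence_bias_bound(cfg.n_trials)})
    table = pd.DataFrame(rows).round(3)
    table.to_csv(OUT / "ipc_scenarios.csv", index=False)
    print(table.to_string(index=False))
    print("\nZero-lag mixing is invisible to the imaginary part of coherency; "
          "only the phase-lagged source lifts post-perturbation IPC above the "
          "independence bias bound.")


if __name__ == "__main__":
    main()
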