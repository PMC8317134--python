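"""Correlation battery over behavior and neural metrics, with paired t-tests
and Benjamini-Hochberg false-discovery-rate control.

The battery reproduces the structure of the source analysis: Pearson
correlations of three behavioral measures (miniBEST, dual-task interference in
percent, reactive step threshold) against (a) the twelve coherence cells
(2 electrode pairs x 2 windows x 3 behaviors), FDR-adjusted as one family, and
(b) the baseline-subtracted beta-power peaks, reported with raw p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

BEHAVIOR_METRICS = ("minibest", "dti_pct", "step_threshold")
COHERENCE_METRICS = ("ipc_AFz-Cz_pre", "ipc_AFz-Cz_post",
                     "ipc_CPz-Cz_pre", "ipc_CPz-Cz_post")
BETA_METRICS = ("beta_peak_overall", "beta_peak_early", "beta_peak_late")


def pearson(x, y) -> tuple[float, float, int]:
    """Product-moment r with the two-tailed p from t = r sqrt(n-2)/sqrt(1-r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), n


def paired_t(a, b) -> tuple[float, float, int]:
    """Paired two-tailed t-test on n-1 degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    n = a.size
    if n < 2:
        raise ValueError("need n >= 2")
    if np.std(a - b, ddof=1) == 0:
        raise ValueError("zero variance of the paired differences")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p), n


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def normality_diagnostics(table: pd.DataFrame,
                          columns=BEHAVIOR_METRICS) -> pd.DataFrame:
    """Kolmogorov-Smirnov (vs a fitted normal) per column — diagnostics only,
    never gating the battery."""
    rows = []
    for col in columns:
        v = np.asarray(table[col], dtype=float)
        v = v[np.isfinite(v)]
        stat, p = sps.kstest((v - v.mean()) / v.std(ddof=1), "norm")
        rows.append({"metric": col, "ks_stat": float(stat), "p": float(p), "n": v.size})
    return pd.DataFrame(rows)


def correlation_battery(behavior: pd.DataFrame, neural: pd.DataFrame,
                        coherence_metrics=COHERENCE_METRICS,
                        beta_metrics=BETA_METRICS,
                        behaviors=BEHAVIOR_METRICS) -> pd.DataFrame:
    """One row per (behavior, neural metric) with r, complete-case n, p_raw and
    (for the coherence family only) p_fdr.

    Tables are joined on ``id``; each row uses the complete cases for its pair
    of columns, so behavioral-only participants drop out of EEG rows without
    affecting the rest (needs >= 3 complete cases per cell).
    """
    merged = behavior.merge(neural, on="id", how="outer", validate="one_to_one")
    rows = []
    for family, metrics in (("coherence", coherence_metrics), ("beta_power", beta_metrics)):
        for metric in metrics:
            if metric not in merged.columns:
                continue
            for beh in behaviors:
                sub = merged[[beh, metric]].dropna()
                if len(sub) < 3:
                    raise ValueError(
                        f"fewer than 3 complete cases for {beh} vs {metric}")
                r, p, n = pearson(sub[beh], sub[metric])
                window = metric.rsplit("_", 1)[-1] if family == "coherence" else ""
                rows.append({"behavior": beh, "neural": metric, "family": family,
                             "window": window, "r": r, "n": n, "p_raw": p,
                             "p_fdr": np.nan})
    table = pd.DataFrame(rows)
    fam = table["family"] == "coherence"
    if fam.any():
        table.loc[fam, "p_fdr"] = fdr_bh(table.loc[fam, "p_raw"].to_numpy())
    return table


def behavior_correlations(behavior: pd.DataFrame) -> pd.DataFrame:
    """The three behavior-behavior Pearson correlations (percent DTI form)."""
    pairs = [("minibest", "dti_pct"), ("minibest", "step_threshold"),
             ("dti_pct", "step_threshold")]
    rows = []
    for a, b in pairs:
        sub = behavior[[a, b]].dropna()
        r, p, n = pearson(sub[a], sub[b])
        rows.append({"x": a, "y": b, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)
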