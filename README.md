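# betabalance

Analysis of perturbation-evoked cortical beta dynamics and reactive balance
behavior in older adults, built for researchers studying cortical
contributions to balance control with scalp EEG.

During support-surface perturbations, motor cortical beta power (13–30 Hz, at
Cz) rises sharply, and phase-lagged coupling between motor and prefrontal
(AFz) or somatosensory (CPz) regions indexes circuit-specific engagement.
This package implements the full quantification chain and the behavioral
battery it is correlated against:

- **ERSP** — Morlet-wavelet event-related spectral perturbation at 10 linear
  frequencies over 12–50 Hz (3→6 cycles, 256 ms support, 14 ms grid), with
  beta power summarised as the baseline mean over −500–0 ms and
  baseline-subtracted peaks over 100–500, 100–300 and 300–500 ms, in dB.
- **IPC** — the imaginary part of coherency,
  `|Im(Sxy/√(Sxx·Syy))|`, on Hann-tapered 768-sample segments with 0.9
  overlap (1.3 Hz resolution), anchored so the six pre-perturbation segment
  centres span −388…−8 ms and the five post-perturbation centres 144…448 ms.
  Zero-lag (volume-conducted) coupling is invisible to this estimator.
- **Behavior** — dual-task interference
  `DTI% = −(TUG_dual − TUG_single)/TUG_single × 100`, miniBEST totals
  (bilateral items take the lower side, max 28), and an adaptive
  reactive-step-threshold staircase (start 8 cm, +1 cm after 3 no-steps,
  10-trial held blocks, −0.5 cm after 5 consecutive steps, threshold at the
  ≈50 % stepping block).
- **Statistics** — Pearson correlations, paired t-tests, and
  Benjamini–Hochberg FDR over the 12-cell coherence × behavior family.
- **Synthetic data** — a generator with known ground truth (1/f background,
  calibrated beta bursts, phase-lagged shared sources, planted behavioral
  correlations) so the whole chain is testable without recordings, plus the
  published 15-participant characteristics table as a packaged fixture.

## Worked example

```python
import betabalance as bb

# behavior battery on the packaged participant table
fix = bb.paper_behavior_fixture()
print(bb.behavior_correlations(fix))

# synthetic epochs with a +6 dB late beta burst and lagged AFz-Cz coupling
cfg = bb.SyntheticEEGConfig(burst_gain_db=6.0, coupling_gain=0.8, seed=21)
epochs, truth = bb.gen_epochs(cfg)
print(bb.channel_beta_summary(epochs, "Cz"))
_, pre_ipc, post_ipc = bb.pair_ipc(epochs, "AFz", "Cz")
print(pre_ipc, post_ipc, bb.independence_bias_bound(cfg.n_trials))
```

prints

```
       x               y         r         p   n
0  minibest         dti_pct  0.378782  0.163838  15
1  minibest  step_threshold  0.474132  0.074173  15
2   dti_pct  step_threshold  0.758672  0.001042  15
BetaPowerSummary(baseline_db=10.955..., peak_overall_db=6.0047...,
                 peak_early_db=5.8144..., peak_late_db=6.0047...)
0.145 0.350 0.263
```

Reading: among the three behavioral measures only dual-task interference and
step threshold are significantly related (r = 0.76, p = 0.001) — participants
who slow more under cognitive load elicit stepping at lower perturbation
magnitudes. The injected 6 dB beta burst is recovered at the peak of the
evoked beta time course, and the quarter-cycle-lagged shared source lifts
post-perturbation AFz–Cz IPC (0.35) well above both its pre-perturbation
level (0.15) and the independence bias bound (0.26).

The numbered scripts under `analysis/` run the same stages as narrative
drivers and write their tables under `results/`:

```sh
python analysis/01_behavior_battery.py      # group stats + correlations
python analysis/02_beta_power_recovery.py   # burst injection/recovery
python analysis/03_coherence_nulls.py       # volume-conduction nulls vs lag
python analysis/04_staircase_recovery.py    # threshold recovery study
python analysis/05_full_pipeline.py         # full synthetic cohort
```

See `docs/methods.md` for the model, parameter and calibration details.

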