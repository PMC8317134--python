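# Methods

## Scope and data model

The package quantifies cortical engagement around support-surface balance
perturbations in older adults and relates it to behavioral balance measures.
Epoched EEG is held as a `(channels × trials × samples)` array time-locked to
perturbation onset at t = 0, with epochs spanning −1 to +2 s at 1,000 Hz
(3,000 samples, half-open window, onset at local index 1,000). Three midline
channels matter for the analyses: Cz (motor), CPz (somatosensory) and AFz
(prefrontal). Behavioral data are per-participant rows of miniBEST total,
single- and dual-task Timed-Up-and-Go (TUG) durations, dual-task interference
(DTI) and the reactive step threshold; the published participant table ships
as a packaged CSV.

## Preprocessing

Continuous data are band-pass filtered 1–100 Hz and notched at 60 Hz before
epoching. Both filters are zero-phase (forward–backward) IIR designs so
evoked latencies are preserved: a Butterworth band-pass (scipy order 8, i.e. a
16-pole band-pass, giving > 20 dB attenuation at 120 Hz after bidirectional
application) and an `iirnotch` with Q = 30 (2 Hz bandwidth, altering the
13–30 Hz band by far less than 0.5 dB). The filter family and order are
configuration knobs; the defaults above are this package's choice since no
canonical order exists for this protocol. Line-noise removal by narrow notch
(rather than regression-based spectral estimation) is adequate here because
the synthetic line component is stationary. Bad-channel interpolation and
ICA-based artifact removal are intentionally absent: the pipeline accepts
pre-cleaned epochs, and the synthetic inputs are artifact-free. Trials
flagged offline (e.g. stepping reactions) are removed with their original
indices retained as provenance; removing all trials is an error.

## Beta-band ERSP

Time–frequency power uses a tapered complex Morlet wavelet at 10 linearly
spaced frequencies from 12 to 50 Hz. The cycle count rises linearly from 3 at
12 Hz to 6 at 50 Hz, `cycles(f) = 3 + 3 (f − 12)/38`. Each wavelet is a
Gaussian-enveloped complex exponential (σ_t = cycles / 2πf) truncated to a
256-sample support (the 256 ms sliding window), normalised so a
unit-amplitude sinusoid at the wavelet's centre frequency yields unit power.
Squared magnitudes are averaged across trials and sampled on a 14 ms grid;
power is reported as 10·log10(µV²) — the power (not amplitude) dB convention
of event-related spectral perturbation practice. The output grid is
restricted to times where the full support lies inside the epoch; no padding
is used, so the −500 to 0 ms baseline is free of edge artifacts.

Beta power is the mean of the ERSP rows at the four sampled frequencies
nearest 16/20/24/29 Hz — the 2nd–5th bins, 16.22/20.44/24.67/28.89 Hz. (A
10-point linear grid over 12–50 Hz cannot land exactly on the printed
centres; the 2nd–5th-bin reading is recorded as this package's choice.) The
summary reports the scalar baseline mean over [−500, 0) ms and
baseline-subtracted pointwise maxima over 100–500, 100–300 and 300–500 ms,
inclusive bounds, no interpolation. Because the early/late windows tile the
overall window on the 14 ms grid, the overall peak equals the larger of the
two sub-window peaks by construction.

## Imaginary part of coherency (IPC)

Connectivity between electrode pairs (AFz–Cz, CPz–Cz) uses the magnitude of
the imaginary part of coherency: `|Im(Sxy / √(Sxx·Syy))|`, with the
expectation taken across trials at each segment centre (trial-ensemble
averaging keeps per-centre time resolution). A zero-lag common source —
volume conduction — contributes only to the real part, so IPC is immune to
it; this is the reason the estimator is used for closely spaced midline
electrodes.

Segments are 768 samples (1.302 Hz bin spacing at 1 kHz), Hann-tapered and
demeaned, with 0.9 overlap. The advance is rounded *down* to 76 samples and
the grid anchored so −8 ms is the last pre-perturbation centre: this uniquely
reproduces the canonical centres −388…−8 ms (six pre segments in [−400, 0))
and 144…448 ms (five post segments in [100, 500]). The un-rounded 76.8 ms
advance is carried in output metadata as the nominal resolution; rounding to
77 would be inconsistent with those centres. The pre window is taken as
half-open [−400, 0). The beta band comprises every bin whose centre lies in
[13, 30] Hz inclusive (14 bins). The absolute value of the imaginary part is
reported, since group values are conventionally printed unsigned.

At n trials the |Im| estimator has positive bias under independence of order
1/√n; the package exposes `independence_bias_bound(n) = 1/√n + 0.05` as the
null threshold used by the volume-conduction tests.

## Behavioral metrics

DTI is `dti_s = −(dual − single)` seconds and `dti_pct = 100·dti_s/single`;
negative values mean dual-task slowing. Correlation analyses use the percent
form: on the packaged table it reproduces the printed miniBEST–DTI r = 0.38
(the seconds form gives 0.41), while the DTI–threshold r = 0.76 is insensitive
to the choice. The miniBEST total sums 14 items scored 0–2, bilateral items
contributing the lower of the two sides, maximum 28.

The staircase emulates the platform protocol: start at 8 cm; after 3
consecutive no-step trials rise 1 cm; the first step response opens a held
block of 10 further trials; 5 consecutive steps within a block lower the
magnitude 0.5 cm and open a new block; a block completing with step fraction
in [0.3, 0.7] terminates with that magnitude as the threshold. The [0.3,
0.7] acceptance band operationalises "about 5 of 10 trials", for which no
printed tolerance exists. Deterministic or degenerate responders can never
satisfy it; they fall back to the midpoint between the highest held magnitude
with step fraction < 0.5 and the lowest with fraction > 0.5, flagged
`converged=False` (ties resolve to the lower magnitude — the conservative
threshold). The default trial cap is 120. Against logistic responders
(P(step) = expit((m − θ)/s)) with s = 1 cm, 200-seed ensembles recover θ with
median absolute error ≤ 1 cm and median estimates monotone in θ; estimates
carry a slight negative bias (≈ 0.5–1 cm) because ascent stops at the first
step response, which tends to occur below θ.

## Statistics

Pearson correlations (two-tailed p from t = r√(n−2)/√(1−r²) on n−2 df),
paired t-tests (n−1 df; zero difference variance is a degenerate-input error,
not t = ∞), and Benjamini–Hochberg step-up adjustment. The FDR family is
exactly the 12 coherence cells (3 behaviors × 2 pairs × 2 windows);
beta-power correlations are reported with raw p, mirroring the source
analysis's separate treatment. Each battery row uses the complete cases for
its column pair, so participants with behavioral data but unusable EEG drop
out of EEG rows only. Kolmogorov–Smirnov normality checks are emitted as
diagnostics and never gate the battery. α = 0.05 two-tailed throughout.

## Synthetic data generator

The generator defines the study conditions for every downstream test:

- **Background**: independent per-channel 1/f (power exponent 1) noise,
  10 µV RMS, 22 trials per participant (matching the ≈ 21.9 analysable
  trials of a 24-perturbation protocol), 3 channels, −1 to 2 s at 1 kHz.
- **Evoked burst**: non-phase-locked 13–30 Hz noise under a raised-cosine
  envelope over the burst window (default 100–500 ms) added to Cz. Power-based
  ERSP detects it without evoked-potential confounds, matching the induced
  character of perturbation-evoked beta. The amplitude is calibrated
  empirically per realization — bisection against the package's own wavelet
  beta-power measurement until the peak rise over the window equals
  `burst_gain_db` to 0.005 dB. A closed-form calibration is fragile against
  the 1/f background and the envelope/wavelet smearing interplay; the
  empirical loop also means recovered peaks have essentially no sampling
  scatter around the target, so between-participant variance in simulated
  cohorts comes from the coupling and behavior draws, not the burst.
- **Shared source**: one beta-band signal added to Cz (amplitude equal to the
  background's beta-band RMS by default) and, delayed by `coupling_lag_ms`
  and scaled by `coupling_gain`, to a partner channel, active only
  post-onset with a 50 ms onset ramp. The default lag of 12.5 ms is a
  quarter period at 20 Hz, maximising |Im(coherency)| at band centre; the
  zero-lag switch turns the same construction into a volume-conduction null.
  The fractional delay is applied in the frequency domain (circular; the
  wrap sits at the epoch edges, outside every analysis window).
- **Line noise**: optional 60 Hz sinusoid, common to all channels, random
  phase per trial.
- **Behavior tables**: a latent trivariate normal over (miniBEST, DTI%,
  step threshold) with a caller-supplied correlation matrix, mapped to
  marginal scales from the packaged table's group rows (miniBEST 23.7 ± 2.4
  rounded and clipped to 0–28; DTI% −19 ± 22; TUG 8.5 ± 1.8 s). Step
  thresholds use mean 12, sd 2.5 cm clipped to [6, 18] — the sd is tightened
  below the table's 3.3 so the clamp is rarely active and planted
  correlations survive the transform. `tug_dual` is derived from the drawn
  DTI% so the interference identities hold exactly.

Everything is bit-reproducible per seed. What the generator does **not**
emulate: realistic 64-channel topographies and volume-conduction head models,
eyeblink/EMG artifacts, platform-deceleration responses, non-stationary
backgrounds, or perturbation directions other than forward. Passing tests
therefore demonstrate correctness of the estimators and protocol logic under
controlled conditions, not robustness to real-recording artifacts.

The long-run IPC oracle is the same segment-grid estimator with auto/cross
spectra accumulated over independent generator batches (default 10⁵ trials);
recovery tests compare moderate-trial measurements against it rather than
against an analytic value, because the band-averaged IPC of an enveloped,
band-limited source over Hann-tapered segments has no convenient closed form.

## Numerical choices and degenerate inputs

Wavelet convolution is FFT-based; the brute-force per-sample inner-product
oracle in the test suite agrees to 1e−6 relative error. Filters use
`sosfiltfilt`/`filtfilt`; filter-order commutativity holds to 1e−6 relative
RMS away from edge transients (the 1 Hz high-pass edge rings for seconds, so
the property is evaluated on the interior of a long record). Segment centres
off the epoch, unknown channel labels, all-trials-dropped, zero auto-spectra,
single-trial coherency, non-PSD correlation targets, non-positive TUG times
and out-of-range item scores all raise errors naming the offending entity.

## Problem sizes

Default test and demonstration scales: 22 trials × 3,000 samples per
participant, 15-participant cohorts, 200-seed staircase ensembles, 100-seed
coupling ensembles, 2,000-trial IPC measurements against a 10⁵-trial oracle,
and 10⁴-row behavior tables for correlation-recovery checks. These sizes give
Monte-Carlo standard errors comfortably inside the stated tolerances.
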