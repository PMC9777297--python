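# Methods

This package implements an EEG decoding pipeline for two complex emotions —
pleasure and grief — elicited in 12-s trials and classified from 1-s signal
windows, together with a synthetic-EEG generator that stands in for the
unavailable human recordings. This note documents the models, parameter
choices, numerical details and limitations.

## Experiment model

The simulated session follows the emotion-elicitation design the features
were built for: an *emotional block* is four 12-s emotion trials of one
condition interleaved with three 12-s neutral segments (7 × 12 s = 84 s);
blocks alternate pleasure/grief until each condition has
`blocks_per_condition` blocks (default 4, i.e. 8 blocks and 672 s per
session). The block is interpreted as this 4 + 3 composition because it is
the only arrangement of 12-s segments that sums to the 84-s block length.
Each emotion segment is one *trial*; all 1-s windows cut from it share the
trial id, and cross-validation folds are assigned at the trial level.
Stimulus modality (text/audio/video/picture) is carried in the annotations
but does not modulate the signal (a deliberate non-goal).

## Synthetic EEG generator

Per channel the signal is a sum of:

* **1/f background** — Gaussian noise shaped to a power spectrum
  ∝ 1/f^α (α = `noise_exponent`, default 1.0), scaled to
  `background_rms` (default 8 µV).
* **Band-limited oscillations** — white noise masked to a band in the
  frequency domain, i.e. narrowband noise with a realistic fluctuating
  amplitude envelope (pure sinusoids would make the envelope-correlation
  features degenerate). Defaults: theta 4–7 Hz at 2 µV RMS, alpha 8–15 Hz at
  9 µV RMS, beta 16–31 Hz at 1.5 µV RMS. The alpha amplitude is set well
  above the in-band background so that alpha-band power is dominated by the
  oscillation; this keeps the dilution of the injected asymmetry contrast by
  the background near 10 %.
* **Blink artifacts** — 0.5-s half-cosine transients (default 120 µV,
  `artifact_rate` = 2/min) with a fixed spatial profile decaying from
  frontal to occipital rows: a rank-one component, which is exactly the
  structure ICA-based cleaning can isolate.

**Emotion contrast.** The class signal is a frontal alpha-power asymmetry.
`faa_effect` (δ) is defined as the *between-condition difference in frontal
alpha asymmetry*, FAA = ln P_right − ln P_left: during pleasure trials
left-frontal alpha amplitude is scaled by e^(−δ/8) and right-frontal by
e^(+δ/8) (log-power shifts of ∓δ/4, FAA = +δ/2), and grief reverses the
tilt, so FAA(pleasure) − FAA(grief) = δ. Positive FAA under the
alpha-inverse-activation convention indicates relatively greater left
cortical activation, the usual approach-emotion signature. δ has no
empirical anchor (the effect size between conditions is not quantified
anywhere for real data); it is a free simulation parameter, with δ = 1.5
used as the "clearly decodable" condition and δ = 0 as the null.

All randomness flows from one master seed through
`numpy.random.SeedSequence([seed, participant_id])`, so cohorts are
reproducible participant-by-participant.

## Preprocessing

* **Band-pass filter**: order-4 Butterworth applied forward–backward
  (zero phase, `sosfiltfilt`).
* **ICA artifact removal**: FastICA (default `min(n_channels, 32)`
  components, seeded). Components are compared against a blink reference —
  the mean of Fp1/Fp2 filtered to 1–4 Hz — after filtering the component
  time courses to the same band; components with |r| > 0.7 are subtracted
  from the data (the residual outside the ICA subspace is untouched).
  FastICA's global convergence tolerance is rarely met on this data because
  the background is Gaussian and that subspace rotates freely; the blink
  component stabilises within a few iterations regardless, so hitting
  `max_iter` raises a warning, and only a non-finite unmixing matrix is an
  error. No epoch rejection is performed anywhere.
* **Windowing**: non-overlapping 1-s windows within emotion segments only;
  neutral segments are never labeled. Non-overlap avoids within-trial
  dependence beyond what trial-grouped folds already handle.

## Time-frequency / FAA features

The complex Morlet wavelet is w(t) = exp(−t²/2s²)·exp(i2πft) on a time grid
spanning ±2 s, with width s = C/(2πf) and C = 7 cycles at every centre
frequency (a constant-Q choice; no frequency-dependent rule is imposed).
The positive-frequency (analytic) carrier convention is used; band powers
are invariant under conjugation. Kernels are L2-normalised so white noise
excites every centre frequency equally.

Band log-power per (channel, band): windows are reflection-padded, convolved
with kernels at 1-Hz steps across the band, and |·|² is averaged over the
original samples and the band's frequencies before taking ln (floored at
1e-12 µV² so silence maps to a finite value). For speed the convolution
truncates each band's kernels at four Gaussian widths (tail energy < 1e-6),
never beyond the ±2 s span, and runs in single precision; at C = 7 a 1-Hz
delta kernel is wider than the ±2 s span, so delta estimates from 1-s
windows are biased smooth — inherent to resolving 1 Hz with 7 cycles, and
identical for both classes.

The five-band split is delta 1–3, theta 4–7, alpha 8–15, beta 16–31 and
gamma 32–45 Hz (finite edges chosen for the open-ended delta/gamma
definitions; gamma capped below the muscle-artifact range). FAA is computed
for the seven frontal homologous pairs in the alpha band from the same log
powers. With 63 channels: 63 × 5 + 7 = 322 columns. Log (not raw) power is
used throughout so that the asymmetry is a difference and the FSDD score is
scale-free.

## Envelope-correlation features

Per window and band: Butterworth band-pass, amplitude envelope as the
magnitude of the analytic signal (Hilbert transform), Spearman correlation
(average ranks on ties, then Pearson of ranks) across all channel pairs,
strict upper triangle concatenated over bands. Seven bands are used here —
delta 1–3, theta 4–7, low-alpha 8–10, high-alpha 11–15, beta 16–31,
low-gamma 32–45, high-gamma 46–60 Hz — the minimal refinement of the
five-band table that yields seven bands including a distinct high-alpha.
With 63 channels: 63·62/2 × 7 = 13,671 features. (A printed feature count of
12,672 circulates for this construction but is arithmetically irreconcilable
with 63 channels and any whole band count; the implementation reports
n(n−1)/2 × n_bands.) Correlations are computed within each 1-s window,
consistent with windowed classification. A zero-variance channel cannot be
ranked; its correlations are defined as 0 and flagged with a warning.

## Feature selection

The distance-discriminant score (FSDD) is the two-class standardised mean
distance per column, |μ₁ − μ₀| / √(σ₁² + σ₀²) (sample variances); it is
invariant to affine rescaling of a column. Ties break by ascending column
index (stable sort). No published formula exists for the cited criterion;
this realisation captures its distance-based intent and is swappable: mRMR
(greedy relevance-minus-mean-|correlation|, greedy over the first 256
positions, relevance order beyond) and a Welch-t backend sit behind the
same interface. Default selection size k = 100.

## Classification

Repeated (10×) 5-fold CV with folds dealt round-robin over *trials*,
class-by-class, after a seeded shuffle — no trial's windows ever straddle
train and test. Per fold, a StandardScaler and the feature ranking are fit
on training rows only, then applied to test rows; the SVM is linear with
C = 1 (high-dimensional, few samples; RBF available via config). The summary
accuracy is the mean over all (repeat, fold) cells. The chance baseline
permutes labels at the *trial* level (window-level permutation would break
the dependence structure and overstate significance); null runs use one
repeat per permutation, and p = (1 + #{null ≥ observed}) / (1 + n_perm).

## Visualization

UMAP (the `umap-learn` implementation, seeded; n_neighbors = 15,
min_dist = 0.1 — common defaults) embeds window-feature rows in 2-D for
qualitative inspection; the topography stage tallies pooled top-20 features
per (region, hemisphere, band). Pair-valued features (FAA, correlations)
have no single scalp site and are counted separately from the channel tally.

## Montage

The 62 enumerated cap channels (7+7 frontal, 5+5 temporal, 13+13
central-parietal, 3+3 occipital, 6 midline) are completed to the 63-channel
analysis matrix by appending the standard midline site Pz, which is absent
from the enumeration; the extra channel is configurable because no source
names the 63rd channel. The occipital label "O7" is treated as a typo for
O1 (O7 does not exist in the 10-10 system and O1 is O2's homologue).

## Problem sizes

Desk-scale runs (tests, acceptance script, analysis drivers) use a reduced
design: 14 participants, 2 blocks per condition with 6-s segments — 16
trials and 96 labeled windows per participant at the full 63-channel,
250-Hz resolution. This preserves every structural property (grouping,
balance, scheduling) while keeping a cohort simulation-plus-decode around a
minute. `SimConfig` defaults remain the full design (4 blocks per condition,
12-s segments).

## Screening arithmetic

Category percentages are reported to one decimal, rounded half-up; the
two-decimal affected rate is *truncated* (186/568 = 32.7465 → 32.74), since
that is the only convention that reproduces the reported two-decimal figure.

## What passing tests do and do not show

The generator produces stationary Gaussian-envelope oscillations, a single
rank-one artifact type, and a one-parameter, purely alpha-asymmetry class
contrast. Real EEG adds non-stationarity, volume conduction, correlated
muscle/movement artifacts, modality-specific responses and idiosyncratic
spectral topographies. Recovery results here therefore validate the
*pipeline* — that the features measure what they claim, that grouping
prevents leakage, that selection and the permutation null are calibrated —
not any claim about decodability of real recordings.

## Known limitations

* No volume-conduction or source model; channel correlations arise only
  from injected shared components.
* δ is a free parameter; no empirical effect size exists to anchor it.
* The ICA cleaner targets the blink reference only; muscle artifacts are
  neither simulated nor specifically removed.
* Delta-band wavelet estimates from 1-s windows are strongly smoothed (see
  above); they are retained for completeness, not precision.
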