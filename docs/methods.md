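# Methods

This note records the model, the parameter choices, the synthetic-data
assumptions and the numerical decisions behind `swsync`, in the order the
pipeline runs.

## Preprocessing

Two causal IIR filters per channel: a 6th-order Butterworth high-pass at
0.5 Hz (baseline drift) followed by a second-order notch at 50 Hz (mains).
The notch quality factor is Q = 35 (≈ 1.4 Hz bandwidth) — narrow enough to
leave beta/gamma activity intact; only the filter order is externally
prescribed, the bandwidth is our choice. Filtering is forward-only with zero
initial state so the identical code can run on a live stream; group delay is
not compensated and no start-up samples are dropped. Tests that quantify
attenuation therefore discard the transient explicitly (the 0.5-Hz high-pass
needs several seconds to settle on a DC step). Linear filters commute, so
applying the high-pass first is cosmetic.

## Wavelet transform and phase

The complex Morlet mother wavelet `ψ(t) = π^(−1/4) e^{2πi f_c t} e^{−t²/2}`
has the analytic spectrum `ψ̂(f) = √2 π^(1/4) e^{−2π²(f−f_c)²}`, peaking at
the center frequency `f_c`. A single scale `a = f_c/f_a` is analysed; the
`1/a` (not `1/√a`) normalization of the transform is kept as stated because
any amplitude normalization cancels in the phase.

Numerics:

* The transform is a Riemann-sum convolution on the sampling grid, evaluated
  with an FFT (`scipy.signal.fftconvolve`). The kernel is truncated at 8
  envelope standard deviations (|t/a| ≤ 8); the slow reference path
  (`cwt_direct`) truncates at 6, giving a relative truncation discrepancy
  ~1e−8, far below the 1e−6 equivalence tolerance used in tests.
* Boundary policy: phases are computed once over the full recording and then
  sliced into windows. Isolated segments are reflect-padded 1 s per side and
  the pads discarded. At the default scale the wavelet envelope std is
  `a = 1/12 s ≈ 83 ms`, so 1 s of padding makes edge error negligible.
* Phase samples where |T| < 1e−12 × max|T| are numerically meaningless and
  returned as NaN; all downstream averages skip them sample-wise.

## Synchronization index

`γ(k,l) = sqrt(⟨sin Δφ⟩² + ⟨cos Δφ⟩²)` — the resultant length (the standard
phase-locking value). The defining endpoint properties (γ = 1 under perfect
locking via the trigonometric identity, γ = 0 for a uniform phase-difference
distribution) hold for the square-rooted form, which is the one implemented;
the squared resultant satisfies the same two calibration points, so both
conventions agree exactly at the endpoints used for calibration tests.

Global synchronization γ̄ is the *mean* of the N(N−1)/2 distinct pairs and
the channel index γ(k) the mean of the N−1 pairs involving k. Averaging
(rather than bare summation) is required for the indices to stay in [0, 1]
and to be comparable across subset sizes.

Window membership: a sample belongs to window [start, end) iff its timestamp
lies in that half-open interval; all intervals in the package (annotations,
windows, timelines) are half-open, which removes every adjacency ambiguity
on the 0.5-s grid.

The (f_c, f_a) grid search maximizes the percentage difference
`100·(⟨γ̄⟩_ictal − ⟨γ̄⟩_interictal)/⟨γ̄⟩_interictal` over a default grid
f_c ∈ {0.6, 0.8, …, 2.0} Hz × f_a ∈ {5, 6, …, 20} Hz, which brackets the
defaults (1, 12) with ample margin. Exact grid bounds are our choice.

## Windowing, taxonomy and features

1-s windows at 0.5-s step. Relative to each annotated seizure, windows are
coded 0 (no overlap), 1–2 (partial overlap at onset), 3 (first embedded),
4 (interior embedded), 5 (last embedded), 6–7 (partial overlap at offset);
binary ictal ground truth is code ≠ 0. Geometry notes: a grid-aligned onset
leaves a single leading partial window (code 1, code 2 absent), and a
seizure shorter than one window has only partial windows, coded 1, 2 from
the front and 7, 6 from the back (3–5 absent) — a documented degenerate
case.

Features per window: γ̄ over the active subset, and normalized amplitude
`A_m(n) = A_m / A_ref`, where `A_m` is the mean |signal| over the subset's
channels and window samples. `A_ref` is the same statistic over the first
30 s of the recording, assumed interictal; if a seizure intrudes there, the
earliest seizure-free 30-s stretch (scanned on the 0.5-s grid) is used
instead. Amplitudes always average over the *active* subset's channels: a
reduced headset has no access to the remaining electrodes, so using all 19
would not be deployable. The normalization exists because absolute EEG
amplitude varies strongly with age and electrode impedance; the synthetic
cohort spreads per-subject amplitude scales 3× to verify the feature
absorbs it.

## Detector

Training rows: ictal = windows with taxonomy 3–5 and γ̄ above the 95th
percentile of the interictal γ̄ of the training subjects (computed per fold,
never touching the held-out subject); interictal = seeded uniform subsample
at 3 interictal rows per ictal row. Partially overlapping windows (codes
1, 2, 6, 7) never train the model but count as ictal ground truth at test
time. Features are standardized by the training rows' mean and standard
deviation. Classification is an unweighted 10-nearest-neighbour majority
vote in the scaled plane; with k even, a 5–5 tie resolves to interictal,
biasing against false positives. The empirical quantile uses linear
interpolation between order statistics.

LOOCV: one fold per subject; per-fold interictal subsamples draw from
independent seed streams spawned from the master seed, so the whole
cross-validation is bit-for-bit reproducible. Whether the original analysis
drew its interictal sample once or per fold is not determinable; per-fold
seeded sampling is cleaner and is what is implemented.

Post-processing relabels every isolated ictal window as interictal, making
two consecutive windows (1.5 s of merged timeline) the shortest possible
detection. It is idempotent and never increases ictal time (verified
exhaustively for all sequences up to length 12).

## Metrics and fragmentation

Window decisions are OR-merged onto a 0.5-s timeline (a half-interval is
ictal iff either covering window is). OVR and PERR are computed on that
timeline with exact interval arithmetic against the annotated seizure
intervals; FP and MT are counted on the raw window decisions (windows with
taxonomy 0 classified ictal, and maximal runs of them). Per-subject values
are aggregated as cohort mean ± SD.

SFRAG = 100 − OVR of the merged, *non-post-processed* decisions restricted
to an interval of abnormal activity. The identity OVR + SFRAG = 100 on
shared inputs is exact and asserted. Resolution limit: with 1-s windows,
interruptions shorter than ~0.5 s are generally invisible, and gap lengths
blur by roughly half a window at each edge — recovery tests therefore use
gaps ≥ 1.5 s and a ±10-percentage-point band.

## Synthetic EEG generator

The generator is the package's test bed; its defaults define the conditions
every stochastic check runs under.

* Background: per-channel pink noise (1/f, 15 µV RMS) plus alpha-band
  (8–12 Hz) narrowband noise, 6 µV RMS, 2.5× stronger on O1/O2. Channels
  are statistically independent — alpha is realized as independent filtered
  noise per channel precisely so that no spurious inter-channel locking
  leaks into the interictal γ̄ (a shared constant-phase sinusoid would be
  phase-locked by construction).
* SWD: one cycle = Gaussian-derivative spike (20 ms width, early in the
  cycle) + full-cycle slow wave, repeating at 3 Hz (configurable within the
  clinical 2.5–5.5 Hz band). The spike's harmonics put power at the 12-Hz
  analysis frequency. The waveform is shared across channels with
  per-channel gain (σ = 0.1 around 1) and a constant per-channel time shift
  drawn from the 0.3-rad phase jitter, then added on top of the background
  at 4× its mean absolute amplitude. Ictal windows thus show γ̄ ≈ 0.9 and
  A_m(n) ≈ 4 against an interictal baseline of γ̄ ≈ 0.4, A_m(n) ≈ 1.
* Schedule: 6 seizures per 600-s subject, durations triangular on [3, 20] s
  with mode 10 s (matching the stated minimum/maximum/median without
  inventing a distribution family), non-overlapping, ≥ 10 s apart, none in
  the first 30 s (the amplitude reference), onsets on a 0.1-s grid so they
  mostly fall off the window grid.
* Fragmentation: gaps strictly inside seizures in one of three modes —
  spike loss (slow delta persists), cessation (background only, the
  default), or desynchronization (per-channel, per-cycle random time
  offsets, destroying inter-channel locking while amplitude persists).
* Interictal events: short (0.6–1.8 s) generalized epileptiform bursts
  (expected 2 per 600-s recording) to exercise false positives, and frontal
  blink artifacts (~1/min, 120 µV on Fp1/Fp2).

What the generator does *not* emulate: realistic thalamocortical dynamics,
age-dependent spectra, muscle/electrode artifacts, eye-state changes, or
the heavy-tailed amplitude statistics of real scalp EEG. Passing recovery
tests therefore demonstrates the pipeline's correctness and internal
consistency on data with the assumed structure — not clinical performance,
which can only be established on real recordings.

## Problem sizes and scope choices

The LOOCV recovery check uses 10 subjects × 600 s × 19 channels at 250 Hz
(≈ 1199 windows/subject); fragmentation recovery uses fixed 16-s seizures so
that a 10 % gap still respects the 1.5-s minimum gap length. These sizes
give stable statistics for the stochastic assertions while keeping the full
suite fast. EDF writing restricts itself to 1-s data records and 16-bit
encoding — the quantization step of the chosen per-channel physical range
bounds the round-trip error, which tests assert.

## Known limitations

* Filters are causal by design; wavelet phases near sharp transients are
  therefore slightly delayed relative to a zero-phase implementation.
* The detector offers binary decisions only (no probabilities), and the
  nearest-neighbour archive grows with the training cohort.
* Fragmentation is a retrospective quantity: it requires the abnormal
  interval to be marked first and post-processing to be off.
* γ̄ alone does not separate ictal from interictal windows when discharge
  amplitude approaches the background level — this overlap is reproduced by
  the generator at unit gain and is the reason the classifier uses two
  features.
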