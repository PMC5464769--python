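# Methods

This note documents the models behind the synthetic-data generators, the
estimators, the numerical choices, and what the validation suite does and
does not establish.

## Synthetic locomotor activity

Per-bin counts are Poisson with a rate set by a square circadian gate:
`base_rate` inside the active phase (duration α), `rest_rate` outside. A
square gate rather than a sinusoid was chosen because every downstream
analysis is onset/offset-based; smoothing of the edges is left to the
Poisson noise. The phase is a single bookkeeping variable: under full
LD12:12 cycles the expressed onset is clamped to dark onset; on release
into free run the onset steps by −ψ once (so the free-running onset series
extrapolates back to the entrained onset minus the phase angle ψ) and then
advances by τ per cycle; re-entry into LD12:12 re-clamps immediately.
Light pulses in free run add a step: pulses falling at circadian times
CT 12–20 apply the configured delay, CT 20–4 the configured advance (the
conventional delay/advance zones of the mouse phase-response curve), both
stored in circadian hours with advance positive.

Masking is multiplicative: rates in LIGHT are scaled by (1 − m), m ∈ [0, 1].
Dark activation (`dark_gain`) scales DARK rest-phase bins, but only where
the animal has seen light within the preceding 24 h — masking is a response
to the light stimulus, so sustained DD is not amplified (a literal
"every dark rest bin" rule would also contradict the observation that
rest-phase activity under DD does not differ between the genotype presets).

Defaults describe a wild-type-like C57BL/6 mouse: τ = 23.8 h, α_LD = 12 h,
α_DD = 12.3 h, ψ = −0.49 h, base 3.8 and rest 0.25 counts per 5-min bin
(≈ 550 movements/day), m = 0.5, 5-min bins. The `mutant-like` preset of the
pipeline (m = 1, α_DD = 14.8 h, ψ = +0.36 h, dark gain 2, lower overall
rate) is a calibration for a light-hypersensitive genotype, not a claim
about any particular animal.

## Synthetic hypnograms and EEG

Hypnograms are a first-order Markov chain over {W, TDW, NREM, REM} at 4-s
steps with one row-stochastic transition matrix per light condition; TDW is
entered only from W. The default matrices give roughly 30% W / 3% TDW /
55% NREM / 12% REM in the light and 51/23/22/4% in the dark, with bout
lengths of minutes — coarse but sufficient for time-course and classifier
validation. The generator keeps the ground-truth TDW labels;
`collapse_tdw()` yields the W/NREM/REM hypnogram a visual scorer would
produce.

Epoch signals are 1/f-shaped Gaussian noise (power ∝ f^−slope, clamped
below 0.5 Hz, scaled to a target rms in µV) plus sinusoidal band peaks with
per-epoch frequency jitter: a 2-Hz delta peak for NREM, theta peaks for TDW
(centre 8.0 Hz in light, 8.75 Hz in dark — a 0.75-Hz dark offset) and REM,
and no peak for quiet wake. The TDW theta amplitude (12 µV over a 12-µV rms
background) puts the theta/total ratio near 0.55, i.e. clearly
theta-dominated; quiet wake sits near the 1/f floor. Sampling is 256 Hz so
4-s epochs give exact 0.25-Hz bins. What this generator does *not* emulate:
spindles, artifacts, state-transition dynamics inside epochs, EMG, and
inter-animal spectral variability — classifier performance on real
recordings must be established separately; passing tests here show the
algorithm implements its stated rules and separates the synthetic states.

A per-epoch `nrem_delta_scale` hook modulates the NREM delta amplitude, used
to emulate homeostatic delta decay or rebound; the Markov chain itself has
no sleep-pressure dynamics, so recovery curves from the default generator
test bookkeeping identities, not homeostasis biology.

The ERG generator places a negative raised-cosine trough (depth = a-wave
amplitude, support 5–35 ms) and a disjoint positive bump (peak = b − a,
support 35–95 ms) after the stimulus, so the amplitude extractor recovers
the requested (a, b) exactly at zero noise.

## Estimators and numerical choices

**Onset/offset detection.** Counts are smoothed with a centred 30-min
moving average; a candidate onset is the first run of ≥6 smoothed bins at
or above 25% of the cycle's smoothed maximum following ≥12 bins below it
(offsets: the time-reversed rule). The scan window extends one smoothing
width before each cycle boundary (smoothing can push a run across it), an
event claimed by the previous cycle is not reported twice, and the
quiescence window must lie inside the data so bouts truncated by the
recording edge are never reported. The event time is then refined on the
raw bins by a maximum-likelihood Poisson changepoint in the local window,
with rest and active rates estimated from the flanking bins — the smoothed
crossing itself is biased early by about 1.5 bins and adds ~1-bin jitter,
while the ML refinement is unbiased with ~0.05 h jitter at default rates.
Cycles without a detectable event yield NaN. For cohort summaries, onsets
whose regression residual exceeds 5 robust standard deviations are dropped
(`reject_onset_outliers`) — the curation step otherwise done by eye on
actograms; a single spurious bout otherwise dominates the phase-angle
extrapolation.

**Periodogram.** `Qp = Σ_h N_h (M̄_h − M̄)² / σ̂²` with `σ̂² = Σ(x − M̄)²/n`,
testing every bin-multiple period in 20–28 h. Under arrhythmicity Qp is
χ²_{K−1}; the reported `signif_line` is the conventional pointwise 0.99
line. Because ~100 periods are tested, the pointwise line is exceeded by
pure noise in roughly a quarter of runs, so `peak_significant` applies a
Bonferroni correction across tested periods. A constant trace has undefined
Qp and is flagged rather than scored.

**Phase angle and phase shift.** ψ follows the extrapolation definition
(DD regression evaluated at the last LD day, subtracted from the mean LD
onset; negative when the free-running onset extrapolates later). Phase
shifts average 3 pre-pulse and 10 post-pulse onsets (first post-pulse day
excluded), projected with the pre-pulse fitted τ and converted to circadian
hours (×24/τ). Validation places the pulse after 14 free-running days so
the pre-pulse regression identifies τ well; recovery is asserted on the
mean over 10 seeded animals per condition, matching the group design such
experiments use — single-animal estimates carry ~0.07 h noise from
onset-detection jitter, which a 3-onset pre-pulse mean cannot reduce.

**Spectra.** One Hann-tapered periodogram per 4-s epoch (no segment
averaging: 0.25-Hz bins are the point), power density scaled so that
Σ power · Δf equals the taper-power-normalised variance of the windowed
epoch. Band sums include bins whose centres lie in the closed band. The
theta-ratio numerator covers bin centres in [TPF − 1, TPF + 1] even where
that dips below the 3.5-Hz edge of the denominator, following the
±1-Hz-around-the-peak definition. TPF ties (flat spectra) return the lowest
frequency, flagged. TDW context rules run as a single forward sweep (final
labels to the left, input labels to the right), then one isolation pass on
the frozen result; no fixpoint iteration. The isolation rule demands ≥3
flanking W epochs and is exposed as a parameter, since "3" could also be
read as "exactly 3"; the first epoch of a file cannot become TDW (no
in-file predecessor) and the last is exempt from the following-epoch rule.

**Homeostasis.** Hourly state minutes always sum to 60 (TDW is reported
separately and inside total W). NREM delta power is the mean 1–4 Hz band
power over the NREM epochs of each hour; hours with fewer than 75 NREM
epochs (5 min) are missing. The percent scale divides by the mean NREM
delta power in a reference window, default the last 4 h of the light period
of the two baseline days (ZT8–12) — a conventional, configurable choice;
both absolute and percent scales are emitted since either normalisation is
defensible. Recovery accumulation aligns recovery hours to a (day-folded)
baseline by ZT and cumulatively sums the difference.

**Pipeline.** Each animal derives an independent seed stream from the
master seed; sub-generators (activity, hypnogram, EEG, ERG) use fixed
per-module stream offsets, so runs are bit-identical for a given config.
The manifest lists every output file with a SHA-256 checksum. Group
contrasts are Welch (unpaired) or paired t-tests, two-sided, with
zero-variance inputs flagged. Figures are optional and excluded from the
determinism contract. Validation problem sizes (10–28 day activity records,
one to three days of EEG, 1M epochs for the Markov stationarity check) were
chosen so each check has comfortable statistical power while the whole
suite runs in well under a minute per module on one CPU.

## Known limitations

- The detector's threshold is a fraction of the per-cycle smoothed maximum,
  so cycles whose active phase is entirely masked (m = 1 with zero rest
  rate in the light) can yield spurious thresholds on pure noise; the
  outlier-rejection pass handles the resulting rare mis-detections.
- The light/dark spectral ratio is a linear percent difference, not a log
  ratio; spectra are absolute (µV²/Hz) with normalisation left to the
  caller.
- EDF export is not provided; epoch signals interchange as raw float32
  matrices with a JSON sidecar, and EDF reading requires mne.
- The TDW classifier is validated against its own generator's ground truth;
  agreement with visual scoring of real EEG is outside what these tests can
  show.
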