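# Methods

This note documents the models, estimators and numerical choices behind
`fearphys`, what the synthetic-data generators do and do not emulate, and
the known limitations a user should weigh before trusting a number.

## Photometry pipeline

Stage order is fixed: downsample → smooth → peri-event window → per-trial
detrend → isosbestic subtraction → metrics. The order matters (smoothing
after windowing would leak edge transients into the trial; detrending
before downsampling would fit the noise floor at full rate), so the
pipeline asserts and records it.

- **Downsampling** is by non-overlapping block means (default factor 50),
  which is simultaneously an anti-alias average and a deterministic
  decimation; a trailing partial block is dropped and the effective
  sampling rate divides accordingly.
- **Smoothing** is a zero-phase moving average: a boxcar (default 10
  samples) run forward then backward with reflection padding, i.e. an
  effective triangular impulse response of unit DC gain and no phase
  shift. Reflection padding avoids edge transients inside peri-event
  windows.
- **Peri-event windows** default to −30…+40 s around tone onset, endpoints
  inclusive on the time axis (a 70-s window at 20 Hz has 1401 samples).
  Trials whose window leaves the recording are excluded with a warning,
  never zero-padded or truncated — padding would corrupt the linear fit.
- **Detrending** fits each channel against time by least squares (degree 1
  by default) over the *entire* window, transient epoch included, and
  ΔF/F = 100·(raw − fit)/fit. A trial whose fitted signal is not strictly
  positive is marked invalid rather than divided through.
- **Correction**: corrected = ΔF/F(465) − ΔF/F(405). Because the simulator
  (and, to good approximation, a real rig) applies motion as the same
  fractional modulation of both channels, the subtraction cancels it; the
  test suite verifies residual corrected power stays within noise bounds
  with transients disabled.
- **Metrics**: the peak is the maximum of the corrected signal over a
  half-open window (0, 5] s after onset — half-open so a pre-onset sample
  can never be reported as a "response to tone onset"; the AUC is the
  trapezoidal integral over (−5, 0) and (0, 5) s on the seconds time axis.
  The session summary averages the first two trials. Peak values are
  flagged for log transformation downstream, since peak ΔF/F distributions
  are right-skewed.

### Known bias: bandwidth attenuation and detrending lift

Two systematic effects reduce reported peaks relative to the true
underlying transient, both properties of the *prescribed processing*, not
implementation error:

1. With a ~1 kHz input, 50× downsampling gives ~20 Hz; a 10-sample
   forward-backward boxcar is then ~0.5 s of smoothing. For a fast
   indicator transient (rise 0.2 s / decay 1.0 s, GCaMP6s-like) this
   attenuates the peak by ≈9 %. The attenuation factor is exactly
   predictable by pushing the bare kernel through the same linear
   operators, and a regression test pins it.
2. Fitting the trend over the full window, transient included, lifts the
   predicted signal by amp·∫K/T (≈2 % of the peak for a 1-s-decay kernel
   in a 70-s window), lowering ΔF/F correspondingly.

Both effects are identical across groups processed with identical
settings, so group *comparisons* are unaffected; absolute peak values are
lower bounds. The amplitude-recovery property test therefore runs at
transient kinetics slow enough (0.5/2.0 s) that these effects do not
dominate, and recovers true peaks with ≤10 % median error at SNR ≥ 5.

## Spontaneous EPSC detection

Detection runs on a lightly smoothed trace (0.5 ms boxcar; configurable)
to suppress sample-level noise without distorting millisecond kinetics.
The threshold is robust: median − k·1.4826·MAD with k = 3.5 by default, so
it does not inflate with event rate. Candidate peaks closer than 5 ms
merge. A candidate is accepted only if it rises at least `min_amp_pa`
(default 5 pA) above its local minimum within the preceding 5 ms; this
single criterion rejects both free-standing noise maxima and noise ripples
riding on the decay tail of an earlier event — which pass a pure amplitude
threshold for tens of milliseconds — while keeping genuine overlapping
events, whose rise from the inter-event dip is nearly their full
amplitude.

Amplitude is the mean of the smoothed trace over ±0.5 ms around the peak
(averaging suppresses the upward argmax-selection bias of reading a single
noisy extremum) referenced to the median over −20…−5 ms before the peak;
when another detected event contaminates that window, the inter-event dip
is used instead. Kinetics — 10–90 % rise and peak-to-1/e decay, reported
in ms — come from a per-event biexponential least-squares fit by default:
first-crossing measurements on noisy traces are biased (early crossings
shorten the decay and lengthen the rise by ~σ/slope), whereas the fitted
waveform's analytic crossing times are unbiased at SNR ≥ 5 within ~1 %.
Interpolated-crossing kinetics remain available
(`kinetics_method="crossing"`). Events too close to a trace edge or
neighbour get NaN kinetics but still count toward frequency.

These detection criteria (threshold form, windows, definitions of rise and
decay) are this package's own conventions — common choices in the field,
all exposed as `DetectionParams` and logged.

## Evoked measurements

Baseline is the mean over −10…−1 ms before the *first* stimulus. The
response amplitude is the largest baseline-referenced inward deflection
within 20 ms after the stimulus, peak-averaged as above. For the second
pulse of a 50-ms pair, the decaying tail of the first response is removed
by a mono-exponential fitted to the 20 ms before the second stimulus and
extrapolated under the response (with a flat-mean fallback when the fit is
degenerate); at a ~10 ms decay the overlap is ~2 % of the second response,
so the correction is small but kept on by default (`tail_subtraction`).
Negative computed amplitudes clip to zero with a warning.

- **PPR**: per sweep, A₂/A₁. The *cell-level* value defaults to
  mean(A₂)/mean(A₁) — the estimate one gets from averaged traces — because
  averaging per-sweep ratios carries an upward Jensen bias of order
  CV(A₁)², about +7 % under binomial quantal variability at 20 sites,
  p = 0.4, 20 sweeps. `method="mean-of-ratios"` is available.
- **1/CV² = μ²/σ²** and **VMR = σ²/μ** use the n−1 sample variance and
  warn when n ≠ 20 (the conventional count). The plug-in 1/CV² is the
  reported definition, but at n = 20 it overestimates the population value
  by ≈(n−1)/(n−3) ≈ 12 %; `bias_corrected=True` applies the normal-theory
  unbiased form (n−3)/(n−1)·μ̂²/s² − 1/n, which the recovery study uses.
  VMR's corresponding bias is ≈CV(μ̂)² < 1 % and is left uncorrected.
- **AMPA/NMDA**: |−70 mV peak| over the baseline-subtracted +40 mV current
  read at exactly onset + 50 ms (linear interpolation between samples);
  magnitudes are used because holding potentials flip the sign. The ratio
  is refused when the NMDA component is within 3 SDs of the baseline
  noise. Junction potentials are not compensated anywhere, matching the
  recording convention the data follow.

## Statistics

- Two-group comparisons follow a recorded decision trail: Shapiro–Wilk per
  group at α = 0.05 (scipy's implementation; its p-value is consumed, not
  re-derived), an optional natural-log re-test for right-skewed positive
  data, Levene's test, then an equal-variance unpaired two-sided t-test if
  assumptions hold, Mann–Whitney otherwise. With null normal data the
  whole gate's type-I error stays 0.05 ± 0.01 (verified over 10⁴
  replicates).
- Mann–Whitney uses the exact null distribution when n₁+n₂ ≤ 12 without
  ties, otherwise the normal approximation with tie and continuity
  corrections; the suite checks exact p-values against full enumeration.
- The two-way repeated-measures (mixed) ANOVA partitions sums of squares
  by hand — between-subjects: group + subjects-within-group error;
  within-subjects: time + time×group + time×subjects error — and is
  cross-checked against an independent implementation (pingouin). Degrees
  of freedom are uncorrected: no Greenhouse–Geisser adjustment by default,
  matching the convention of reporting nominal (levels−1),
  (levels−1)(N−groups) df. Designs must be balanced and complete; nothing
  is imputed. No multiple-testing correction is applied anywhere; α = 0.05
  two-sided throughout.

## Simulators: what they emulate, and what they don't

- **Photometry** (`simulate_photometry`): per channel, an exponential
  photobleaching trend (single exponential per channel — the simplest
  trend the per-trial linear fit is designed to remove locally), shared
  fractional motion artifacts (Poisson-timed Gaussian bumps, SD
  `motion_frac_sd`), tone-locked biexponential indicator transients in the
  465-channel only (added after motion scaling, so they are
  multiplicatively independent of bleaching and the detrend+subtract
  pipeline is approximately exact over 70-s windows), and white Gaussian
  noise. Default schedule: six 30-s tones, 3-min inter-trial interval,
  first onset at 60 s. Bleaching and artifact magnitudes are free
  parameters — realistic choices, not measurements. Not emulated:
  hemodynamic contamination, wavelength-dependent motion coupling,
  spike-to-calcium nonlinearity, sensor saturation. Passing tests show the
  pipeline recovers what this generative model produces; they cannot
  certify artifact cancellation when the two channels decouple.
- **Spontaneous EPSCs** (`simulate_sepsc_trace`): Poisson event times,
  truncated-normal amplitudes, a common biexponential kernel (default taus
  2.091/8.573 ms, chosen so the analytic 10–90 % rise is 2.16 ms and
  peak-to-1/e decay 10.93 ms, typical measured values), Gaussian noise.
  Kernels are unit-peak on the sample grid, so a noise-free event's trace
  extremum equals its nominal amplitude exactly. Truth kinetics use the
  analyzer's own definitions so recovery is well-posed. Not emulated:
  kinetic heterogeneity across synapses, dendritic filtering, series
  resistance artifacts.
- **Evoked release** (`simulate_evoked_sweeps`): A = q·Binomial(N, p) per
  pulse, facilitation multiplying p on the second pulse (rejected if
  p·facilitation > 1), responses at 50 ms spacing, defaults N = 20,
  p = 0.4, q = 8 pA, 20 sweeps at a nominal 0.05 Hz. Closed forms
  E[A] = Npq and Var[A] = Np(1−p)q² are verified to 3 SE in tests.
- **AMPA/NMDA pairs** (`simulate_ampa_nmda_pair`): the +40 mV sweep mixes
  a fast outward component (half the AMPA conductance, linear I–V assumed)
  with a slow NMDA-like component scaled so the current at onset + 50 ms
  equals the requested value exactly.

All generators are bit-reproducible given (config, seed).

## Problem sizes and numerical conventions

The recovery study in `scripts/acceptance.py` uses ten 120-s sweeps for
frequency, five 60-s sweeps for amplitude, 200 isolated events for each
kinetic constant, 200 simulated cells × 20 sweeps for PPR, and 500 cells
for 1/CV² and VMR — sizes at which the estimators' standard errors sit
well below the quantities measured, while the whole script completes in a
couple of minutes on one CPU.

Time is seconds everywhere in memory; milliseconds appear only in reported
rise/decay values and parameter names suffixed `_ms`. Arrays are float64,
and the HDF5 layouts round-trip bit-exactly (CSV round-trips through
full-precision `%.17g` with round-trip float parsing). Event windows are
half-open [start, end) in sample space; printed time axes include both
endpoints. Validation is total: a file or object violating an invariant is
rejected with the invariant named, never silently repaired.

## Limitations

- Absolute photometry peaks are biased low at fast indicator kinetics (see
  above); compare groups, not absolute values, or slow the smoothing.
- The sEPSC detector is tuned for events ≥ ~5 pA over ~1.5 pA RMS noise;
  at lower SNR, misses grow before false positives do (the acceptance
  filter is conservative).
- The binomial quantal simulator has no intersite heterogeneity, no
  desensitization, and stationary p across sweeps; 1/CV² and VMR
  interpretations inherit those assumptions.
- `two_way_rm_anova` requires complete balanced data by design; unbalanced
  or missing-cell designs need a mixed-effects model, out of scope here.
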