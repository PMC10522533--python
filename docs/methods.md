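# Methods notes

This note documents the models, parameter choices and numerical
conventions behind the package, and what the synthetic-data tests do
and do not establish about real recordings.

## Stimulus model

Synthetic vocalizations are 350 ms glottal-like harmonic stacks
(twelve harmonics with 1/k rolloff) on an F0 glide, shaped by two
formant-like Gaussian spectral resonances, an attack–decay amplitude
contour, occasional 4–8 Hz amplitude-modulation bursts and a small
aspiration-noise floor, then RMS-equalized (target 0.1) and given 10 ms
linear onset/offset ramps. All five emotion categories draw from one
shared parameter distribution (F0 120–300 Hz, glide −25…+25%, noise
floor 6–14%): the design requires the stimulus set to be acoustically
matched across categories — the category label tags an exemplar rather
than an acoustic recipe. An earlier variant with category-specific
registers produced category-linked envelope structure that leaks into
the target-frequency bins of the sequence envelope, which a matched set
must not do. Stimuli are synthesized at 8 kHz; all spectral content of
interest sits well below 4 kHz, and the sequence-level control
analyses (57.6 s renders through a 64-band filterbank) stay cheap.

### Frequency scrambling

The control manipulation shuffles complex rFFT coefficients within
consecutive 200 Hz windows aligned from 0 Hz (DC and Nyquist fixed;
Hermitian symmetry implicit in the rFFT), inverts, applies the original
Hilbert envelope, RMS-equalizes and re-ramps. Magnitude and phase move
together under one seeded permutation per window by default; an
`independent` mode draws separate permutations. Envelope handling has
two modes:

* `multiply` (default): the original envelope multiplies the scrambled
  carrier. The carrier keeps its own random envelope ripple, so at
  matched RMS the output's envelope mean sits ~2–3% below the
  original's (a noise-like carrier has a lower crest-adjusted envelope
  mean). Envelope-spectrum comparisons therefore normalize the envelope
  by its mean (see controls below).
* `impose`: alternating projections (envelope flattening /
  band-limiting to the original's 99%-power bandwidth, three rounds
  plus a final flattening) give an output whose temporal envelope
  matches the original almost exactly while keeping the coarse spectral
  distribution; useful when exact envelope preservation matters more
  than literal simplicity.

Scrambling demonstrably halves nothing else: duration, rate and RMS are
preserved; the smoothed (20 Hz low-pass) temporal envelope correlates
with the original at r ≈ 0.85–0.99; spectral center of gravity moves by
<10% on harmonic complexes; normalized autocorrelation at the pitch lag
collapses, so the harmonicity-to-noise ratio drops for every stimulus.

## Sequences

144 slots of 400 ms (350 ms sound + 50 ms gap) give the 2.5 Hz base
rate and 57.6 s duration; 1-based positions 3, 6, …, 144 carry the
target category (0.833 Hz). 24 unique targets and 48 unique non-targets
(12 per non-target category, sampled seeded from the 84-sound set) each
appear exactly twice, with every unique token presented once before any
repeat (applied to targets and non-targets alike). Six attention probes
(RMS ÷ 10) land on random non-target slots whose audio lies fully
outside the 2 s linear fade-in/out. A paired scrambled sequence reuses
the identical slot order with scrambled stimuli.

## Acoustic negative controls

Per simulated participant, a fresh scrambled stimulus set and a paired
sequence are built; the summed spectral magnitude at the first five
target harmonics (base bins excluded) is computed for (a) the
mean-normalized Hilbert envelope of the rendered audio and (b) the
simulated cochlear response, and a paired one-tailed t-test (intact >
scrambled) runs across participants. Two choices matter:

* *Fresh scrambles per participant.* With a single shared scramble
  realization the only between-participant variance is slot ordering,
  which is tiny, so any fixed realization-specific offset produces
  arbitrarily large |t| of arbitrary sign. Per-participant scrambling
  moves that offset into between-participant variance and the null test
  becomes calibrated.
* *Mean-normalized envelopes.* The multiply-mode envelope-level deficit
  is a pure scale effect; normalization leaves the temporal-structure
  comparison the control is about.

The cochlear model is an ERB-spaced bank of 64 fourth-order gammatone
filters (Slaney parameterization, scipy's design; center frequencies
from 50 Hz by Slaney's closed form), half-wave rectified and summed
across bands. The rectified fine structure is harmonicity-sensitive, so
the scrambled response's spectrum can differ in overall level — leaning
in the scrambled > intact direction — while the one-tailed contrast
stays non-significant.

## Synthetic EEG

The response model is the one the analysis presumes: per channel c and
time t (relative to sequence onset),

    x_c(t) = gain_p · topo_b(c) · Σ_k B_k cos(2π k f_b t + φ_k) · v(t)
           + gain_p · g · topo_t(c) · Σ_m T_m cos(2π h_m f_t t + ψ_m) · v(t)
           + gain_p · g · topo_e(c) · Σ_j ERP_j(t − onsets)
           + n_c(t)

with v(t) the stimulus volume envelope (2 s linear fades),
h_m ∈ {1, 2, 4, 5, 7} the non-base-coincident target harmonics, g = 1
(intact) or `scrambled_gain` (scrambled), gain_p ~ lognormal(0, 0.2)
per participant, and n the noise. Defaults: B = (2.5, 1.2, 0.6) µV,
T = (2.0, 1.5, 1.0, 0.7, 0.4) µV, noise 6 µV broadband with power
∝ 1/f (flattened below 0.1 Hz), scrambled gain 0.6, ERP components at
152 ms (50 ms FWHM, 0.7 µV) and 339 ms (90 ms, 0.8 µV), 24
participants, 512 Hz, 128 BioSemi channels + 2 mastoids. The response
amplitudes are set so a single participant's 10-trial average carries
per-harmonic spectral SNR of roughly 5–20 — a robust tagging response —
rather than mimicking any particular dataset's noise level.

Design notes:

* *Topographies are mean-centered over the scalp* (peak 1, mastoids 0).
  Physical EEG fields integrate to ≈0 over the scalp, and the analysis
  average-references; an all-positive map would lose its scalp mean
  (~0.31 here) at that step, biasing every amplitude-recovery check.
* *Phases are common across participants up to 0.25 rad jitter* and
  fixed across a participant's trials: evoked responses share latency
  across people, and both time-domain averaging and grand-averaging
  across participants require phase coherence.
* *ERP components scale with g* like the steady-state target term; an
  unscaled transient would make the intact−scrambled time-domain
  contrast identically null by construction.
* *Noise* is white Gaussian shaped to 1/f^α in power (per channel, α
  recoverable by log–log regression to ±0.2), mixed through the
  Cholesky factor of a smooth distance-based spatial covariance
  (length 6 cm) so neighboring channels correlate, then rescaled to the
  per-channel σ. FFT lengths are padded to fast sizes (trial lengths
  like 31 539 samples are near-prime).

## Numerical conventions

* Sample counts: `round(duration × rate)` everywhere — 61.6 s at
  256 Hz → 15 770 samples; 52.8 s at 256 Hz → 13 517.
* Spectra: single-sided, 2/N normalization (a bin-centered sinusoid of
  amplitude a reads a; DC and Nyquist carry 1/N). DC is excluded from
  every statistic.
* Filtering is zero-phase (`sosfiltfilt`) throughout; the band-pass and
  notch stages are cascaded second-order sections applied in one pass.
  The 0.1 Hz high-pass settles over ~10 s, well inside the pre-sequence
  margin of continuous recordings.
* Local noise windows: offsets ±2…±13 (12 bins per side after skipping
  the adjacent bin), drop the window's max and min, sample SD with
  ddof = 1. Inside a 25-bin contrast chunk the window is capped at
  offsets ±2…±12. σ = 0 yields z = +∞ if the amplitude exceeds the
  mean, else 0.
* Harmonic selection: longest leading run of z > 2.32 per sequence
  type, maximum across types; an empty selection is reported as "no
  significant response" rather than padded to one harmonic.
* Epoch rejection: an epoch with max |amplitude| exactly 100 µV is
  kept; anything strictly above is deleted. Rejection precedes
  re-referencing and baseline correction. Epoch counts are equalized by
  seeded subsampling without replacement.
* Consecutivity: 25 ms at 512 Hz is 13 samples; a significant window
  must be strictly longer (≥14 consecutive points).
* The time-domain branch stays at 512 Hz (no down-sampling); the base
  rate and its harmonics are notched with 0.5 Hz-wide zero-phase
  band-stops.
* FDR: Benjamini–Hochberg step-up at q = 0.05, across the 128 scalp
  channels (per time point in the ERP branch).

## Known properties and limitations

* *Null calibration of the harmonic z.* Under the exact noise rule the
  nominal p < 0.01 threshold (z > 2.32) exceeds on ~4% of pure-noise
  harmonic bins, not 1%: estimating the mean and SD from 22 bins gives
  a t-like tail (~1.6% even for Gaussian bins), and dropping the
  window's extremes shrinks the SD estimate to ~0.84 of truth. This is
  a property of the statistic as defined, reproduced faithfully here
  and reported by the acceptance script; treat single-harmonic z values
  near threshold accordingly.
* Parameter-recovery scenarios use amplitudes well above the averaged
  noise floor; at realistic (much smaller) response amplitudes the
  baseline-subtracted amplitude is biased low by the Rayleigh noise
  floor around −E|n| per harmonic.
* The ERP window detection/rejection scenarios run with the
  steady-state target term off: with it on, intact and scrambled differ
  at every epoch time point by construction, and "window latency"
  stops being well-defined.
* The null spurious-window rate is computed on directly generated
  per-participant average noise at the pipeline's empirical level
  (0.5 µV, 1/f, spatially correlated) — the FDR-plus-consecutivity
  control is exercised exactly, without the cost of ~5 000 full
  recording simulations.
* The synthetic world omits eye blinks, muscle artifacts, electrode
  drift, non-stationary noise and between-participant latency/topography
  differences beyond a scalar gain and small phase jitter. Passing
  tests establish that the implementation performs the stated
  computations correctly and that the statistics behave as designed on
  data matching their assumptions — not that real recordings will show
  comparable effect sizes.
* Artifact rejection by ICA is out of scope: the pipeline accepts an
  externally cleaned recording.
* Acceptance problem sizes: 24 participants × 10 trials per type for
  the frequency branch, 2 trials per type for the ERP scenarios, 200
  noise-only simulations for the null calibration, 100 null datasets
  for the spurious-window rate, 24 paired sequences for the acoustic
  controls.
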