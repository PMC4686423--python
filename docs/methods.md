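# Methods

This note documents the models and procedures implemented in `localsleep`,
the assumptions behind them, the defaults and why they were chosen, what
the synthetic-session generator does and does not emulate, and the
numerical choices that matter for reproducing results.

## Data model and units

A session is a directory holding a JSON manifest, little-endian float32
binaries for each trace (LFP channels × samples, EEG, EMG), and CSV tables
for spikes, laser trials, and optional per-second state labels. All times
are seconds (float64 in tables), voltages microvolts, sample indexing
0-based, intervals half-open `[start, end)`. Traces are float32 both on
disk and in memory, so write → read round-trips are bit-exact. LFP
sampling must be ≥ 200 Hz so the 70–100 Hz analyses are defined; the
generator uses 1 kHz, the rate typical of downsampled extracellular
recordings.

Laser protocols are 30 s constant-power ON blocks separated by 60–90 s OFF
(5 s blocks are supported through the trial table); effects are always
paired within trial: stimulation `[0, 30)` s against the immediately
preceding `[−30, 0)` s.

## Spectral statistics

Spectra are multitaper estimates with DPSS tapers under the K = 2NW − 1
convention: 19 tapers over 30 s windows (NW = 10) for band-power
statistics, 5 tapers in 5 s windows sliding every 1 s (NW = 3) for
spectrograms. Band power is the sum of one-sided PSD bins with both band
edges inclusive, times the bin width; integrating the spectrum recovers
the signal variance. dB is defined as 10·log₁₀(power ratio) throughout.

Normalized spectrograms take the median power across trials first, then
divide each frequency row by its mean over the 30 s pre-stimulus window
(that order is a documented choice; the alternative order gives nearly
identical pictures but is not what is implemented). Trials whose pre
window precedes the record are dropped with a warning.

Band-power effects are per-trial paired dB differences summarized by the
Hodges–Lehmann estimate (median of Walsh averages) with a 95% CI obtained
by inverting the Wilcoxon signed-rank test — exact null distribution of
W⁺ for n ≤ 25 (subset-sum counting), normal approximation above. At least
6 trials are required for the inversion to be defined.

Channel significance maps apply two published rules independently:
(a) Bonferroni-corrected signed-rank significance of the delta dB change
across channels, and (b) a flag for a ≥ 2% rise in normalized delta power
(delta / 0–50 Hz power, median across trials). The beta/gamma band
defaults to 15–50 Hz with a 12–50 Hz variant available in the config.

## Slow-wave events

The LFP is bandpassed 0.1–5 Hz with a windowed-sinc FIR filter of length
3·fs/f_lo, applied as a single symmetric-kernel FFT convolution — exactly
zero-phase and O(N log N), with reflection padding so record edges see a
continuous signal (this also makes the detector exactly invariant to DC
offsets). Candidate troughs are local minima below −100 μV; each candidate
is paired with the first subsequent local maximum to give a peak-to-peak
amplitude. Candidates whose surrounding 400 ms of *raw* LFP has a standard
deviation above 2000 μV are rejected as artifacts before ranking. The
events kept are the top 3% of peak-to-peak amplitudes within the session:
exactly ⌈0.03·n⌉ events, boundary ties broken by earlier trough time, so
the count on a pure periodic input has a closed form. Event-rate and
amplitude changes are paired per trial and summarized with the shared
signed-rank machinery.

## OFF periods

All single- and multi-unit spikes on a channel (poolable across channels)
enter one point process, binned at 1 ms and smoothed with a Gaussian
kernel of 20 ms SD truncated at ±4 SD to approximate an instantaneous
rate. OFF periods are maximal runs of rate below 10⁻⁹ Hz lasting ≥ 50 ms
— equivalently, stretches with no spike within the truncated kernel
support. Gaps touching the record edges count as OFF periods by default
(documented contract; excludable). The phase of an OFF period is the
delta phase at its midpoint, interpolated circularly.

The chance level of OFF-period time is estimated by fitting a gamma
distribution to the interspike intervals (MLE with location 0;
method-of-moments fallback) and generating renewal trains with the same
spike count; the identical detector runs on each of the (default 1000)
simulations and the observed fraction is compared with the null 97.5th
percentile. Phase uniformity is tested with Pearson's chi-square over 10
bins (dof = 9).

The 1 ms grid blurs the exact gap arithmetic by a few milliseconds: a
single silent gap of G ms in dense spiking yields one OFF period of
G − 160 ms within about ±5 ms.

## Phase locking

Instantaneous delta phase is the Hilbert angle of the 1–4 Hz FIR-filtered
trace, with one filter length at each edge flagged invalid. Phase
conventions: troughs of a negative-going slow wave sit at ±π. Subcortical
channels can be polarity-aligned so the laser-locked deflection is
negative before phase analysis.

The PLV is the magnitude of the circular mean of the per-sample phase
difference pooled over trial windows, with the mean angle reported as the
offset of the second channel relative to the reference. Significance
comes from shuffling the trial pairing (500 permutations); the offset
angle gets a percentile bootstrap CI over trials (500 resamples).

The modulation index is the Kullback–Leibler distance of a phase-binned
distribution from uniform, in bits: MI = Σ pᵢ log₂ pᵢ + log₂ n_bins with
0·log 0 ≡ 0. Spike MI uses 10 equal bins over [−π, π) (left-closed) and
the preferred phase is the center of the fullest bin. Gamma MI bins the
70–100 Hz analytic-signal envelope by delta phase into 100 bins,
normalizes the bin means to sum to 1, and computes the MI on that
distribution; a least-squares sinusoid fit A·cos(φ − φ₀) + c to the bin
profile supplies the preferred phase only (keeping the MI well defined).
Per-unit MI changes are paired per trial (trials with under 10 spikes in
either window are dropped) and summarized by signed-rank inversion.

A practical caveat the synthetic tests quantify: MI measured against the
*estimated* LFP phase is strongly attenuated relative to MI against the
true phase, because background 1–4 Hz activity adds phase noise. This is
a property of the measurement, not a bug; real-data MI values are small
for the same reason, and the laser-locked *change* in MI remains
detectable at ~40 trials.

Circular kurtosis is the mean cosine of twice the deviation from the
circular mean (1 for a point mass, ~0 for uniform). Group comparisons of
per-unit peak phases report the difference with two intervals: a
label-shuffle bootstrap CI (the chance distribution, used for the
significance call) and a resample-with-replacement CI of the difference
itself.

## Single units and spike-history GLM

Units are classified by waveform peak-to-trough time: under 200 μs Narrow
(putative reticular), 200 μs and over Wide (documented boundary
tie-break); when raw mean waveforms are supplied the time is measured on
a 10× sinc-interpolated grid. Rate changes are paired per trial and
summarized by signed-rank inversion.

Onset latency uses 10 ms bins: the 2 s of pre-stimulus bins are
bootstrapped (1000 resamples of trial-mean bin values) to set two-sided
thresholds at α = 0.005 — the per-bin level that corrects for the 10
post-onset comparisons — and the first post-onset bin outside them is
reported. The same machinery serves trial-averaged LFP deflections.

Temporal firing structure is modelled as a discrete-time point process: a
Poisson GLM with log link on 2 ms bins whose covariates are binary spike
indicators at lags 1–50 bins (2–100 ms), fitted per condition
(baseline windows vs stimulation windows; history never crosses a window
boundary). Each coefficient is the log rate gain contributed by a spike
at that lag; bursting appears as a positive coefficient at the (2, 4] ms
lag (array index 1). Cross-condition change at that lag is declared when
the two 95% CIs do not overlap — a conservative rule whose cohort
false-positive rate on null units stays well under 0.1. Fits require
≥ 500 spikes (configurable) and non-convergent fits are flagged and
excluded. With ~95% CIs on 50 lags, one or two chance exclusions of zero
per null fit are expected; per-lag coverage, not joint coverage, is the
calibrated quantity.

## Arousal state and behavior

EMG effects sum 10–200 Hz periodogram power in non-overlapping 1 s
windows; trial effects are paired dB changes, and onset speed is the
second-before vs second-after comparison.

Sleep scoring is semi-automated: wake requires ≥ 5 s of 60–200 Hz EMG
amplitude (Hilbert envelope, Gaussian-smoothed with 50 ms SD) above a
threshold; remaining time is NREM when the smoothed (1 s SD) per-second
<4 Hz : 4–16 Hz EEG power ratio is above a second threshold, REM below
it, with REM additionally requiring ≥ 10 s of immediately preceding sleep
(avoiding wake/REM confusion; labelled NREM otherwise). Thresholds are
normally entered manually while blind to laser timing; the auto-suggestion
uses an Otsu-style two-class split of the log distributions with a
bimodality check (class separation ≥ 2 pooled SDs). When a session is
single-state the split is degenerate, and the fallback anchors on the
absolute EEG ratio (ratio ≥ 1, i.e. sub-4 Hz power dominating 4–16 Hz,
reads as sleep). Sessions where explicit thresholds produce no state
separation raise a quality flag, mirroring the practice of excluding such
sessions.

Motion scoring computes Horn–Schunck optical flow (regularization α² = 1,
100 iterations, intensities scaled to [0, 1], so the trace is invariant
to global luminance scaling) between consecutive grayscale frames; each
frame pair is summarized by the flow magnitude at the point of maximal
motion, the trace is normalized by its mean and smoothed with a 200-frame
moving average.

EEG–EMG coupling is the Pearson correlation of per-trial delta-power and
EMG-power changes, with a pair-resampling bootstrap CI and significance
judged against the 97.5th percentile of |r| under random re-pairing.
Shuffled-onset controls re-place the laser onsets uniformly within
NREM-labelled seconds (full analysis window inside the record) and
recompute a caller-supplied statistic 400 times to produce a null CI.

## Fiber irradiance

Irradiance below the fiber tip combines geometric cone spread and
Kubelka–Munk scattering loss:

I(z) = I₀ · ρ² / ((S·z + 1)(z + ρ)²),  ρ = r·√((n/NA)² − 1),  I₀ = P/(πr²)

for core radius r, numerical aperture NA, tissue refractive index n and
scattering coefficient S (mm⁻¹). Two presets ship: physical mouse
gray-matter values at 473 nm (n = 1.36, S = 11.2 mm⁻¹) and a **calibrated
"paper" preset** (effective n = 1.7437, S = 33.573 mm⁻¹) fitted with
`calibrate_to_depths` so the model reproduces the reference activation
depths (0.4 mm at 1 mW and 0.75 mm at 3 mW input for a 0.21 NA, 200 μm
fiber at a 1 mW/mm² threshold). The closed form approximates the online
transmission calculator commonly used for such estimates, so the fitted
parameters are effective values, not literal tissue constants. Depth at
threshold is the unique root of I(z) = threshold, found by bisection to
10⁻⁴ mm; a surface irradiance below threshold returns depth 0 with a
warning.

## Synthetic sessions: what they emulate and what they don't

The generator produces, at 1 kHz: 1/f background LFP (spectral shaping of
white noise, exponent 1 — the standard LFP assumption); during laser-ON
blocks an asymmetric delta oscillation (fundamental plus phase-locked
second harmonic, cos φ − a·cos 2φ with a = 0.3, giving deeper troughs
than peaks) whose instantaneous frequency wanders around 2 Hz; discrete
large slow-wave events (negative trough then positive peak, 350–600 μV)
injected at a subset of ON-block delta troughs — these are the labelled
ground-truth slow waves, their number tied by a census to ~3% of the
session's candidate minima so a top-3% detector can recover them;
delta-phase-modulated 70–100 Hz amplitude; occasional 9–15 Hz spindle
transients; optional ±7000 μV alternating-sign artifact bursts (which the
detector's 2000 μV window-SD rule rejects).

Injected delta power is calibrated **per ON block as a gain on that
block's own background delta power** (measured by Welch periodogram), so
the realized dB change is homogeneous across trials and the
Hodges–Lehmann recovery is unbiased; with constant absolute injected
power the per-trial dB distribution is skewed and the robust estimator
sits visibly below the plain median — a real property of dB-of-ratio
statistics worth knowing when simulating.

OFF periods are placed at ON-block delta troughs with probability 0.5 and
10 ms jitter, log-normal durations with median 122 ms (σ = 0.35 log
units), giving roughly 12–16% of ON time silent. Spike trains come from
thinning a conditional intensity: base rate × von Mises phase modulation
(normalized to mean 1) × multiplicative per-2 ms-lag history gains
(aligned to the same absolute 2 ms bins the GLM uses) × zero inside OFF
periods; spike times get sub-bin jitter so ISI distributions are
continuous. EEG/EMG carry wake/NREM/REM structure: state-dependent
60–200 Hz EMG amplitude and NREM delta vs wake/REM theta in the EEG.

Not emulated: biophysical thalamocortical dynamics, traveling-wave
structure, electrode drift and unit instability, real artifact morphology,
EMG crosstalk, and video beyond moving-blob frame stacks. Passing the
recovery tests therefore shows the *analyses* are correct and calibrated
under their stated assumptions — not that real recordings satisfy those
assumptions.

## Problem sizes and reproducibility

Desk-scale defaults keep every check fast: recovery tests use ~15–40
trial sessions (900–3400 s at 1 kHz), null calibrations use 30–200
Monte-Carlo repetitions, and renewal nulls 300–1000 simulations; these
sizes are the package's own trade-off between statistical resolution and
turnaround. One global seed lives in the config; each pipeline stage
derives its own seed by hashing the stage name (SHA-256, reduced below
2³¹), so stages are individually reproducible and independent. All
stochastic results are bit-reproducible given the seed; the full pipeline
writes byte-identical statistics JSON on repeated runs.

## Known limitations

- The signed-rank CI uses a normal approximation above n = 25; for heavily
  tied or highly discrete data the exact and approximate CIs can differ at
  the last Walsh average.
- The gamma-renewal null conditions on spike count, not duration; for very
  sparse trains the simulated record can end before `t1`, inflating null
  OFF fractions slightly (the self-consistency test bounds this).
- MI estimates carry the usual positive small-sample bias ((n_bins−1)/
  (2 ln 2 · n) to first order); paired pre/ON differences cancel most of
  it, pooled MIs do not.
- The CI-non-overlap rule for GLM condition changes is conservative
  relative to a Wald test on the coefficient difference; a Wald variant is
  available in the code but non-default.
- Horn–Schunck flow is computed at full frame resolution with fixed
  regularization; very large inter-frame displacements (> a few pixels)
  underestimate motion, as expected for the method.
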