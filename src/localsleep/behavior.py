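"""Arousal-state analyses: EMG power, sleep scoring, motion, couplings.

Sleep is scored semi-automatically: wake = runs of at least 5 s of
supra-threshold 60-200 Hz EMG amplitude (Gaussian-smoothed, 50 ms SD); the
remaining time is split into NREM vs REM by a threshold on the smoothed
ratio of sub-4 Hz to 4-16 Hz EEG power.  Motion is scored from grayscale
frame stacks by Horn-Schunck optical flow.  Laser-locked EMG and state
effects use the shared signed-rank machinery; couplings are tested against
shuffled controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve, gaussian_filter1d, uniform_filter1d
from scipy.signal import hilbert, periodogram

from .slowwaves import bandpass_fir
from .stats import PairedEffect, signed_rank_effect

STATES = ("wake", "nrem", "rem")


# ---------------------------------------------------------------- EMG power

def emg_band_power(emg, fs: float, band=(10.0, 200.0), win_s: float = 1.0):
    """Summed band power in non-overlapping windows (default 1 s).

    Returns (window start times s, power per window in uV^2).
    """
    if fs <= 2 * band[1]:
        raise ValueError("sampling rate too low for the band")
    emg = np.asarray(emg, dtype=float)
    nper = int(round(win_s * fs))
    n_win = emg.size // nper
    power = np.empty(n_win)
    for w in range(n_win):
        freqs, psd = periodogram(emg[w * nper:(w + 1) * nper], fs)
        sel = (freqs >= band[0]) & (freqs <= band[1])
        power[w] = np.sum(psd[sel]) * (freqs[1] - freqs[0])
    return np.arange(n_win) * win_s, power


def emg_power_change(
    emg, fs: float, onsets, duration_s: float = 30.0, band=(10.0, 200.0)
) -> PairedEffect:
    """Median dB change in EMG band power, stimulation vs pre, across trials."""
    t, p = emg_band_power(emg, fs, band)
    diffs = []
    for onset in np.asarray(onsets, dtype=float):
        on = (t >= onset) & (t < onset + duration_s)
        pre = (t >= onset - duration_s) & (t < onset)
        diffs.append(10 * np.log10(p[on].sum() / p[pre].sum()))
    return signed_rank_effect(np.array(diffs))


def emg_first_second_change(emg, fs: float, onsets, band=(10.0, 200.0)) -> PairedEffect:
    """dB change between the second before and the second after laser onset."""
    t, p = emg_band_power(emg, fs, band, win_s=1.0)
    diffs = []
    for onset in np.asarray(onsets, dtype=float):
        i = int(np.floor(onset))
        diffs.append(10 * np.log10(p[i] / p[i - 1]))
    return signed_rank_effect(np.array(diffs))


# -------------------------------------------------------------- sleep scoring

@dataclass
class SleepLabels:
    states: np.ndarray  # per-second labels from STATES
    emg_threshold: float
    ratio_threshold: float
    quality_ok: bool = True
    note: str = ""

    def occupancy(self, sel=None) -> dict:
        s = self.states if sel is None else self.states[sel]
        return {st: float(np.mean(s == st) * 100.0) for st in STATES}


def _bimodal_threshold(values):
    """Otsu-style two-class split with a bimodality check.

    Returns (threshold, strong) where ``strong`` is False when the two
    classes are not separated relative to their spreads (unimodal data),
    in which case the threshold is unusable and a caller-side fallback
    should decide which single class the data belong to.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    hist, edges = np.histogram(v, bins=128)
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(hist)
    w1 = hist.sum() - w0
    m0 = np.cumsum(hist * centers)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (m0[-1] - m0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    i = int(np.nanargmax(between))
    thresh = float(centers[i])
    lo, hi = v[v <= thresh], v[v > thresh]
    if lo.size < 2 or hi.size < 2:
        return thresh, False
    spread = np.std(lo) + np.std(hi)
    d = (hi.mean() - lo.mean()) / spread if spread > 0 else 0.0
    return thresh, bool(d >= 2.0)


def emg_amplitude(emg, fs: float, band=(60.0, 200.0), smooth_ms: float = 50.0):
    """Instantaneous 60-200 Hz EMG amplitude, Gaussian-smoothed (50 ms SD)."""
    env = np.abs(hilbert(bandpass_fir(np.asarray(emg, float), fs, band)))
    return gaussian_filter1d(env, smooth_ms / 1000.0 * fs)


def eeg_state_ratio(eeg, fs: float, smooth_sd_s: float = 1.0):
    """Per-second ratio of <4 Hz to 4-16 Hz EEG power, Gaussian-smoothed."""
    eeg = np.asarray(eeg, dtype=float)
    lo = bandpass_fir(eeg, fs, (0.5, 4.0))
    hi = bandpass_fir(eeg, fs, (4.0, 16.0))
    n_sec = int(eeg.size // fs)
    nper = int(fs)
    ratio = np.empty(n_sec)
    for s in range(n_sec):
        seg = slice(s * nper, (s + 1) * nper)
        ratio[s] = np.mean(lo[seg] ** 2) / np.mean(hi[seg] ** 2)
    return gaussian_filter1d(ratio, smooth_sd_s)


def score_sleep(
    eeg,
    emg,
    fs: float,
    emg_thresh: float = None,
    ratio_thresh: float = None,
    min_wake_s: float = 5.0,
    min_nrem_before_rem_s: float = 10.0,
) -> SleepLabels:
    """Per-second wake/NREM/REM labels from EEG and EMG.

    Thresholds may be supplied (the semi-automated, manually-entered mode)
    or suggested automatically by a two-class variance split of the log EMG
    amplitude and log EEG ratio.  Wake requires at least ``min_wake_s``
    contiguous seconds of supra-threshold EMG; REM requires at least 10 s of
    immediately preceding sleep (otherwise the second is labelled NREM).
    """
    amp = emg_amplitude(emg, fs)
    n_sec = int(min(len(emg), len(eeg)) // fs)
    amp_sec = amp[: n_sec * int(fs)].reshape(n_sec, int(fs)).mean(axis=1)
    ratio = eeg_state_ratio(eeg, fs)[:n_sec]
    note = ""
    quality = True
    # ratio > 1 means sub-4 Hz power dominates 4-16 Hz: the absolute anchor
    # used when a session is single-state and the auto split is degenerate
    sleepy = float(np.median(ratio)) >= 1.0
    if emg_thresh is None:
        t, strong = _bimodal_threshold(np.log(amp_sec + 1e-12))
        if strong:
            emg_thresh = float(np.exp(t))
        else:
            note += "unimodal EMG; "
            emg_thresh = (float(amp_sec.max()) * 2.0 if sleepy
                          else float(amp_sec.min()) * 0.5)
    if ratio_thresh is None:
        t, strong = _bimodal_threshold(np.log(ratio + 1e-12))
        if strong:
            ratio_thresh = float(np.exp(t))
        else:
            note += "unimodal EEG ratio; "
            ratio_thresh = (float(ratio.min()) * 0.5 if sleepy
                            else float(ratio.max()) * 2.0)
    above = amp_sec > emg_thresh
    states = np.array(["nrem"] * n_sec, dtype=object)
    # wake: runs of >= min_wake_s supra-threshold seconds
    i = 0
    while i < n_sec:
        if above[i]:
            j = i
            while j < n_sec and above[j]:
                j += 1
            if j - i >= min_wake_s:
                states[i:j] = "wake"
            i = j
        else:
            i += 1
    sleep = states != "wake"
    states[sleep & (ratio < ratio_thresh)] = "rem"
    # REM needs a preceding sleep bout
    run = 0
    for i in range(n_sec):
        if states[i] == "wake":
            run = 0
        elif states[i] == "nrem":
            run += 1
        else:  # rem candidate
            if run < min_nrem_before_rem_s:
                states[i] = "nrem"
            run += 1
    if ("unimodal" not in note and len(set(states.tolist())) == 1
            and n_sec > 60):
        # explicit or bimodal thresholds that still collapse to one state
        # indicate no usable sleep/wake separation
        quality = False
        note += "no state separation at these thresholds; "
    labels = SleepLabels(states.astype(str), float(emg_thresh),
                         float(ratio_thresh), quality, note)
    if not quality:
        warnings.warn("sleep scoring quality flag raised: " + note)
    return labels


def state_occupancy_change(
    labels: SleepLabels, onsets, duration_s: float = 30.0
) -> dict:
    """Per-state occupancy change (percentage points), stim vs pre windows."""
    sec = np.arange(labels.states.size)
    out = {}
    diffs = {st: [] for st in STATES}
    for onset in np.asarray(onsets, dtype=float):
        on = (sec >= onset) & (sec < onset + duration_s)
        pre = (sec >= onset - duration_s) & (sec < onset)
        for st in STATES:
            occ_on = 100.0 * np.mean(labels.states[on] == st)
            occ_pre = 100.0 * np.mean(labels.states[pre] == st)
            diffs[st].append(occ_on - occ_pre)
    for st in STATES:
        out[st] = signed_rank_effect(np.array(diffs[st]))
    return out


# -------------------------------------------------------------- optical flow

@dataclass
class MotionTrace:
    magnitude: np.ndarray  # per frame pair, mean-normalized
    smooth_frames: int
    raw_magnitude: np.ndarray = field(repr=False, default=None)


def _horn_schunck(a, b, alpha2: float = 1.0, n_iter: int = 100):
    """Horn-Schunck optical flow between two frames (intensities in [0,1])."""
    kx = np.array([[-0.25, 0.25], [-0.25, 0.25]])
    ky = np.array([[-0.25, -0.25], [0.25, 0.25]])
    kt = np.full((2, 2), 0.25)
    ix = convolve(a, kx) + convolve(b, kx)
    iy = convolve(a, ky) + convolve(b, ky)
    it = convolve(b, kt) - convolve(a, kt)
    avg = np.array(
        [[1 / 12, 1 / 6, 1 / 12], [1 / 6, 0, 1 / 6], [1 / 12, 1 / 6, 1 / 12]]
    )
    u = np.zeros_like(a)
    v = np.zeros_like(a)
    denom = alpha2 + ix**2 + iy**2
    for _ in range(n_iter):
        ubar = convolve(u, avg)
        vbar = convolve(v, avg)
        t = (ix * ubar + iy * vbar + it) / denom
        u = ubar - ix * t
        v = vbar - iy * t
    return u, v


def motion_from_frames(
    frames, smooth_frames: int = 200, alpha2: float = 1.0, n_iter: int = 100
) -> MotionTrace:
    """Per-frame motion magnitude from Horn-Schunck optical flow.

    Each frame pair's flow field is summarized by the magnitude at the point
    of maximal motion; the trace is normalized by its mean (robust to
    lighting and camera-placement differences) and smoothed with a moving
    average of ``smooth_frames`` frames.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (n_frames, h, w) stack with at least 2 frames")
    peak = stack.max()
    if peak > 0:
        stack = stack / peak
    mags = np.empty(stack.shape[0] - 1)
    for i in range(stack.shape[0] - 1):
        u, v = _horn_schunck(stack[i], stack[i + 1], alpha2, n_iter)
        mags[i] = np.sqrt(u**2 + v**2).max()
    raw = mags.copy()
    m = mags.mean()
    if m > 0:
        mags = mags / m
    smoothed = uniform_filter1d(mags, size=min(smooth_frames, mags.size))
    return MotionTrace(smoothed, smooth_frames, raw)


# ------------------------------------------------------------- couplings

@dataclass
class CorrelationResult:
    r: float
    boot_ci: tuple
    null_abs_975: float
    n_boot: int

    @property
    def significant(self) -> bool:
        return abs(self.r) > self.null_abs_975


def eeg_emg_correlation(
    delta_changes, emg_changes, n_boot: int = 1000, seed=None
) -> CorrelationResult:
    """Pearson correlation of per-trial EEG delta vs EMG power changes.

    A pair-resampling bootstrap gives the CI of r; significance compares
    |r| to the 97.5th percentile of |r| under random re-pairing of trials.
    """
    x = np.asarray(delta_changes, dtype=float)
    y = np.asarray(emg_changes, dtype=float)
    if x.size != y.size or x.size < 10:
        raise ValueError("need at least 10 paired trials")
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    null = np.empty(n_boot)
    n = x.size
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        boot[i] = np.corrcoef(x[idx], y[idx])[0, 1]
        null[i] = np.corrcoef(x, y[rng.permutation(n)])[0, 1]
    return CorrelationResult(
        r,
        tuple(np.percentile(boot, [2.5, 97.5])),
        float(np.percentile(np.abs(null), 97.5)),
        n_boot,
    )


@dataclass
class ShuffledOnsetResult:
    true_value: float
    null_values: np.ndarray
    null_ci: tuple

    @property
    def outside_null(self) -> bool:
        return not (self.null_ci[0] <= self.true_value <= self.null_ci[1])


def shuffled_onset_control(
    stat_fn,
    true_onsets,
    labels: SleepLabels,
    n_shuffles: int = 400,
    duration_s: float = 30.0,
    seed=None,
    state: str = "nrem",
) -> ShuffledOnsetResult:
    """Null distribution of a laser-locked statistic at shuffled onsets.

    ``stat_fn(onsets) -> float`` recomputes the statistic; shuffled onsets
    are drawn uniformly from seconds labelled ``state`` whose full
    [-duration, +duration] window both fits the record and (for the onset
    second) lies in that state.
    """
    n_onsets = len(np.asarray(true_onsets))
    sec = np.arange(labels.states.size)
    ok = (labels.states == state) & (sec >= duration_s) & (
        sec < labels.states.size - duration_s
    )
    candidates = sec[ok].astype(float)
    if candidates.size < n_onsets:
        raise ValueError(f"not enough {state} time to place shuffled onsets")
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        onsets = np.sort(rng.choice(candidates, size=n_onsets, replace=False))
        null[i] = stat_fn(onsets)
    true_value = float(stat_fn(np.asarray(true_onsets, dtype=float)))
    return ShuffledOnsetResult(
        true_value, null, tuple(np.percentile(null, [2.5, 97.5]))
    )
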