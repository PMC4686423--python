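"""Detection of individual slow-wave events in the LFP.

The LFP is zero-phase bandpassed 0.1-5 Hz with a windowed-sinc FIR filter,
local minima deeper than -100 uV are taken as candidate troughs, each
trough's peak-to-peak amplitude is measured to the first subsequent local
maximum, candidates inside high-variance artifact windows are discarded,
and the top 3% of peak-to-peak amplitudes within the session are kept as
slow-wave events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, find_peaks, firwin

from .stats import PairedEffect, signed_rank_effect


@dataclass
class SlowWaveEvent:
    trough_time: float  # s
    trough_amp: float  # uV, negative
    next_peak_time: float  # s
    peak_amp: float  # uV
    session_percentile: float

    @property
    def peak_to_peak(self) -> float:
        return self.peak_amp - self.trough_amp


def bandpass_fir(x, fs: float, band=(0.1, 5.0)):
    """Zero-phase FIR bandpass via a symmetric windowed-sinc kernel.

    Kernel length 3*fs/f_lo (rounded up to odd); the symmetric kernel is
    applied once by FFT convolution, which is exactly zero-phase.
    """
    lo, hi = band
    if fs < 2 * hi:
        raise ValueError("sampling rate below Nyquist for the band")
    numtaps = int(round(3 * fs / lo))
    numtaps += 1 - numtaps % 2  # odd
    h = firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    x = np.asarray(x, dtype=float)
    # reflect-pad so record edges see a continuous signal instead of a step
    pad = min(numtaps, x.size - 1)
    xp = np.pad(x, pad, mode="reflect")
    return fftconvolve(xp, h, mode="same")[pad:pad + x.size]


def detect_slow_waves(
    lfp,
    fs: float,
    band=(0.1, 5.0),
    min_trough_uv: float = 100.0,
    top_pct: float = 3.0,
    artifact_sd_uv: float = 2000.0,
    artifact_win_s: float = 0.4,
) -> list:
    """Detect slow-wave events in a single-channel LFP (uV).

    Candidates whose surrounding raw-LFP window (default 400 ms) has a
    standard deviation above ``artifact_sd_uv`` are rejected before the
    session-level percentile ranking.  The top ``top_pct`` percent of
    peak-to-peak amplitudes are returned (k = ceil(pct/100 * n_candidates)
    events; boundary ties broken by earlier trough time).
    """
    lfp = np.asarray(lfp, dtype=float)
    if lfp.size < 10 * fs:
        raise ValueError("need at least 10 s of LFP")
    xf = bandpass_fir(lfp, fs, band)
    troughs, _ = find_peaks(-xf, height=min_trough_uv)
    peaks, _ = find_peaks(xf)
    if troughs.size == 0 or peaks.size == 0:
        return []
    half = int(round(artifact_win_s * fs / 2))
    cands = []
    for tr in troughs:
        j = np.searchsorted(peaks, tr, side="right")
        if j >= peaks.size:
            continue
        pk = peaks[j]
        a, b = max(0, tr - half), min(lfp.size, tr + half)
        if np.std(lfp[a:b]) > artifact_sd_uv:
            continue
        cands.append((tr, pk, xf[pk] - xf[tr]))
    if not cands:
        return []
    p2p = np.array([c[2] for c in cands])
    n_keep = math.ceil(top_pct / 100.0 * len(cands))
    # largest first; ties at the boundary broken by earlier time
    order = np.lexsort((np.array([c[0] for c in cands]), -p2p))
    keep = sorted(order[:n_keep], key=lambda i: cands[i][0])
    ranks = p2p.argsort().argsort()  # ascending rank
    events = []
    for i in keep:
        tr, pk, _ = cands[i]
        events.append(
            SlowWaveEvent(
                trough_time=tr / fs,
                trough_amp=float(xf[tr]),
                next_peak_time=pk / fs,
                peak_amp=float(xf[pk]),
                session_percentile=float(100.0 * (ranks[i] + 1) / len(cands)),
            )
        )
    return events


def _per_trial_rates(times, onsets, duration_s):
    times = np.asarray(times, dtype=float)
    on_rates, pre_rates = [], []
    for onset in np.asarray(onsets, dtype=float):
        n_on = np.sum((times >= onset) & (times < onset + duration_s))
        n_pre = np.sum((times >= onset - duration_s) & (times < onset))
        on_rates.append(n_on / duration_s)
        pre_rates.append(n_pre / duration_s)
    return np.array(on_rates), np.array(pre_rates)


def event_rate_change(events, onsets, duration_s: float = 30.0) -> PairedEffect:
    """Median change in events/s, stimulation vs pre window, across trials."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 6:
        raise ValueError("need at least 6 trials")
    times = [e.trough_time for e in events]
    on_r, pre_r = _per_trial_rates(times, onsets, duration_s)
    return signed_rank_effect(on_r - pre_r)


def event_amplitude_stats(events, onsets, duration_s: float = 30.0):
    """Paired-by-trial changes in trough and peak amplitudes (uV).

    For each trial with at least one event in both the pre and stimulation
    windows, the median trough and peak amplitudes are compared; returns
    dict with 'trough' and 'peak' PairedEffect entries.
    """
    if not events:
        raise ValueError("no events supplied")
    t = np.array([e.trough_time for e in events])
    tr_amp = np.array([e.trough_amp for e in events])
    pk_amp = np.array([e.peak_amp for e in events])
    d_tr, d_pk = [], []
    for onset in np.asarray(onsets, dtype=float):
        on = (t >= onset) & (t < onset + duration_s)
        pre = (t >= onset - duration_s) & (t < onset)
        if on.any() and pre.any():
            d_tr.append(np.median(tr_amp[on]) - np.median(tr_amp[pre]))
            d_pk.append(np.median(pk_amp[on]) - np.median(pk_amp[pre]))
    if len(d_tr) < 2:
        raise ValueError("too few trials with events in both windows")
    return {
        "trough": signed_rank_effect(np.array(d_tr)),
        "peak": signed_rank_effect(np.array(d_pk)),
    }
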