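"""Multitaper spectral estimation and laser-locked band-power statistics.

Spectra use DPSS (Slepian) tapers with the K = 2*NW - 1 convention, i.e.
NW = (K+1)/2: full-trial spectra with 19 tapers over 30 s windows and
spectrograms with 5 tapers in 5 s windows sliding every 1 s.  Band-power
effects are paired pre-stimulus ([-30, 0) s) versus stimulation ([0, 30) s)
dB differences summarized by Hodges-Lehmann medians with signed-rank CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

from .stats import PairedEffect, signed_rank_effect


@dataclass
class Spectrum:
    freqs: np.ndarray
    power: np.ndarray  # uV^2/Hz, one-sided
    window_s: float
    n_tapers: int
    nw: float

    def band_power(self, band) -> float:
        """Total power (uV^2) in [lo, hi], edges inclusive on the grid."""
        lo, hi = band
        df = self.freqs[1] - self.freqs[0]
        sel = (self.freqs >= lo) & (self.freqs <= hi)
        return float(np.sum(self.power[sel]) * df)


@dataclass
class BandPowerEffect:
    band: tuple
    pre_db: np.ndarray
    stim_db: np.ndarray
    effect: PairedEffect = field(default=None)

    @property
    def median_change_db(self) -> float:
        return self.effect.median

    @property
    def ci_db(self) -> tuple:
        return self.effect.ci


def multitaper_spectrum(x, fs: float, window_s: float = 30.0, k: int = 19) -> Spectrum:
    """Multitaper PSD averaged over K DPSS tapers and non-overlapping windows.

    NW is taken as (K+1)/2.  Power is one-sided density in input-units^2/Hz;
    integrating over frequency recovers the signal variance (Parseval).
    """
    x = np.asarray(x, dtype=float)
    if k < 1:
        raise ValueError("need at least one taper")
    nper = int(round(window_s * fs))
    if x.size < nper:
        raise ValueError("trace shorter than one window")
    nw = (k + 1) / 2.0
    tapers = dpss(nper, nw, Kmax=k)  # unit-energy rows
    n_win = x.size // nper
    freqs = rfftfreq(nper, d=1.0 / fs)
    psd = np.zeros(freqs.size)
    for w in range(n_win):
        seg = x[w * nper:(w + 1) * nper]
        spec = np.abs(rfft(seg[None, :] * tapers, axis=1)) ** 2
        psd += spec.mean(axis=0)
    psd /= n_win * fs
    # one-sided scaling: double everything except DC (and Nyquist if present)
    psd[1:] *= 2.0
    if nper % 2 == 0:
        psd[-1] /= 2.0
    return Spectrum(freqs, psd, window_s, k, nw)


def normalized_spectrogram(
    x,
    fs: float,
    onsets,
    window_s: float = 5.0,
    k: int = 5,
    step_s: float = 1.0,
    pre_s: float = 30.0,
    post_s: float = 30.0,
):
    """Trial-locked multitaper spectrogram in dB relative to the pre window.

    The median power across trials is taken first, then each frequency row is
    divided by its mean over the pre-stimulus window, and the ratio is
    expressed in dB.  Trials whose pre window would start before the record
    are dropped with a warning.

    Returns (times_s relative to onset, freqs, matrix dB [freq x time]).
    """
    x = np.asarray(x, dtype=float)
    nper = int(round(window_s * fs))
    nw = (k + 1) / 2.0
    tapers = dpss(nper, nw, Kmax=k)
    freqs = rfftfreq(nper, d=1.0 / fs)
    starts = np.arange(-pre_s, post_s - window_s + step_s / 2, step_s)
    times = starts + window_s / 2.0
    per_trial = []
    for onset in np.asarray(onsets, dtype=float):
        i0 = int(round((onset - pre_s) * fs))
        i1 = int(round((onset + post_s) * fs))
        if i0 < 0 or i1 > x.size:
            warnings.warn(f"trial at {onset:.1f}s lacks a full window; dropped")
            continue
        mat = np.empty((freqs.size, starts.size))
        for j, s in enumerate(starts):
            a = int(round((onset + s) * fs))
            seg = x[a:a + nper]
            spec = np.abs(rfft(seg[None, :] * tapers, axis=1)) ** 2
            mat[:, j] = spec.mean(axis=0) / fs
        per_trial.append(mat)
    if not per_trial:
        raise ValueError("no trial has a full pre-stimulus window")
    med = np.median(np.stack(per_trial), axis=0)
    pre_cols = times < 0
    baseline = med[:, pre_cols].mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out_db = 10.0 * np.log10(med / baseline)
    return times, freqs, out_db


def _paired_band_powers_db(x, fs, onsets, band, window_s=30.0, k=19):
    pre_db, stim_db = [], []
    nper = int(round(window_s * fs))
    for onset in np.asarray(onsets, dtype=float):
        i_on = int(round(onset * fs))
        if i_on - nper < 0 or i_on + nper > x.size:
            raise ValueError(f"trial at {onset:.1f}s lacks a full pre/stim window")
        pre = multitaper_spectrum(x[i_on - nper:i_on], fs, window_s, k)
        stim = multitaper_spectrum(x[i_on:i_on + nper], fs, window_s, k)
        pre_db.append(10 * np.log10(pre.band_power(band)))
        stim_db.append(10 * np.log10(stim.band_power(band)))
    return np.array(pre_db), np.array(stim_db)


def band_power_change(
    x, fs: float, onsets, band, window_s: float = 30.0, k: int = 19
) -> BandPowerEffect:
    """Paired pre-vs-stimulation band-power change in dB across trials."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 6:
        raise ValueError("need at least 6 trials for signed-rank CI inversion")
    pre_db, stim_db = _paired_band_powers_db(x, fs, onsets, band, window_s, k)
    eff = signed_rank_effect(stim_db - pre_db)
    return BandPowerEffect(tuple(band), pre_db, stim_db, eff)


@dataclass
class ChannelEffect:
    channel: int
    change_db: float
    p: float
    significant_bonferroni: bool
    normalized_delta_change: float
    delta_effect_flag: bool


def delta_effect_map(
    lfp,
    fs: float,
    onsets,
    delta_band=(1.0, 4.0),
    broad_band=(0.0, 50.0),
    alpha: float = 0.05,
    norm_delta_thresh: float = 0.02,
    window_s: float = 30.0,
    k: int = 19,
) -> list:
    """Per-channel delta-effect labels under two published rules.

    (a) signed-rank significance of the delta dB change, Bonferroni-corrected
    across channels; (b) a >= 2% increase in normalized delta power
    (delta / 0-50 Hz power) between the pre and stimulation windows.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    n_ch = lfp.shape[0]
    out = []
    nper = int(round(window_s * fs))
    for ch in range(n_ch):
        eff = band_power_change(lfp[ch], fs, onsets, delta_band, window_s, k)
        # normalized delta per trial, pre and stim
        nd_pre, nd_stim = [], []
        for onset in np.asarray(onsets, dtype=float):
            i_on = int(round(onset * fs))
            sp_pre = multitaper_spectrum(lfp[ch][i_on - nper:i_on], fs, window_s, k)
            sp_stim = multitaper_spectrum(lfp[ch][i_on:i_on + nper], fs, window_s, k)
            nd_pre.append(sp_pre.band_power(delta_band) / sp_pre.band_power(broad_band))
            nd_stim.append(
                sp_stim.band_power(delta_band) / sp_stim.band_power(broad_band)
            )
        nd_change = float(np.median(np.array(nd_stim) - np.array(nd_pre)))
        out.append(
            ChannelEffect(
                channel=ch,
                change_db=eff.effect.median,
                p=eff.effect.p,
                significant_bonferroni=eff.effect.p < alpha / n_ch,
                normalized_delta_change=nd_change,
                delta_effect_flag=nd_change >= norm_delta_thresh,
            )
        )
    return out
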