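"""Single-unit statistics: waveform classification, rate effects, onset
latency, and spike-history GLMs.

Units are split by waveform peak-to-trough time at 200 us (Narrow = putative
reticular, Wide = putative thalamocortical/cortical).  Firing-rate and
phase-locking effects use the shared signed-rank machinery.  Temporal
firing patterns are modelled as a discrete-time point process: a Poisson
GLM with log link at 2 ms resolution whose covariates are binary spike
indicators at lags 1..50 bins (2..100 ms); bursting shows up as a positive
coefficient at the 2-4 ms lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .stats import PairedEffect, signed_rank_effect

N_LAGS = 50
BIN_MS = 2.0


def classify_unit(peak_to_trough_us: float) -> str:
    """'Narrow' for peak-to-trough under 200 us, else 'Wide'."""
    if peak_to_trough_us <= 0:
        raise ValueError("peak-to-trough time must be positive")
    return "Narrow" if peak_to_trough_us < 200.0 else "Wide"


def peak_to_trough_us(waveform, fs: float, upsample: int = 10) -> float:
    """Peak-to-trough time of a mean waveform, on a sinc-interpolated grid."""
    w = np.asarray(waveform, dtype=float)
    n = w.size
    from scipy.signal import resample

    wu = resample(w, n * upsample)
    fsu = fs * upsample
    i_tr = int(np.argmin(wu))
    i_pk = i_tr + int(np.argmax(wu[i_tr:]))
    return (i_pk - i_tr) / fsu * 1e6


def rate_change(
    spike_times, onsets, duration_s: float = 30.0
) -> PairedEffect:
    """Median change in firing rate (Hz), stimulation vs pre, across trials."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 6:
        raise ValueError("need at least 6 trials")
    spikes = np.asarray(spike_times, dtype=float)
    diffs = []
    for onset in onsets:
        n_on = np.sum((spikes >= onset) & (spikes < onset + duration_s))
        n_pre = np.sum((spikes >= onset - duration_s) & (spikes < onset))
        diffs.append((n_on - n_pre) / duration_s)
    return signed_rank_effect(np.array(diffs))


@dataclass
class OnsetResponse:
    bin_means: np.ndarray  # post-onset per-10 ms-bin trial-mean values
    threshold_lo: float
    threshold_hi: float
    first_significant_ms: float  # nan if none
    direction: int  # -1 drop, +1 rise, 0 none
    alpha: float


def onset_latency(
    values_per_trial,
    fs_bins_per_s: float = 100.0,
    pre_s: float = 2.0,
    post_s: float = 0.1,
    n_boot: int = 1000,
    alpha: float = 0.005,
    seed=None,
) -> OnsetResponse:
    """Latency of a significant post-onset change in 10 ms bins.

    ``values_per_trial`` is an (n_trials, n_bins) array of per-10 ms-bin
    values (spike counts/rates or mean LFP) covering [-pre_s, post_s) around
    onset.  The 2 s pre-stimulus bins are bootstrapped ``n_boot`` times to
    set thresholds at the alpha/2 and 1-alpha/2 quantiles of the trial-mean
    bin value (alpha = 0.005 corrects for the 10 post-onset comparisons);
    the first post-onset bin outside them is reported.
    """
    vals = np.asarray(values_per_trial, dtype=float)
    n_pre = int(round(pre_s * fs_bins_per_s))
    n_post = int(round(post_s * fs_bins_per_s))
    if vals.shape[1] != n_pre + n_post:
        raise ValueError("values do not cover [-pre, post) at 10 ms resolution")
    pre = vals[:, :n_pre]
    post_means = vals[:, n_pre:].mean(axis=0)
    rng = np.random.default_rng(seed)
    flat = pre.ravel()
    n_trials = vals.shape[0]
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = rng.choice(flat, size=n_trials, replace=True).mean()
    lo = float(np.quantile(boot, alpha / 2))
    hi = float(np.quantile(boot, 1 - alpha / 2))
    first_ms, direction = float("nan"), 0
    for j, m in enumerate(post_means):
        if m < lo or m > hi:
            first_ms = j * 1000.0 / fs_bins_per_s
            direction = -1 if m < lo else 1
            break
    return OnsetResponse(post_means, lo, hi, first_ms, direction, alpha)


@dataclass
class GLMHistoryFit:
    coef: np.ndarray  # (N_LAGS,) log-rate gains per lag
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    intercept: float
    converged: bool
    condition: str = ""
    unit_id: str = ""

    def lag_index_for_ms(self, lo_ms: float) -> int:
        """Array index of the lag bin covering (lo_ms, lo_ms + 2] ms.

        Lag k (array index k-1) covers (2(k-1), 2k] ms, so lo_ms = 2.0 maps
        to index 1 (the second bin).
        """
        return int(round(lo_ms / BIN_MS))


def _binned_train(spike_times, windows, bin_s):
    segs = []
    for t0, t1 in windows:
        n = int(round((t1 - t0) / bin_s))
        edges = t0 + np.arange(n + 1) * bin_s
        counts, _ = np.histogram(spike_times, bins=edges)
        segs.append((counts > 0).astype(float))
    return segs


def fit_history_glm(
    spike_times,
    windows,
    condition: str = "",
    unit_id: str = "",
    min_spikes: int = 500,
    alpha: float = 0.05,
) -> GLMHistoryFit:
    """Poisson GLM of a binned spike train on its own 50x2 ms history.

    ``windows`` is a list of (t0, t1) intervals (e.g. all stimulation
    periods); each is binned at 2 ms and lagged binary spike indicators are
    built within windows only, so history never crosses a window boundary.
    Returns per-lag coefficients with Wald 95% CIs; non-convergent or
    unstable fits are flagged and should be excluded downstream.
    """
    spikes = np.asarray(spike_times, dtype=float)
    bin_s = BIN_MS / 1000.0
    segs = _binned_train(spikes, windows, bin_s)
    total_spikes = int(sum(s.sum() for s in segs))
    if total_spikes < min_spikes:
        raise ValueError(
            f"need at least {min_spikes} spikes in the windows (got {total_spikes})"
        )
    ys, xs = [], []
    for seg in segs:
        if seg.size <= N_LAGS:
            continue
        y = seg[N_LAGS:]
        x = np.empty((y.size, N_LAGS))
        for lag in range(1, N_LAGS + 1):
            x[:, lag - 1] = seg[N_LAGS - lag:-lag]
        ys.append(y)
        xs.append(x)
    y = np.concatenate(ys)
    x = sm.add_constant(np.vstack(xs), has_constant="add")
    try:
        res = sm.GLM(y, x, family=sm.families.Poisson()).fit(maxiter=100)
        converged = bool(res.converged) and np.all(np.isfinite(res.bse))
        ci = res.conf_int(alpha)
        fit = GLMHistoryFit(
            coef=res.params[1:].copy(),
            ci_lo=ci[1:, 0].copy(),
            ci_hi=ci[1:, 1].copy(),
            intercept=float(res.params[0]),
            converged=converged,
            condition=condition,
            unit_id=unit_id,
        )
    except Exception:
        nanv = np.full(N_LAGS, np.nan)
        fit = GLMHistoryFit(nanv, nanv, nanv, np.nan, False, condition, unit_id)
    return fit


def compare_history_2_4ms(fit_base: GLMHistoryFit, fit_stim: GLMHistoryFit) -> dict:
    """Did the (2, 4] ms history coefficient change between conditions?

    Significance = non-overlap of the two 95% CIs for that lag; direction is
    the sign of (stim - baseline).
    """
    if not (fit_base.converged and fit_stim.converged):
        raise ValueError("both fits must have converged")
    i = fit_base.lag_index_for_ms(2.0)  # lag bin (2,4] ms = second bin
    lo_b, hi_b = fit_base.ci_lo[i], fit_base.ci_hi[i]
    lo_s, hi_s = fit_stim.ci_lo[i], fit_stim.ci_hi[i]
    changed = bool(hi_b < lo_s or hi_s < lo_b)
    direction = int(np.sign(fit_stim.coef[i] - fit_base.coef[i])) if changed else 0
    return {
        "changed": changed,
        "direction": direction,
        "coef_base": float(fit_base.coef[i]),
        "coef_stim": float(fit_stim.coef[i]),
    }
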