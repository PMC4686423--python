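"""Delta-phase extraction and phase-locking statistics.

Instantaneous 1-4 Hz phase comes from a zero-phase FIR bandpass followed by
the Hilbert transform.  Phase locking between channels is the phase-locking
value (PLV, magnitude of the circular mean of the phase difference) with a
trial-shuffle permutation test; phase locking of spikes and of gamma
amplitude is the modulation index (MI), the Kullback-Leibler distance of the
phase-binned distribution from uniform, in bits:

    MI = sum_i p_i log2 p_i + log2 n_bins

so MI = 0 for a uniform distribution and log2(n_bins) when a single bin
holds everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .slowwaves import bandpass_fir
from .stats import PairedEffect, signed_rank_effect


@dataclass
class MIResult:
    mi_bits: float
    n_bins: int
    p: np.ndarray = field(repr=False)
    preferred_phase: float  # rad
    n_obs: int

    def __post_init__(self):
        assert -1e-9 <= self.mi_bits <= np.log2(self.n_bins) + 1e-9


@dataclass
class PLVResult:
    plv: float
    offset: float  # rad, circular mean phase difference
    p: float
    n_perms: int
    offset_ci: tuple = None


def delta_phase(lfp, fs: float, band=(1.0, 4.0)):
    """Instantaneous phase (rad, [-pi, pi)) of the bandpassed LFP.

    Returns (phase, valid) where ``valid`` masks out one filter length at
    each edge, where the FIR output is contaminated by the boundary.
    """
    lfp = np.asarray(lfp, dtype=float)
    if lfp.size < 10 * fs / band[0]:
        raise ValueError("record too short for reliable phase estimation")
    xf = bandpass_fir(lfp, fs, band)
    phase = np.angle(hilbert(xf))
    numtaps = int(round(3 * fs / band[0]))
    valid = np.zeros(lfp.size, dtype=bool)
    valid[numtaps:-numtaps] = True
    return phase, valid


def phases_at(times, fs: float, phase, valid=None, t0: float = 0.0):
    """Sample a phase series at event times (circular linear interpolation)."""
    t_grid = t0 + np.arange(phase.size) / fs
    s = np.interp(times, t_grid, np.sin(phase))
    c = np.interp(times, t_grid, np.cos(phase))
    out = np.arctan2(s, c)
    if valid is not None:
        ok = np.interp(times, t_grid, valid.astype(float)) > 0.5
        return out, ok
    return out


def _circ_mean_vec(angles):
    z = np.mean(np.exp(1j * np.asarray(angles)))
    return np.abs(z), np.angle(z)


def plv(phase_a, phase_b, windows, n_perms: int = 500, n_boot: int = 500,
        seed=None) -> PLVResult:
    """Phase-locking value between two phase series over trial windows.

    ``windows`` is a list of (start, stop) sample index pairs.  The PLV is
    the magnitude of the circular mean of (phase_a - phase_b) pooled over
    in-window samples.  Significance: the trial pairing is shuffled
    ``n_perms`` times (window i of channel a paired with a permuted window
    of channel b, truncated to the common length) and the true PLV compared
    with the permuted values.  The offset angle gets a percentile bootstrap
    CI over trials.
    """
    if len(windows) < 6:
        raise ValueError("need at least 6 trial windows")
    a_segs = [np.asarray(phase_a[w0:w1]) for w0, w1 in windows]
    b_segs = [np.asarray(phase_b[w0:w1]) for w0, w1 in windows]
    # offset convention: phase of b relative to the reference channel a
    diffs = [b - a for a, b in zip(a_segs, b_segs)]
    pooled = np.concatenate(diffs)
    plv_val, offset = _circ_mean_vec(pooled)
    rng = np.random.default_rng(seed)
    n = len(windows)
    perm_vals = np.empty(n_perms)
    for p in range(n_perms):
        perm = rng.permutation(n)
        segs = []
        for i, j in enumerate(perm):
            m = min(a_segs[i].size, b_segs[j].size)
            segs.append(b_segs[j][:m] - a_segs[i][:m])
        perm_vals[p], _ = _circ_mean_vec(np.concatenate(segs))
    pval = (1 + np.sum(perm_vals >= plv_val)) / (n_perms + 1)
    # bootstrap CI of the offset angle, over trials
    boot_angles = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        _, boot_angles[b] = _circ_mean_vec(np.concatenate([diffs[i] for i in idx]))
    rel = np.angle(np.exp(1j * (boot_angles - offset)))
    lo, hi = np.percentile(rel, [2.5, 97.5])
    ci = (float(offset + lo), float(offset + hi))
    return PLVResult(float(plv_val), float(offset), float(pval), n_perms, ci)


def _mi_from_weights(weights, n_bins):
    p = np.asarray(weights, dtype=float)
    p = p / p.sum()
    nz = p[p > 0]
    return float(np.sum(nz * np.log2(nz)) + np.log2(n_bins)), p


def spike_phase_mi(spike_phases, n_bins: int = 10, min_spikes: int = 30) -> MIResult:
    """Modulation index of a spike-phase distribution over 10 phase bins.

    The preferred phase is the center of the bin containing the most spikes.
    """
    phases = np.asarray(spike_phases, dtype=float)
    if phases.size == 0:
        raise ValueError("no spikes")
    if phases.size < min_spikes:
        raise ValueError(f"need at least {min_spikes} spikes (got {phases.size})")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    wrapped = np.angle(np.exp(1j * phases))
    counts, _ = np.histogram(wrapped, bins=edges)
    mi, p = _mi_from_weights(counts, n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    return MIResult(mi, n_bins, p, float(centers[np.argmax(counts)]), phases.size)


def gamma_power_mi(
    lfp,
    fs: float,
    gamma_band=(70.0, 100.0),
    delta_band=(1.0, 4.0),
    n_bins: int = 100,
    phase=None,
) -> MIResult:
    """Modulation index of the gamma amplitude envelope by delta phase.

    The 70-100 Hz analytic-signal envelope is averaged within 100 delta-phase
    bins, the bin profile normalized to sum 1, and the MI computed on that
    distribution.  A least-squares sinusoid fit A*cos(phi - phi0) + c to the
    bin means supplies the preferred phase.
    """
    lfp = np.asarray(lfp, dtype=float)
    if fs < 2 * gamma_band[1]:
        raise ValueError("sampling rate below Nyquist for the gamma band")
    if phase is None:
        phase, valid = delta_phase(lfp, fs, delta_band)
    else:
        valid = np.ones(lfp.size, dtype=bool)
    env = np.abs(hilbert(bandpass_fir(lfp, fs, gamma_band)))
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase[valid], edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=env[valid], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    mi, p = _mi_from_weights(means, n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    # sinusoid fit: means ~ a*cos(phi) + b*sin(phi) + c
    design = np.column_stack([np.cos(centers), np.sin(centers), np.ones(n_bins)])
    coef, *_ = np.linalg.lstsq(design, means, rcond=None)
    phi0 = float(np.arctan2(coef[1], coef[0]))
    return MIResult(mi, n_bins, p, phi0, int(valid.sum()))


@dataclass
class MIChange:
    effect: PairedEffect
    mi_pre: float
    mi_on: float

    @property
    def fraction_change(self) -> float:
        return (self.mi_on - self.mi_pre) / self.mi_pre


def mi_change(
    spike_times,
    fs: float,
    phase,
    onsets,
    duration_s: float = 30.0,
    n_bins: int = 10,
    min_spikes_per_trial: int = 10,
    valid=None,
) -> MIChange:
    """Per-trial paired MI change, stimulation vs pre window.

    Trials with fewer than ``min_spikes_per_trial`` spikes in either window
    are dropped; pooled-window MIs give the overall fraction change.
    """
    spikes = np.asarray(spike_times, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 6:
        raise ValueError("need at least 6 trials")
    sp_phase = phases_at(spikes, fs, phase)
    diffs, pre_all, on_all = [], [], []
    for onset in onsets:
        pre = sp_phase[(spikes >= onset - duration_s) & (spikes < onset)]
        on = sp_phase[(spikes >= onset) & (spikes < onset + duration_s)]
        pre_all.append(pre)
        on_all.append(on)
        if pre.size >= min_spikes_per_trial and on.size >= min_spikes_per_trial:
            mi_p, _ = _mi_from_weights(
                np.histogram(pre, bins=np.linspace(-np.pi, np.pi, n_bins + 1))[0] + 0.0,
                n_bins,
            )
            mi_o, _ = _mi_from_weights(
                np.histogram(on, bins=np.linspace(-np.pi, np.pi, n_bins + 1))[0] + 0.0,
                n_bins,
            )
            diffs.append(mi_o - mi_p)
    if len(diffs) < 6:
        raise ValueError("fewer than 6 trials with enough spikes")
    mi_pre = spike_phase_mi(np.concatenate(pre_all), n_bins, min_spikes=1).mi_bits
    mi_on = spike_phase_mi(np.concatenate(on_all), n_bins, min_spikes=1).mi_bits
    return MIChange(signed_rank_effect(np.array(diffs)), mi_pre, mi_on)


def circular_kurtosis(angles) -> float:
    """Circular kurtosis: mean cosine of twice the deviation from the mean.

    k = mean(cos(2*(alpha - mean_direction))); 1 for a point mass, ~0 for a
    uniform sample.
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 1:
        raise ValueError("empty sample")
    _, mu = _circ_mean_vec(a)
    return float(np.mean(np.cos(2 * np.angle(np.exp(1j * (a - mu))))))


@dataclass
class KurtosisCompare:
    diff: float
    boot_ci: tuple  # resample-with-replacement CI of the difference
    null_ci: tuple  # label-shuffle CI (chance distribution of the difference)
    n_boot: int

    @property
    def significant(self) -> bool:
        return not (self.null_ci[0] <= self.diff <= self.null_ci[1])


def circular_kurtosis_compare(
    phases_a, phases_b, n_boot: int = 1000, seed=None
) -> KurtosisCompare:
    """Difference in circular kurtosis of per-unit peak phases between groups.

    Significance is judged against a label-shuffle bootstrap: unit-type
    assignments are permuted ``n_boot`` times and the observed difference
    compared to the 2.5th/97.5th percentiles of the shuffled differences.  A
    resample-with-replacement CI of the difference itself is also reported.
    """
    a = np.asarray(phases_a, dtype=float)
    b = np.asarray(phases_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 units per group")
    diff = circular_kurtosis(a) - circular_kurtosis(b)
    rng = np.random.default_rng(seed)
    pool = np.concatenate([a, b])
    null = np.empty(n_boot)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        perm = rng.permutation(pool.size)
        null[i] = circular_kurtosis(pool[perm[: a.size]]) - circular_kurtosis(
            pool[perm[a.size:]]
        )
        boot[i] = circular_kurtosis(
            a[rng.integers(0, a.size, a.size)]
        ) - circular_kurtosis(b[rng.integers(0, b.size, b.size)])
    return KurtosisCompare(
        float(diff),
        tuple(np.percentile(boot, [2.5, 97.5])),
        tuple(np.percentile(null, [2.5, 97.5])),
        n_boot,
    )


def align_lfp_polarity(lfp, fs: float, onsets, window_s: float = 0.1):
    """Flip an LFP trace so the laser-onset-locked deflection is negative.

    Used for subcortical channels, where electrode placement or referencing
    can invert the sign; returns (trace, flipped flag).
    """
    lfp = np.asarray(lfp, dtype=float)
    nper = int(round(window_s * fs))
    segs = []
    for onset in np.asarray(onsets, dtype=float):
        i = int(round(onset * fs))
        if 0 <= i and i + nper <= lfp.size:
            seg = lfp[i:i + nper]
            segs.append(seg - lfp[max(0, i - nper):i].mean())
    mean_defl = float(np.mean([s.mean() for s in segs])) if segs else 0.0
    if mean_defl > 0:
        return -lfp, True
    return lfp, False
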