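"""Synthetic session generator with ground-truth labels.

Every downstream analysis has a recoverable target here: LFP channels are
1/f background noise plus, during laser-ON blocks, an asymmetric 1-4 Hz
oscillation (deeper troughs than peaks) scaled to a requested delta-band
power change in dB, with 70-100 Hz amplitude modulated by the delta phase;
spike trains come from a conditional-intensity model with von Mises
phase locking, a multiplicative 2 ms-lag history kernel, and zero intensity
inside ground-truth OFF periods; EEG/EMG carry wake/NREM/REM structure
readable by the sleep scorer.

Laser protocol defaults follow the study conditions: 30 s ON blocks at
constant power separated by 60-90 s OFF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq
from scipy.special import i0 as bessel_i0

from .session import Session, SpikeTrain, TrialSet
from .slowwaves import bandpass_fir


@dataclass
class GroundTruth:
    """Injected quantities for one synthetic session or channel/unit."""

    delta_effect_db: dict = field(default_factory=dict)  # channel -> dB
    trough_times: np.ndarray = None  # s, slow-wave troughs during ON
    off_periods: list = field(default_factory=list)  # (start, end) s
    kappa: dict = field(default_factory=dict)  # unit -> (kappa, phi0)
    history_gain: dict = field(default_factory=dict)  # unit -> per-2ms gains
    state_seconds: np.ndarray = None  # per-second labels
    delta_phase: np.ndarray = None  # rad, full-rate phase series
    artifact_times: list = field(default_factory=list)  # s, burst starts
    fs: float = 1000.0

    def off_fraction_pct(self, t0: float, t1: float) -> float:
        tot = sum(min(e, t1) - max(s, t0) for s, e in self.off_periods
                  if e > t0 and s < t1)
        return 100.0 * tot / (t1 - t0)


def default_trials(
    duration_s: float,
    stim_s: float = 30.0,
    gap_range=(60.0, 90.0),
    power_mw: float = 2.0,
    first_onset_s: float = 60.0,
    rng=None,
) -> TrialSet:
    """30 s constant-power ON blocks separated by 60-90 s OFF."""
    rng = np.random.default_rng(rng)
    onsets = []
    t = first_onset_s
    while t + stim_s + 1 <= duration_s:
        onsets.append(t)
        t += stim_s + rng.uniform(*gap_range)
    onsets = np.array(onsets)
    return TrialSet(onsets, onsets + stim_s,
                    np.full(onsets.size, power_mw), stim_s)


def one_over_f_noise(n: int, fs: float, exponent: float = 1.0,
                     rms_uv: float = 40.0, rng=None):
    """1/f^exponent background by spectral shaping of white noise."""
    rng = np.random.default_rng(rng)
    white = rng.standard_normal(n)
    spec = rfft(white)
    freqs = rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = irfft(spec * shape, n)
    return x * (rms_uv / np.std(x))


def _delta_phase_track(n: int, fs: float, f0: float = 2.0,
                       f_jitter: float = 0.3, rng=None):
    """Slowly wandering instantaneous frequency around f0; returns phase."""
    rng = np.random.default_rng(rng)
    n_sec = int(np.ceil(n / fs)) + 2
    f_knots = f0 + f_jitter * rng.standard_normal(n_sec)
    f_knots = np.clip(f_knots, 1.2, 3.8)
    t_knots = np.arange(n_sec) * fs
    inst_f = np.interp(np.arange(n), t_knots, f_knots)
    return np.cumsum(2 * np.pi * inst_f / fs)


def _band_power_on(x, fs: float, trials: TrialSet, band=(1.0, 4.0)):
    """Mean band power (uV^2) over the ON blocks, by Welch periodogram."""
    from scipy.signal import welch

    segs = []
    for a, b in zip(trials.onsets, trials.offsets):
        segs.append(np.asarray(x)[int(a * fs):int(b * fs)])
    seg = np.concatenate(segs)
    nper = min(seg.size, int(30 * fs))
    freqs, psd = welch(seg, fs, nperseg=nper)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.sum(psd[sel]) * (freqs[1] - freqs[0]))


def _on_mask(n: int, fs: float, trials: TrialSet):
    mask = np.zeros(n, dtype=bool)
    for a, b in zip(trials.onsets, trials.offsets):
        mask[int(a * fs):int(b * fs)] = True
    return mask


def generate_lfp(
    duration_s: float,
    trials: TrialSet,
    delta_effect_db: float = 2.5,
    seed=None,
    fs: float = 1000.0,
    asymmetry: float = 0.3,
    background_rms_uv: float = 120.0,
    gamma_rms_uv: float = 4.0,
    gamma_coupling: float = 0.6,
    gamma_phi0: float = np.pi,
    spindle_rate_hz: float = 0.05,
    off_prob: float = 0.5,
    off_median_ms: float = 122.0,
    off_sigma_log: float = 0.35,
    sw_event_amp_uv=(350.0, 600.0),
    sw_event_fraction: float = 0.031,
    artifacts: bool = False,
):
    """One LFP channel with a laser-locked slow-wave effect.

    The ON-block oscillation is fundamental + phase-locked second harmonic,
    ``s(phi) = cos(phi) - asymmetry*cos(2*phi)``, so troughs (phi = pi) are
    deeper than peaks.  On top of it, discrete large-amplitude slow-wave
    events (negative trough followed by a positive peak) are injected at a
    subset of ON-block delta troughs; these are the labelled ground-truth
    slow waves.  Their number is set to ``sw_event_fraction`` of the
    session's candidate minima (census of filtered minima below -100 uV) so
    a top-3%% peak-to-peak detector recovers them.  The combined power of
    oscillation + events is calibrated against the realized baseline
    delta-band power so the ON-vs-pre change is ~``delta_effect_db``.
    Returns (trace uV, GroundTruth).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if trials.offsets.size and trials.offsets.max() > duration_s:
        raise ValueError("duration does not cover the trials")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    x = one_over_f_noise(n, fs, 1.0, background_rms_uv, rng)
    on = _on_mask(n, fs, trials)

    phase = _delta_phase_track(n, fs, rng=rng)
    wrapped = np.angle(np.exp(1j * phase))
    trough_times = np.array([])
    off_periods = []
    if delta_effect_db != 0.0 and on.any():
        p0 = _band_power_on(x, fs, trials)
        p_add = p0 * abs(10.0 ** (delta_effect_db / 10.0) - 1.0)
        sign = 1.0 if delta_effect_db > 0 else -1.0
        # phase-trough sample indices during ON
        cross = np.nonzero(np.diff(np.floor((phase - np.pi) / (2 * np.pi))) > 0)[0]
        cross = cross[on[cross]]
        # soft 250 ms onset/offset ramp keeps edges artifact-free
        ramp = np.convolve(on.astype(float),
                           np.ones(int(0.25 * fs)) / (0.25 * fs), mode="same")
        if sign > 0:
            from scipy.signal import find_peaks

            # per-trial calibration: the injected power (events + rhythmic
            # component) acts as a gain on each block's own background delta
            # power, so the realized dB change is homogeneous across trials.
            ratio = 10.0 ** (delta_effect_db / 10.0) - 1.0
            raw_osc = np.cos(phase) - asymmetry * np.cos(2 * phase)
            budgets, blocks = [], []
            amp_profile = np.zeros(n)
            for a, b in zip(trials.onsets, trials.offsets):
                blk = TrialSet(np.array([a]), np.array([b]),
                               np.array([trials.power_mw[0]]),
                               trials.stim_duration)
                i0, i1 = int(a * fs), int(b * fs)
                budget = _band_power_on(x, fs, blk) * ratio
                budgets.append(budget)
                blocks.append((blk, i0, i1))
                amp_profile[i0:i1] = np.sqrt(2.0 * budget / (1.0 + asymmetry**2))
            # candidate census on background + full-budget oscillation, so
            # the injected event count tracks the top-3% detector's yield
            census = x + raw_osc * amp_profile * ramp
            n_cand = find_peaks(-bandpass_fir(census, fs, (0.1, 5.0)),
                                height=100.0)[0].size
            frac = sw_event_fraction / (1 - sw_event_fraction)
            n_ev = int(round(frac * max(n_cand, 1)))
            # pool of well-separated trough sites with pre-drawn amplitudes
            half = int(0.35 * fs)
            tt = np.arange(-half, half) / fs
            pool = []
            for idx in rng.permutation(cross):
                if half <= idx <= n - half and all(
                        abs(idx - p) > fs for p, _ in pool):
                    pool.append((int(idx), rng.uniform(*sw_event_amp_uv)))
                if len(pool) >= 2 * n_ev + 20:
                    break

            def _build(n_use):
                train = np.zeros(n)
                times = []
                for idx, a in sorted(pool[:n_use]):
                    shape = (-a * np.exp(-(tt**2) / (2 * 0.08**2))
                             + 0.6 * a * np.exp(-((tt - 0.18) ** 2)
                                                / (2 * 0.09**2)))
                    train[idx - half:idx + half] += shape
                    times.append(idx / fs)
                prof = np.zeros(n)
                for budget, (blk, i0, i1) in zip(budgets, blocks):
                    p_ev_t = _band_power_on(train, fs, blk)
                    if p_ev_t > budget > 0:
                        train[i0:i1] *= np.sqrt(budget / p_ev_t)
                        p_ev_t = budget
                    p_osc_t = max(budget - p_ev_t, 0.0)
                    prof[i0:i1] = np.sqrt(2.0 * p_osc_t / (1.0 + asymmetry**2))
                return x + raw_osc * prof * ramp + train, np.asarray(times)

            # one fixed-point round: re-census the finished trace, so the
            # event count matches what a top-3% detector will keep there
            trace, ev_times = _build(n_ev)
            n_cand1 = find_peaks(-bandpass_fir(trace, fs, (0.1, 5.0)),
                                 height=100.0)[0].size
            n_target = n_ev
            for _ in range(8):
                nxt = int(round(frac * max(n_cand1 - n_ev + n_target, 1)))
                if nxt == n_target:
                    break
                n_target = nxt
            n_target = min(n_target, len(pool))
            if n_target != n_ev:
                trace, ev_times = _build(n_target)
            x = trace
            trough_times = ev_times
        else:
            # suppression: attenuate the background's own delta band during ON
            atten = 1.0 - 10.0 ** (delta_effect_db / 20.0)
            x = x - atten * ramp * bandpass_fir(x, fs, (1.0, 4.0))
        # OFF periods at a subset of ON delta troughs, log-normal durations
        for idx in cross:
            if rng.uniform() < off_prob:
                dur = np.exp(np.log(off_median_ms / 1000.0)
                             + off_sigma_log * rng.standard_normal())
                c = idx / fs + rng.normal(0, 0.01)
                off_periods.append((c - dur / 2, c + dur / 2))
    # delta-phase-modulated gamma during ON
    if gamma_rms_uv > 0:
        g = one_over_f_noise(n, fs, 0.0, 1.0, rng)
        g = bandpass_fir(g, fs, (70.0, 100.0))
        g *= gamma_rms_uv / np.std(g)
        mod = np.ones(n)
        mod[on] = 1.0 + gamma_coupling * np.cos(wrapped[on] - gamma_phi0)
        x = x + g * mod
    # spindle transients (9-15 Hz, ~0.7 s)
    n_spindles = rng.poisson(spindle_rate_hz * duration_s)
    for _ in range(n_spindles):
        t0 = rng.uniform(1.0, duration_s - 1.0)
        f_sp = rng.uniform(9.0, 15.0)
        tt = np.arange(int(0.7 * fs)) / fs
        burst = 30.0 * np.hanning(tt.size) * np.sin(2 * np.pi * f_sp * tt)
        i0 = int(t0 * fs)
        x[i0:i0 + burst.size] += burst[: max(0, n - i0)]
    artifact_times = []
    if artifacts:
        # alternating-sign square bursts whose 400 ms-window SD clearly
        # exceeds the 2000 uV artifact-rejection rule
        w = int(0.15 * fs)
        burst = 7000.0 * np.sign(np.sin(2 * np.pi * 25.0 * np.arange(w) / fs))
        for _ in range(max(3, int(duration_s / 120))):
            i0 = int(rng.uniform(5.0, duration_s - 5.0) * fs)
            x[i0:i0 + w] += burst[: x.size - i0]
            artifact_times.append(i0 / fs)
    gt = GroundTruth(
        delta_effect_db={0: delta_effect_db},
        trough_times=trough_times,
        off_periods=off_periods,
        delta_phase=wrapped,
        artifact_times=artifact_times,
        fs=fs,
    )
    return x, gt


def generate_spike_train(
    duration_s: float,
    base_rate_hz: float,
    phase_lock=None,  # (kappa, phi0) against a supplied phase series
    phase=None,  # rad per sample at fs
    history_gain=None,  # per-2 ms-lag multiplicative gains, lags (0,2],(2,4],..
    off_periods=None,  # list of (start, end) s where intensity is 0
    seed=None,
    fs: float = 1000.0,
    unit_id: str = "u0",
    peak_to_trough_us: float = 350.0,
    region: str = "cortex",
    quality: str = "single",
    on_mask=None,  # restrict phase modulation to these samples
    rate_profile=None,  # optional per-sample rate multiplier
):
    """Spike train from a conditional-intensity model (1 ms thinning grid).

    lambda(t) = base_rate * vonmises(phase(t); kappa, phi0) [mean 1]
                * prod_lags gain[lag, spike present] * 1[t not in OFF].

    With ``history_gain=None`` the train is an inhomogeneous Poisson process
    (vectorized); with history it is simulated sequentially.  Spike times get
    uniform sub-bin jitter so ISIs are continuous.
    """
    if base_rate_hz <= 0:
        raise ValueError("base rate must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs
    n = int(round(duration_s * fs))
    lam = np.full(n, base_rate_hz)
    if rate_profile is not None:
        lam = lam * np.asarray(rate_profile, dtype=float)[:n]
    if phase_lock is not None:
        kappa, phi0 = phase_lock
        if kappa < 0:
            raise ValueError("kappa must be non-negative")
        if kappa > 0:
            if phase is None:
                raise ValueError("phase series required for phase locking")
            vm = np.exp(kappa * np.cos(phase[:n] - phi0)) / bessel_i0(kappa)
            if on_mask is not None:
                lam = np.where(on_mask[:n], lam * vm, lam)
            else:
                lam = lam * vm
    off_mask = np.ones(n, dtype=bool)
    if off_periods:
        for s, e in off_periods:
            off_mask[max(0, int(s * fs)):min(n, int(np.ceil(e * fs)))] = False
    lam = lam * off_mask
    if history_gain is None:
        p = np.clip(lam * dt, 0, 1)
        hits = np.nonzero(rng.uniform(size=n) < p)[0]
        times = (hits + rng.uniform(size=hits.size)) * dt
    else:
        # history lags follow the same absolute 2 ms binning the GLM uses:
        # a spike in bin b multiplies the rate in bin b+k by gains[k-1]
        gains = np.asarray(history_gain, dtype=float)
        lag_samples = 2  # 2 ms bins on the 1 ms grid
        horizon = (gains.size + 1) * lag_samples
        times_list = []
        recent = []  # spike sample indices within horizon
        u = rng.uniform(size=n)
        for i in range(n):
            li = lam[i]
            if recent and i - recent[0] > horizon:
                recent = [s for s in recent if i - s <= horizon]
            if li > 0 and recent:
                bin_i = i // lag_samples
                for s in recent:
                    k = bin_i - s // lag_samples
                    if 1 <= k <= gains.size:
                        li *= gains[k - 1]
            if li > 0 and u[i] < min(li * dt, 1.0):
                recent.append(i)
                times_list.append(i)
        times = (np.asarray(times_list, dtype=float)
                 + rng.uniform(size=len(times_list))) * dt
    train = SpikeTrain(unit_id, np.sort(times), peak_to_trough_us, region, quality)
    gt = GroundTruth(
        kappa={unit_id: phase_lock if phase_lock else (0.0, 0.0)},
        history_gain={unit_id: None if history_gain is None
                      else np.asarray(history_gain, float)},
        off_periods=list(off_periods) if off_periods else [],
        fs=fs,
    )
    return train, gt


STATE_EMG_RMS = {"wake": 30.0, "nrem": 5.0, "rem": 4.0}


def generate_state_session(state_epochs, seed=None, fs: float = 1000.0):
    """EEG + EMG with wake/NREM/REM structure, plus per-second labels.

    ``state_epochs`` is a list of (state, duration_s) pairs.  EMG 60-200 Hz
    amplitude is high in wake only; the EEG <4 Hz : 4-16 Hz power ratio is
    high in NREM (2 Hz oscillation) and low in wake/REM (7 Hz theta).
    Returns (eeg uV, emg uV, labels per second, GroundTruth).
    """
    states = {s for s, _ in state_epochs}
    bad = states - set(STATE_EMG_RMS)
    if bad:
        raise ValueError(f"unknown states: {bad}")
    rng = np.random.default_rng(seed)
    total_s = sum(d for _, d in state_epochs)
    n = int(round(total_s * fs))
    eeg = one_over_f_noise(n, fs, 1.0, 20.0, rng)
    emg_carrier = bandpass_fir(rng.standard_normal(n), fs, (60.0, 200.0))
    emg_carrier /= np.std(emg_carrier)
    emg_amp = np.empty(n)
    t = np.arange(n) / fs
    i0 = 0
    for state, dur in state_epochs:
        i1 = min(i0 + int(round(dur * fs)), n)
        seg = slice(i0, i1)
        emg_amp[seg] = STATE_EMG_RMS[state]
        if state == "nrem":
            eeg[seg] += 60.0 * np.sin(2 * np.pi * 2.0 * t[seg]
                                      + rng.uniform(0, 2 * np.pi))
        else:
            eeg[seg] += 25.0 * np.sin(2 * np.pi * 7.0 * t[seg]
                                      + rng.uniform(0, 2 * np.pi))
        i0 = i1
    emg = emg_carrier * emg_amp + rng.standard_normal(n)
    # one label per second, read off the epoch covering that second's center
    bounds = np.cumsum([d for _, d in state_epochs])
    names = [s for s, _ in state_epochs]
    n_sec = int(np.ceil(total_s))
    idx = np.minimum(np.searchsorted(bounds, np.arange(n_sec) + 0.5),
                     len(names) - 1)
    labels = np.array([names[i] for i in idx], dtype=str)
    gt = GroundTruth(state_seconds=labels, fs=fs)
    return eeg, emg, labels, gt


PRESETS = ("awake-stim", "nrem", "anesthesia", "halo")


def generate_session(
    preset: str = "awake-stim",
    duration_s: float = 600.0,
    seed=None,
    fs: float = 1000.0,
    n_channels: int = 2,
    delta_effect_db: float = 2.5,
    n_units: int = 2,
    base_rate_hz: float = 12.0,
    kappa: float = 1.0,
    stim_s: float = 30.0,
    power_mw: float = 2.0,
) -> tuple:
    """Full synthetic Session for a named experimental condition.

    Presets: "awake-stim" (ChR2 stimulation in the awake animal; channel 0
    carries the injected delta effect, channel 1 is null), "nrem"
    (stimulation during sleep, all-NREM background), "anesthesia" (like
    nrem with stronger background delta), "halo" (halorhodopsin suppression:
    negative delta effect during ON).  Returns (Session, GroundTruth).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    rng = np.random.default_rng(seed)
    trials = default_trials(duration_s, stim_s=stim_s, power_mw=power_mw,
                            rng=rng)
    if trials.onsets.size == 0:
        raise ValueError("duration too short for any trial")
    eff = {"awake-stim": delta_effect_db, "nrem": delta_effect_db,
           "anesthesia": delta_effect_db, "halo": -abs(delta_effect_db)}[preset]
    lfp = np.empty((n_channels, int(round(duration_s * fs))), dtype=np.float32)
    gt = GroundTruth(fs=fs)
    phase0 = None
    for ch in range(n_channels):
        ch_eff = eff if ch == 0 else 0.0
        trace, ch_gt = generate_lfp(
            duration_s, trials, ch_eff, seed=rng.integers(2**31), fs=fs
        )
        lfp[ch] = trace
        gt.delta_effect_db[ch] = ch_eff
        if ch == 0:
            gt.trough_times = ch_gt.trough_times
            gt.off_periods = ch_gt.off_periods
            gt.delta_phase = ch_gt.delta_phase
            phase0 = ch_gt.delta_phase
    on_mask = _on_mask(lfp.shape[1], fs, trials)
    spikes = []
    for u in range(n_units):
        uid = f"u{u}"
        train, u_gt = generate_spike_train(
            duration_s, base_rate_hz, phase_lock=(kappa, np.pi),
            phase=phase0, off_periods=gt.off_periods,
            seed=rng.integers(2**31), fs=fs, unit_id=uid,
            peak_to_trough_us=float(rng.uniform(250, 450)),
            on_mask=on_mask,
        )
        spikes.append(train)
        gt.kappa[uid] = (kappa, np.pi)
    if preset in ("nrem", "anesthesia", "halo"):
        epochs = [("nrem", duration_s)]
    else:
        epochs = [("wake", 120.0), ("nrem", duration_s - 240.0), ("wake", 120.0)]
    eeg, emg, labels, _ = generate_state_session(
        epochs, seed=rng.integers(2**31), fs=fs
    )
    gt.state_seconds = labels
    meta = [{"tag": "ipsi-posterior" if c == 0 else "contra", "x": float(c),
             "y": 0.0} for c in range(n_channels)]
    session = Session(
        lfp=lfp, fs_lfp=fs, eeg=eeg, fs_eeg=fs, emg=emg, fs_emg=fs,
        spikes=spikes, trials=trials, channel_meta=meta, state_labels=labels,
    )
    return session, gt
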