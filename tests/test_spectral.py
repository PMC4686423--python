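"""Multitaper spectra, normalized spectrograms, band-power effects."""

import numpy as np
import pytest

from localsleep.spectral import (
    band_power_change,
    delta_effect_map,
    multitaper_spectrum,
    normalized_spectrogram,
)
from localsleep.session import TrialSet

FS = 1000.0


class TestMultitaperSpectrum:
    def test_pure_tone_power_concentrated(self):
        """A 3 Hz unit sinusoid keeps >= 95% of its power within the
        multitaper bandwidth 2*NW/T of the line."""
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 3.0 * t)
        sp = multitaper_spectrum(x, FS, window_s=30.0, k=19)
        bw = 2 * sp.nw / sp.window_s
        inside = sp.band_power((3.0 - bw, 3.0 + bw))
        total = sp.band_power((0.0, FS / 2))
        assert inside / total >= 0.95

    def test_parseval_white_noise(self):
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(10):
            x = rng.normal(0, 2.0, int(30 * FS))
            sp = multitaper_spectrum(x, FS, 30.0, 19)
            ratios.append(sp.band_power((0, FS / 2)) / np.var(x))
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_constant_signal_power_at_dc_only(self):
        # all power concentrates within the taper bandwidth around 0 Hz
        sp = multitaper_spectrum(np.full(int(30 * FS), 5.0), FS, 30.0, 5)
        bw = 2 * sp.nw / sp.window_s
        assert sp.power[0] > 0
        dc = sp.band_power((0.0, bw))
        assert dc / sp.band_power((0.0, FS / 2)) > 0.999

    def test_requires_at_least_one_taper_and_enough_data(self):
        with pytest.raises(ValueError):
            multitaper_spectrum(np.zeros(1000), FS, 30.0, 0)
        with pytest.raises(ValueError):
            multitaper_spectrum(np.zeros(1000), FS, 30.0, 5)


class TestNormalizedSpectrogram:
    def test_stationary_noise_near_zero_db(self):
        # cells scatter around 0 dB with the single-window estimator
        # variance (5 tapers, median of 20 trials): small mean, rare tails
        rng = np.random.default_rng(1)
        x = rng.normal(0, 50, int(1400 * FS))
        onsets = 40.0 + 65.0 * np.arange(20)
        _, freqs, mat = normalized_spectrogram(x, FS, onsets)
        sel = freqs <= 100
        assert np.abs(np.mean(mat[sel])) < 0.5
        assert np.mean(np.abs(mat[sel]) > 1.0) < 0.15

    def test_single_trial_is_its_own_normalization(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 50, int(120 * FS))
        t1, f1, m1 = normalized_spectrogram(x, FS, [60.0])
        t2, f2, m2 = normalized_spectrogram(x, FS, [60.0, 60.0])
        # median of identical trials equals the single trial
        assert np.allclose(m1, m2)

    def test_trial_without_pre_window_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 50, int(200 * FS))
        with pytest.warns(UserWarning):
            times, freqs, mat = normalized_spectrogram(x, FS, [10.0, 100.0])
        assert np.isfinite(mat).all()

    def test_injected_delta_visible_in_on_cells(self, stim_lfp):
        x, gt, trials = stim_lfp
        times, freqs, mat = normalized_spectrogram(
            x, FS, trials.onsets[:10]
        )
        band = (freqs >= 1) & (freqs <= 4)
        on = (times >= 5) & (times < 25)
        off = times < -5
        # the injected rhythm concentrates near 2 Hz; the whole band rises
        core = (freqs >= 1.6) & (freqs <= 2.8)
        assert 1.5 <= mat[np.ix_(core, on)].mean() <= 4.5
        assert mat[np.ix_(band, on)].mean() > 0.75
        assert abs(mat[np.ix_(band, off)].mean()) < 0.5


class TestBandPowerChange:
    def test_identical_pre_stim_spans_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 30, int(600 * FS))
        onsets = 40.0 + 65.0 * np.arange(8)
        eff = band_power_change(x, FS, onsets, (1.0, 4.0))
        assert eff.effect.ci_lo < 0 < eff.effect.ci_hi

    def test_db_change_invariant_to_rescaling(self, stim_lfp):
        x, _, trials = stim_lfp
        onsets = trials.onsets[:8]
        a = band_power_change(x, FS, onsets, (1.0, 4.0))
        b = band_power_change(2.7 * x, FS, onsets, (1.0, 4.0))
        assert a.effect.median == pytest.approx(b.effect.median)

    def test_recovers_injected_effect(self, stim_lfp):
        x, gt, trials = stim_lfp
        eff = band_power_change(x, FS, trials.onsets, (1.0, 4.0))
        assert abs(eff.median_change_db - 2.5) <= 0.5

    def test_band_additivity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 20, int(60 * FS))
        sp = multitaper_spectrum(x, FS, 30.0, 19)
        df = sp.freqs[1] - sp.freqs[0]
        whole = sp.band_power((1.0, 8.0))
        parts = sp.band_power((1.0, 4.0)) + sp.band_power((4.0 + df, 8.0))
        assert whole == pytest.approx(parts, rel=1e-9)

    def test_needs_six_trials(self):
        with pytest.raises(ValueError):
            band_power_change(np.zeros(int(400 * FS)), FS,
                              [40.0, 110.0], (1, 4))


class TestDeltaEffectMap:
    FS_LO = 200.0

    def _mini_session(self, rng, n_ch, injected, n_trials=10, amp=20.0):
        stim = 5.0
        onsets = 10.0 + 12.0 * np.arange(n_trials)
        dur = onsets[-1] + 10.0
        n = int(dur * self.FS_LO)
        t = np.arange(n) / self.FS_LO
        lfp = rng.normal(0, 30, (n_ch, n))
        on = np.zeros(n, dtype=bool)
        for o in onsets:
            on[int(o * self.FS_LO):int((o + stim) * self.FS_LO)] = True
        for ch in injected:
            lfp[ch, on] += amp * np.sin(2 * np.pi * 2.2 * t[on])
        return lfp, onsets, stim

    def test_injected_channels_bonferroni_significant(self):
        """Injected channels are always flagged; at most one null channel
        may reach chance-level significance."""
        rng = np.random.default_rng(6)
        lfp, onsets, stim = self._mini_session(rng, 6, injected=[0, 2],
                                               n_trials=12, amp=40.0)
        res = delta_effect_map(lfp, self.FS_LO, onsets, window_s=stim, k=5)
        sig = {e.channel for e in res if e.significant_bonferroni}
        assert sig >= {0, 2} and len(sig) <= 3
        flagged = {e.channel for e in res if e.delta_effect_flag}
        assert flagged == {0, 2}

    def test_family_wise_error_controlled_on_null(self):
        """Across 40 all-null sessions of 6 channels, the Bonferroni map
        should flag any channel in at most ~5% of sessions."""
        rng = np.random.default_rng(7)
        n_bad = 0
        for _ in range(40):
            lfp, onsets, stim = self._mini_session(rng, 6, injected=[],
                                                   n_trials=8)
            res = delta_effect_map(lfp, self.FS_LO, onsets,
                                   window_s=stim, k=5)
            n_bad += any(e.significant_bonferroni for e in res)
        assert n_bad <= 6  # binomial(40, 0.05) upper tail
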