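"""EMG power, sleep scoring, optical flow, couplings, shuffled controls."""

import numpy as np
import pytest

from localsleep.behavior import (
    SleepLabels,
    eeg_emg_correlation,
    emg_band_power,
    emg_first_second_change,
    emg_power_change,
    motion_from_frames,
    score_sleep,
    shuffled_onset_control,
    state_occupancy_change,
)
from localsleep.slowwaves import bandpass_fir
from localsleep.synth import generate_state_session

FS = 1000.0


def _emg_with_profile(duration_s, amp_profile, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration_s * FS)
    carrier = bandpass_fir(rng.standard_normal(n), FS, (60.0, 200.0))
    carrier /= np.std(carrier)
    return carrier * amp_profile + 0.5 * rng.standard_normal(n)


class TestEmgPower:
    ONSETS = 60.0 + 70.0 * np.arange(8)

    def test_power_scales_quadratically(self):
        rng = np.random.default_rng(1)
        emg = rng.normal(0, 10, int(30 * FS))
        _, p1 = emg_band_power(emg, FS)
        _, p2 = emg_band_power(2 * emg, FS)
        assert np.allclose(p2, 4 * p1)

    def test_stationary_noise_spans_zero(self):
        emg = _emg_with_profile(620.0, np.full(int(620 * FS), 20.0))
        eff = emg_power_change(emg, FS, self.ONSETS)
        assert eff.ci_lo <= 0 <= eff.ci_hi

    def test_on_amplitude_drop_detected_and_fast(self):
        prof = np.full(int(620 * FS), 25.0)
        for o in self.ONSETS:
            prof[int(o * FS):int((o + 30) * FS)] = 10.0
        emg = _emg_with_profile(620.0, prof, seed=2)
        eff = emg_power_change(emg, FS, self.ONSETS)
        assert eff.median < 0 and eff.ci_hi < 0
        first = emg_first_second_change(emg, FS, self.ONSETS)
        assert first.median < 0

    def test_band_nyquist_guard(self):
        with pytest.raises(ValueError):
            emg_band_power(np.zeros(1000), fs=300.0)


class TestSleepScoring:
    def test_wake_only_scored_wake(self):
        eeg, emg, labels, _ = generate_state_session([("wake", 300)], seed=3)
        sl = score_sleep(eeg, emg, FS)
        assert np.mean(sl.states == "wake") >= 0.95

    def test_nrem_epochs_recovered(self):
        eeg, emg, labels, _ = generate_state_session(
            [("wake", 120), ("nrem", 300), ("wake", 120)], seed=4)
        sl = score_sleep(eeg, emg, FS)
        nrem_sel = labels == "nrem"
        assert np.mean(sl.states[: labels.size][nrem_sel] == "nrem") >= 0.9

    def test_emg_everywhere_above_threshold_is_all_wake(self):
        eeg, emg, labels, _ = generate_state_session([("nrem", 120)], seed=5)
        sl = score_sleep(eeg, emg, FS, emg_thresh=0.0, ratio_thresh=1.0)
        assert np.all(sl.states == "wake")

    def test_threshold_monotonicity(self):
        eeg, emg, labels, _ = generate_state_session(
            [("wake", 120), ("nrem", 180)], seed=6)
        wake_time = []
        for thr in (1.0, 5.0, 25.0, 100.0):
            sl = score_sleep(eeg, emg, FS, emg_thresh=thr, ratio_thresh=2.0)
            wake_time.append(np.sum(sl.states == "wake"))
        assert all(a >= b for a, b in zip(wake_time, wake_time[1:]))

    def test_label_vector_covers_whole_record(self):
        eeg, emg, labels, _ = generate_state_session([("nrem", 123)], seed=7)
        assert labels.size == 123
        sl = score_sleep(eeg, emg, FS)
        assert sl.states.size == 123


class TestOccupancyChange:
    def test_stationary_states_change_zero_and_closure(self):
        rng = np.random.default_rng(8)
        states = rng.choice(["wake", "nrem", "rem"], size=700,
                            p=[0.4, 0.45, 0.15])
        labels = SleepLabels(states.astype(str), 1.0, 1.0)
        onsets = 60.0 + 70.0 * np.arange(8)
        occ = state_occupancy_change(labels, onsets)
        total = sum(occ[s].median for s in ("wake", "nrem", "rem"))
        assert abs(total) < 5.0
        for s in occ.values():
            assert s.ci_lo <= s.median <= s.ci_hi

    def test_on_biased_nrem_detected(self):
        rng = np.random.default_rng(9)
        onsets = 60.0 + 70.0 * np.arange(10)
        states = np.array(
            rng.choice(["wake", "nrem"], size=800, p=[0.5, 0.5]), dtype=object)
        for o in onsets:  # push ~30 percentage points of NREM into ON blocks
            sel = slice(int(o), int(o) + 30)
            flip = rng.uniform(size=30) < 0.6
            states[sel] = np.where(flip, "nrem", states[sel])
        labels = SleepLabels(states.astype(str), 1.0, 1.0)
        occ = state_occupancy_change(labels, onsets)
        assert occ["nrem"].median > 0 and occ["nrem"].ci_lo > 0
        assert occ["wake"].median < 0


class TestMotion:
    def _translating_square(self, n=40, size=48):
        frames = np.zeros((n, size, size))
        for i in range(n):
            frames[i, 20:28, 5 + i % 30:13 + i % 30] = 1.0
        return frames

    def test_identical_frames_zero_motion(self):
        frames = np.tile(self._translating_square()[0], (6, 1, 1))
        m = motion_from_frames(frames, smooth_frames=3)
        assert np.all(m.raw_magnitude == 0.0)

    def test_translation_gives_positive_steady_trace(self):
        m = motion_from_frames(self._translating_square(), smooth_frames=5)
        assert np.all(m.raw_magnitude > 0)
        assert np.std(m.magnitude) < 0.5  # roughly constant once normalized

    def test_mean_normalization_contract(self):
        m = motion_from_frames(self._translating_square(), smooth_frames=5)
        raw_norm = m.raw_magnitude / m.raw_magnitude.mean()
        assert raw_norm.mean() == pytest.approx(1.0)

    def test_luminance_scaling_invariance(self):
        f = self._translating_square()
        a = motion_from_frames(f, smooth_frames=5)
        b = motion_from_frames(11.0 * f, smooth_frames=5)
        assert np.allclose(a.magnitude, b.magnitude)

    def test_two_frame_minimum(self):
        with pytest.raises(ValueError):
            motion_from_frames(np.zeros((1, 8, 8)))


class TestEegEmgCorrelation:
    def test_perfect_anticorrelation(self):
        x = np.linspace(-1, 1, 20)
        r = eeg_emg_correlation(x, -3 * x, n_boot=100, seed=0)
        assert r.r == pytest.approx(-1.0)

    def test_coupled_effects_detected(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=100)
        y = -0.4 * x + rng.normal(size=100) * np.sqrt(1 - 0.16)
        r = eeg_emg_correlation(x, y, seed=1)
        assert r.r < 0 and r.significant

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(11)
        fp = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            fp += eeg_emg_correlation(x, y, n_boot=200,
                                      seed=int(rng.integers(2**31))).significant
        assert fp / reps <= 0.1

    def test_pair_floor(self):
        with pytest.raises(ValueError):
            eeg_emg_correlation([1, 2], [3, 4])


class TestShuffledOnsets:
    def test_no_effect_statistic_inside_null(self):
        rng = np.random.default_rng(12)
        series = rng.normal(size=1200)
        labels = SleepLabels(np.array(["nrem"] * 1200, dtype=str), 1.0, 1.0)

        def stat(onsets):
            return float(np.mean([series[int(o)] for o in onsets]))

        true_onsets = rng.choice(np.arange(40, 1160), 12, replace=False)
        res = shuffled_onset_control(stat, true_onsets, labels,
                                     n_shuffles=200, seed=2)
        assert res.null_ci[0] <= res.true_value <= res.null_ci[1]

    def test_onset_locked_drop_detected(self):
        rng = np.random.default_rng(13)
        series = rng.normal(size=1200)
        true_onsets = np.sort(rng.choice(np.arange(40, 1160), 12,
                                         replace=False)).astype(float)
        for o in true_onsets:
            series[int(o)] -= 3.0
        labels = SleepLabels(np.array(["nrem"] * 1200, dtype=str), 1.0, 1.0)

        def stat(onsets):
            return float(np.mean([series[int(o)] for o in onsets]))

        res = shuffled_onset_control(stat, true_onsets, labels,
                                     n_shuffles=200, seed=3)
        assert res.true_value < res.null_ci[0]
        assert res.outside_null

    def test_seeded_null_reproducible(self):
        labels = SleepLabels(np.array(["nrem"] * 400, dtype=str), 1.0, 1.0)
        stat = lambda onsets: float(np.sum(onsets))
        a = shuffled_onset_control(stat, [100.0, 200.0], labels,
                                   n_shuffles=50, seed=4)
        b = shuffled_onset_control(stat, [100.0, 200.0], labels,
                                   n_shuffles=50, seed=4)
        assert np.array_equal(a.null_values, b.null_values)
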