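"""Delta phase, PLV, modulation index, circular statistics."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import i0 as bessel_i0

from localsleep.phase import (
    align_lfp_polarity,
    circular_kurtosis,
    circular_kurtosis_compare,
    delta_phase,
    gamma_power_mi,
    mi_change,
    plv,
    spike_phase_mi,
)

FS = 1000.0


class TestDeltaPhase:
    def test_tone_phase_advances_at_its_frequency(self):
        t = np.arange(int(60 * FS)) / FS
        x = 100 * np.cos(2 * np.pi * 2.0 * t)
        ph, valid = delta_phase(x, FS)
        un = np.unwrap(ph[valid])
        slope = (un[-1] - un[0]) / (un.size / FS)
        assert slope == pytest.approx(4 * np.pi, rel=0.01)

    def test_phase_at_minima_is_pi(self):
        t = np.arange(int(60 * FS)) / FS
        x = 100 * np.cos(2 * np.pi * 2.0 * t)
        ph, valid = delta_phase(x, FS)
        minima = (np.round((t - 0.25) * 2.0) == (t - 0.25) * 2.0) & valid
        assert np.allclose(np.abs(ph[minima]), np.pi, atol=0.05)

    def test_sign_flip_shifts_phase_by_pi(self):
        t = np.arange(int(60 * FS)) / FS
        x = 100 * np.cos(2 * np.pi * 2.0 * t) + np.random.default_rng(0).normal(0, 5, t.size)
        ph, valid = delta_phase(x, FS)
        ph_f, _ = delta_phase(-x, FS)
        d = np.angle(np.exp(1j * (ph_f - ph)))[valid]
        assert np.abs(np.mean(np.abs(d)) - np.pi) < 0.05

    def test_polarity_alignment_flips_positive_deflections(self):
        x = np.zeros(int(30 * FS))
        for o in (5.0, 10.0, 15.0):
            x[int(o * FS):int(o * FS) + 100] += 200.0
        y, flipped = align_lfp_polarity(x, FS, [5.0, 10.0, 15.0])
        assert flipped and np.allclose(y, -x)
        y2, flipped2 = align_lfp_polarity(-x, FS, [5.0, 10.0, 15.0])
        assert not flipped2


class TestPLV:
    WIN = [(i * 1000, (i + 1) * 1000) for i in range(10)]

    def test_identical_phases(self):
        rng = np.random.default_rng(0)
        pa = rng.uniform(-np.pi, np.pi, 20000)
        r = plv(pa, pa, self.WIN, n_perms=50, n_boot=50, seed=1)
        assert r.plv == pytest.approx(1.0)
        assert r.offset == pytest.approx(0.0)

    def test_constant_shift(self):
        rng = np.random.default_rng(1)
        pa = rng.uniform(-np.pi, np.pi, 20000)
        r = plv(pa, pa + 0.5, self.WIN, n_perms=50, n_boot=50, seed=1)
        assert r.plv == pytest.approx(1.0)
        assert r.offset == pytest.approx(0.5, abs=1e-6)

    def test_independent_phases_null(self):
        rng = np.random.default_rng(2)
        sig = 0
        for rep in range(20):
            pa = rng.uniform(-np.pi, np.pi, 10000)
            pb = rng.uniform(-np.pi, np.pi, 10000)
            r = plv(pa, pb, self.WIN, n_perms=100, n_boot=20,
                    seed=int(rng.integers(2**31)))
            if rep == 0:
                assert r.plv < 0.1
            sig += r.p <= 0.05
        assert sig <= 2  # p > 0.05 in >= 90% of null runs

    def test_null_p_uniform(self):
        """Permutation p-values under independence are uniform on (0, 1]."""
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            # trial-structured phases so the permutation has exchangeability
            pa = np.concatenate([np.full(50, a) + rng.normal(0, 0.3, 50)
                                 for a in rng.uniform(-np.pi, np.pi, 8)])
            pb = np.concatenate([np.full(50, a) + rng.normal(0, 0.3, 50)
                                 for a in rng.uniform(-np.pi, np.pi, 8)])
            win = [(i * 50, (i + 1) * 50) for i in range(8)]
            ps.append(plv(pa, pb, win, n_perms=99, n_boot=10,
                          seed=int(rng.integers(2**31))).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_needs_six_windows(self):
        with pytest.raises(ValueError):
            plv(np.zeros(100), np.zeros(100), [(0, 50)])


class TestSpikeMI:
    def test_uniform_counts_zero(self):
        phases = np.repeat(-np.pi + (np.arange(10) + 0.5) * 2 * np.pi / 10, 5)
        assert spike_phase_mi(phases).mi_bits == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_maximum(self):
        r = spike_phase_mi(np.full(100, 0.1))
        assert r.mi_bits == pytest.approx(np.log2(10))
        assert r.preferred_phase == pytest.approx(0.1 * 0 + np.pi / 10,
                                                  abs=2 * np.pi / 10)

    def test_von_mises_sample_matches_numeric_oracle(self):
        """MI of 10k von Mises(kappa=1) draws agrees with the MI of the
        exactly binned von Mises density within 0.02 bits."""
        kappa = 1.0
        edges = np.linspace(-np.pi, np.pi, 11)
        # numeric integration of the density per bin
        p = []
        for a, b in zip(edges[:-1], edges[1:]):
            xs = np.linspace(a, b, 2000)
            p.append(np.trapezoid(
                np.exp(kappa * np.cos(xs)) / (2 * np.pi * bessel_i0(kappa)), xs))
        p = np.array(p) / np.sum(p)
        mi_true = float(np.sum(p * np.log2(p)) + np.log2(10))
        draws = sps.vonmises.rvs(kappa, size=10_000,
                                 random_state=np.random.default_rng(0))
        r = spike_phase_mi(np.angle(np.exp(1j * draws)))
        assert abs(r.mi_bits - mi_true) < 0.02

    def test_bin_aligned_rotation_invariance(self):
        rng = np.random.default_rng(1)
        phases = sps.vonmises.rvs(2.0, size=2000, random_state=rng)
        a = spike_phase_mi(phases).mi_bits
        b = spike_phase_mi(phases + 2 * np.pi / 10).mi_bits
        assert a == pytest.approx(b, abs=1e-12)

    def test_mi_bounded_by_log_bins(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            phases = rng.uniform(-np.pi, np.pi, rng.integers(30, 500))
            r = spike_phase_mi(phases)
            assert 0.0 <= r.mi_bits <= np.log2(10) + 1e-12

    def test_spike_floor(self):
        with pytest.raises(ValueError):
            spike_phase_mi(np.zeros(5))
        with pytest.raises(ValueError):
            spike_phase_mi([])


class TestGammaMI:
    def test_phase_independent_amplitude_near_zero(self):
        rng = np.random.default_rng(3)
        t = np.arange(int(100 * FS)) / FS
        x = 200 * np.cos(2 * np.pi * 2 * t) + 10 * rng.normal(size=t.size)
        r = gamma_power_mi(x, FS)
        assert r.mi_bits < 0.001

    def test_sinusoidal_coupling_matches_analytic_profile(self):
        t = np.arange(int(200 * FS)) / FS
        phi = np.angle(np.exp(1j * (2 * np.pi * 2 * t - np.pi)))
        x = (200 * np.cos(2 * np.pi * 2 * t - np.pi)
             + (1 + 0.5 * np.cos(phi)) * 10 * np.cos(2 * np.pi * 85 * t))
        r = gamma_power_mi(x, FS)
        centers = (np.linspace(-np.pi, np.pi, 101)[:-1]
                   + np.linspace(-np.pi, np.pi, 101)[1:]) / 2
        prof = 1 + 0.5 * np.cos(centers)
        p = prof / prof.sum()
        mi_true = np.sum(p * np.log2(p)) + np.log2(100)
        assert r.mi_bits == pytest.approx(mi_true, rel=0.05)
        assert abs(r.preferred_phase) < 0.05


class TestMIChange:
    def test_stationary_unit_spans_zero(self):
        rng = np.random.default_rng(4)
        onsets = 60.0 + 70.0 * np.arange(8)
        spikes = np.sort(rng.uniform(0, 600, 9000))
        phase = rng.uniform(-np.pi, np.pi, int(600 * FS))
        mc = mi_change(spikes, FS, phase, onsets)
        assert mc.effect.ci_lo <= 0 <= mc.effect.ci_hi

    def test_locking_onset_detected(self, mi_locked_session):
        mc = mi_locked_session
        assert mc.effect.median > 0
        assert mc.effect.ci_lo > 0
        assert mc.fraction_change > 0


@pytest.fixture(scope="module")
def mi_locked_session():
    from localsleep.synth import (_on_mask, default_trials, generate_lfp,
                                  generate_spike_train)

    dur = 3400.0
    rng = np.random.default_rng(11)
    trials = default_trials(dur, gap_range=(45, 60), rng=rng)
    x, gt = generate_lfp(dur, trials, 2.5, seed=2)
    onm = _on_mask(int(dur * FS), FS, trials)
    train, _ = generate_spike_train(
        dur, 15.0, phase_lock=(1.0, np.pi), phase=gt.delta_phase,
        seed=3, on_mask=onm, off_periods=gt.off_periods)
    dph, _ = delta_phase(x, FS)
    return mi_change(train.spike_times, FS, dph, trials.onsets, 30.0)


class TestCircularKurtosis:
    def test_point_mass_is_one_uniform_near_zero(self):
        assert circular_kurtosis(np.full(50, 1.2)) == pytest.approx(1.0)
        u = np.linspace(-np.pi, np.pi, 1000, endpoint=False)
        assert abs(circular_kurtosis(u)) < 0.01

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(5)
        a = sps.vonmises.rvs(2.0, size=15, random_state=rng)
        r = circular_kurtosis_compare(a, a, n_boot=300, seed=1)
        assert abs(r.diff) < 1e-12
        assert r.boot_ci[0] <= 0 <= r.boot_ci[1]

    def test_tight_vs_uniform_significant(self):
        rng = np.random.default_rng(6)
        tight = sps.vonmises.rvs(8.0, size=15, random_state=rng)
        unif = rng.uniform(-np.pi, np.pi, 15)
        r = circular_kurtosis_compare(tight, unif, n_boot=500, seed=2)
        assert r.diff > 0
        assert r.boot_ci[0] > 0
        assert r.significant

    def test_shuffled_labels_centre_on_zero(self):
        rng = np.random.default_rng(7)
        pool = sps.vonmises.rvs(3.0, size=30, random_state=rng)
        diffs = []
        for _ in range(200):
            perm = rng.permutation(30)
            diffs.append(circular_kurtosis(pool[perm[:15]])
                         - circular_kurtosis(pool[perm[15:]]))
        assert abs(np.mean(diffs)) < 0.05

    def test_group_size_floor(self):
        with pytest.raises(ValueError):
            circular_kurtosis_compare([0.1, 0.2], [0.3, 0.4, 0.5])
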