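"""Population OFF-period detection and its renewal-process null.

Pooled single- and multi-unit spikes are smoothed with a 20 ms-SD Gaussian
kernel (truncated at +/-4 SD) on a 1 ms grid to approximate an instantaneous
firing rate; OFF periods are maximal runs of at least 50 ms where that rate
is zero (below a 1e-9 Hz floor).  The chance level of OFF-period time is
estimated by fitting a gamma distribution to the interspike intervals and
regenerating renewal spike trains with the same spike count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .stats import chi_square_uniformity


@dataclass
class OffPeriod:
    start: float  # s
    end: float  # s

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1000.0

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class OffNullResult:
    observed_pct: float
    null_pcts: np.ndarray
    n_sims: int

    @property
    def null_mean_pct(self) -> float:
        return float(np.mean(self.null_pcts))

    @property
    def null_interval_pct(self) -> tuple:
        lo, hi = np.percentile(self.null_pcts, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def exceeds_null(self) -> bool:
        """True when the observed OFF fraction exceeds the null 97.5th pct."""
        return self.observed_pct > self.null_interval_pct[1]


def smoothed_rate(spike_times, t0: float, t1: float, kernel_sd_ms: float = 20.0,
                  grid_ms: float = 1.0):
    """Gaussian-kernel rate estimate (Hz) on a regular grid over [t0, t1)."""
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    dt = grid_ms / 1000.0
    edges = np.arange(t0, t1 + dt / 2, dt)
    counts, _ = np.histogram(np.asarray(spike_times, dtype=float), bins=edges)
    sd_bins = kernel_sd_ms / grid_ms
    half = int(np.ceil(4 * sd_bins))
    kx = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (kx / sd_bins) ** 2)
    kernel /= kernel.sum() * dt  # rate in Hz
    rate = np.convolve(counts, kernel, mode="same")
    centers = edges[:-1] + dt / 2
    return centers, rate


def detect_off_periods(
    spike_times,
    t0: float,
    t1: float,
    kernel_sd_ms: float = 20.0,
    min_dur_ms: float = 50.0,
    eps_hz: float = 1e-9,
    include_edges: bool = True,
) -> list:
    """OFF periods: maximal runs of zero smoothed rate lasting >= 50 ms.

    Gaps touching the record edges count as OFF periods by default (the
    contract for degenerate inputs); pass ``include_edges=False`` to drop
    them.
    """
    centers, rate = smoothed_rate(spike_times, t0, t1, kernel_sd_ms)
    dt = centers[1] - centers[0] if centers.size > 1 else (t1 - t0)
    off = rate < eps_hz
    periods = []
    i = 0
    n = off.size
    while i < n:
        if off[i]:
            j = i
            while j < n and off[j]:
                j += 1
            start = centers[i] - dt / 2
            end = centers[j - 1] + dt / 2
            touches_edge = i == 0 or j == n
            if (end - start) * 1000.0 >= min_dur_ms and (
                include_edges or not touches_edge
            ):
                periods.append(OffPeriod(start, end))
            i = j
        else:
            i += 1
    return periods


def off_fraction(periods, t0: float, t1: float) -> float:
    """Percent of [t0, t1) spent inside OFF periods."""
    total = sum(p.end - p.start for p in periods)
    return 100.0 * total / (t1 - t0)


def fit_isi_gamma(spike_times):
    """Gamma fit (MLE, location fixed at 0) to interspike intervals.

    Falls back to method of moments when the MLE does not converge.
    """
    isis = np.diff(np.asarray(spike_times, dtype=float))
    isis = isis[isis > 0]
    if isis.size < 1:
        raise ValueError("need at least 2 spikes")
    try:
        shape, _, scale = sps.gamma.fit(isis, floc=0)
        if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0):
            raise RuntimeError
    except Exception:
        m, v = np.mean(isis), np.var(isis)
        shape = m**2 / v if v > 0 else 1.0
        scale = v / m if v > 0 else m
    return float(shape), float(scale)


def off_fraction_null(
    spike_times,
    t0: float,
    t1: float,
    n_sims: int = 1000,
    seed=None,
    kernel_sd_ms: float = 20.0,
    min_dur_ms: float = 50.0,
) -> OffNullResult:
    """Compare the observed OFF fraction against a gamma-renewal null.

    Each simulation draws the same number of spikes as the data from the
    fitted gamma ISI distribution (renewal process starting at t0) and runs
    the identical OFF detector.
    """
    spikes = np.asarray(spike_times, dtype=float)
    if spikes.size < 2:
        raise ValueError("need at least 2 spikes")
    observed = off_fraction(
        detect_off_periods(spikes, t0, t1, kernel_sd_ms, min_dur_ms), t0, t1
    )
    shape, scale = fit_isi_gamma(spikes)
    rng = np.random.default_rng(seed)
    null = np.empty(n_sims)
    n_isi = spikes.size - 1
    for s in range(n_sims):
        isis = rng.gamma(shape, scale, size=n_isi)
        sim = t0 + np.concatenate(([0.0], np.cumsum(isis)))
        null[s] = off_fraction(
            detect_off_periods(sim, t0, t1, kernel_sd_ms, min_dur_ms), t0, t1
        )
    return OffNullResult(observed, null, n_sims)


def off_phase_test(periods, phase_times, phase_values, n_bins: int = 10):
    """Chi-square test of OFF-period midpoint phases against uniformity.

    Midpoint phases are read off the delta-phase series by interpolation
    (circular, via sin/cos components); returns (statistic, dof, p, counts).
    """
    if len(periods) < 1:
        raise ValueError("no OFF periods")
    mids = np.array([p.midpoint for p in periods])
    ph_sin = np.interp(mids, phase_times, np.sin(phase_values))
    ph_cos = np.interp(mids, phase_times, np.cos(phase_values))
    phases = np.arctan2(ph_sin, ph_cos)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    stat, dof, p = chi_square_uniformity(counts)
    return stat, dof, p, counts
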