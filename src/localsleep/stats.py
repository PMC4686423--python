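"""Shared inferential machinery.

Paired effect sizes are reported throughout the pipeline as the
Hodges-Lehmann estimate (median of Walsh averages) with a 95% confidence
interval obtained by inverting the Wilcoxon signed-rank test: exact null
distribution for n <= 25, normal approximation above.  Electrode-count
comparisons use a Monte-Carlo bootstrap on Beta posteriors (uniform prior),
and phase-bin uniformity is tested with Pearson's chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sps


@dataclass
class PairedEffect:
    """Hodges-Lehmann median of paired differences with signed-rank CI."""

    median: float
    ci_lo: float
    ci_hi: float
    n: int
    p: float
    degenerate: bool = False

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_lo, self.ci_hi)

    @property
    def significant(self) -> bool:
        """True when the 95% CI excludes zero."""
        return (self.ci_lo > 0) or (self.ci_hi < 0)


@dataclass
class BetaDiffResult:
    """Monte-Carlo posterior difference of two binomial proportions."""

    k1: int
    n1: int
    k2: int
    n2: int
    median: float
    ci_lo: float
    ci_hi: float
    n_samples: int
    samples: np.ndarray = field(repr=False, default=None)


@lru_cache(maxsize=64)
def _signed_rank_null_cdf(n: int) -> np.ndarray:
    """Exact null PMF counts of the signed-rank statistic W+ for sample size n.

    Counts of subset sums of {1..n}; index w holds #subsets summing to w.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: max_w + 1 - r].copy()
    return counts


def _signed_rank_critical(n: int, alpha: float = 0.05) -> int:
    """Largest k such that P(W+ <= k) <= alpha/2 under the null.

    Returns -1 when even W+=0 exceeds alpha/2 (CI then spans the full range).
    """
    if n <= 25:
        counts = _signed_rank_null_cdf(n)
        cdf = np.cumsum(counts) / counts.sum()
        below = np.nonzero(cdf <= alpha / 2)[0]
        return int(below[-1]) if below.size else -1
    mean = n * (n + 1) / 4
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
    z = sps.norm.ppf(alpha / 2)
    return int(np.floor(mean + z * sd))


def signed_rank_effect(paired_diffs, alpha: float = 0.05) -> PairedEffect:
    """Hodges-Lehmann estimate and CI by signed-rank inversion.

    Parameters
    ----------
    paired_diffs : array-like
        Per-pair differences (e.g. stim minus baseline, one per trial).
    alpha : float
        Two-sided level; the CI is at 1 - alpha.

    Returns
    -------
    PairedEffect
        Median of Walsh averages, CI endpoints, and the signed-rank p-value.
    """
    d = np.asarray(paired_diffs, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need at least 2 paired differences")
    if not np.all(np.isfinite(d)):
        raise ValueError("paired differences must be finite")
    n = d.size
    # Walsh averages (d_i + d_j)/2 for i <= j
    ii, jj = np.triu_indices(n)
    walsh = np.sort((d[ii] + d[jj]) / 2.0)
    median = float(np.median(walsh))
    if np.all(d == d[0]) and d[0] == 0:
        return PairedEffect(0.0, 0.0, 0.0, n, 1.0, degenerate=True)
    k = _signed_rank_critical(n, alpha)
    if k < 0:
        lo, hi = float(walsh[0]), float(walsh[-1])
    else:
        # CI = [w_(k+1), w_(M-k)] in 1-based order statistics
        lo = float(walsh[k])
        hi = float(walsh[walsh.size - 1 - k])
    if np.all(d == 0):
        p = 1.0
    else:
        try:
            p = float(sps.wilcoxon(d, zero_method="wilcox").pvalue)
        except ValueError:  # all zeros after dropping
            p = 1.0
    return PairedEffect(median, lo, hi, n, p)


def binomial_posterior_diff(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    n_samples: int = 1000,
    seed=None,
    prior: str = "uniform",
) -> BetaDiffResult:
    """Monte-Carlo bootstrap for the difference of two binomial proportions.

    Each proportion gets a Beta posterior under the chosen prior
    ("uniform" = Beta(1,1), "jeffreys" = Beta(1/2,1/2)); ``n_samples`` draws
    from each posterior are differenced pairwise and summarized by the median
    and the 2.5th/97.5th percentiles.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n):
            raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    a0, b0 = {"uniform": (1.0, 1.0), "jeffreys": (0.5, 0.5)}[prior]
    rng = np.random.default_rng(seed)
    p1 = rng.beta(k1 + a0, n1 - k1 + b0, size=n_samples)
    p2 = rng.beta(k2 + a0, n2 - k2 + b0, size=n_samples)
    diff = p1 - p2
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return BetaDiffResult(
        k1, n1, k2, n2,
        float(np.median(diff)), float(lo), float(hi), n_samples, diff,
    )


def binomial_proportion_ci(k: int, n: int, alpha: float = 0.05):
    """Proportion k/n with the exact (Clopper-Pearson) confidence interval."""
    if n <= 0 or not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n and n > 0")
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return k / n, (lo, hi)


def chi_square_uniformity(bin_counts):
    """Pearson chi-square of observed bin counts against a uniform expectation.

    Returns (statistic, dof, p) with dof = n_bins - 1.
    """
    counts = np.asarray(bin_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 bins")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    expected = total / counts.size
    statistic = float(np.sum((counts - expected) ** 2 / expected))
    dof = counts.size - 1
    p = float(sps.chi2.sf(statistic, dof))
    return statistic, dof, p


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived by hashing the stage name."""
    import hashlib

    h = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)
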