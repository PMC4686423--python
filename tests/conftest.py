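import numpy as np
import pytest

from localsleep.synth import default_trials, generate_lfp, generate_session

FS = 1000.0


@pytest.fixture(scope="session")
def stim_lfp():
    """~21-trial session-length LFP with a 2.5 dB injected delta effect."""
    rng = np.random.default_rng(42)
    trials = default_trials(1800.0, gap_range=(45.0, 60.0), rng=rng)
    x, gt = generate_lfp(1800.0, trials, 2.5, seed=7)
    return x, gt, trials


@pytest.fixture(scope="session")
def strong_lfp():
    """Strong-effect (6 dB) session for slow-wave detector recovery."""
    rng = np.random.default_rng(9)
    trials = default_trials(1800.0, gap_range=(45.0, 60.0), rng=rng)
    x, gt = generate_lfp(1800.0, trials, 6.0, seed=3)
    return x, gt, trials


@pytest.fixture(scope="session")
def small_session():
    """Two-trial synthetic session (smoke-test scale)."""
    return generate_session("awake-stim", duration_s=260.0, seed=0)
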