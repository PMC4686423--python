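"""Recover an injected delta-band power change with multitaper statistics.

Per trial, the 30 s pre-stimulus and stimulation windows are compared as
19-taper multitaper band powers in dB; the effect is the Hodges-Lehmann
median with a signed-rank-inversion 95% CI.
"""

import numpy as np

from localsleep import band_power_change
from localsleep.synth import default_trials, generate_lfp

fs = 1000.0
rng = np.random.default_rng(3)
trials = default_trials(1400.0, gap_range=(45.0, 60.0), rng=rng)
lfp, truth = generate_lfp(1400.0, trials, delta_effect_db=2.5, seed=4)

eff = band_power_change(lfp, fs, trials.onsets, band=(1.0, 4.0))
print(f"injected: 2.50 dB over {trials.n_trials} trials")
print(f"recovered: {eff.median_change_db:.2f} dB "
      f"(95% CI [{eff.ci_db[0]:.2f}, {eff.ci_db[1]:.2f}])")
# The recovered median should sit within a few tenths of a dB of the
# injected effect; the CI width reflects trial-to-trial background
# fluctuations in 1-4 Hz power.
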