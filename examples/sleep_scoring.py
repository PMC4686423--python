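"""Semi-automated sleep scoring on a synthetic wake/NREM/REM session.

Wake = sustained (>= 5 s) supra-threshold 60-200 Hz EMG amplitude;
remaining time splits into NREM vs REM by the smoothed <4 Hz : 4-16 Hz
EEG power ratio.  Thresholds are auto-suggested here; in practice they
are entered manually while blind to the laser times.
"""

import numpy as np

from localsleep import score_sleep
from localsleep.synth import generate_state_session

epochs = [("wake", 150), ("nrem", 300), ("rem", 60), ("wake", 90),
          ("nrem", 200)]
eeg, emg, truth, _ = generate_state_session(epochs, seed=9)
labels = score_sleep(eeg, emg, fs=1000.0)

agree = np.mean(labels.states[: truth.size] == truth)
print(f"EMG threshold {labels.emg_threshold:.2f} uV, "
      f"EEG ratio threshold {labels.ratio_threshold:.2f}")
print(f"occupancy: {labels.occupancy()}")
print(f"agreement with ground truth: {agree:.1%}")
# Agreement >= 90% shows the scorer separates states from the raw traces;
# disagreements cluster at epoch boundaries where the smoothing blurs
# transitions.
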