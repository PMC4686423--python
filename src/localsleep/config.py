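"""Analysis configuration: every tunable the pipeline uses, with the
study's published values as defaults, round-trippable to YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # frequency bands, Hz
    delta_band: tuple = (1.0, 4.0)
    beta_gamma_band: tuple = (15.0, 50.0)  # figure-caption variant: (12, 50)
    spindle_band: tuple = (9.0, 15.0)
    high_gamma_band: tuple = (70.0, 100.0)
    broadband: tuple = (0.5, 50.0)
    norm_broadband: tuple = (0.0, 50.0)  # denominator of normalized delta
    # multitaper settings (K = 2*NW - 1)
    spectrum_window_s: float = 30.0
    spectrum_tapers: int = 19
    specgram_window_s: float = 5.0
    specgram_tapers: int = 5
    specgram_step_s: float = 1.0
    # slow-wave detector
    sw_band: tuple = (0.1, 5.0)
    sw_min_trough_uv: float = 100.0
    sw_top_pct: float = 3.0
    sw_artifact_sd_uv: float = 2000.0
    # OFF periods
    off_kernel_sd_ms: float = 20.0
    off_min_dur_ms: float = 50.0
    off_null_sims: int = 1000
    off_phase_bins: int = 10
    # phase locking
    mi_spike_bins: int = 10
    mi_gamma_bins: int = 100
    plv_permutations: int = 500
    plv_bootstraps: int = 500
    # units / GLM
    narrow_wide_us: float = 200.0
    glm_lags: int = 50
    glm_bin_ms: float = 2.0
    onset_bootstraps: int = 1000
    onset_alpha: float = 0.005
    # behavior
    emg_band: tuple = (10.0, 200.0)
    emg_score_band: tuple = (60.0, 200.0)
    eeg_ratio_smooth_s: float = 1.0
    min_wake_s: float = 5.0
    kurtosis_bootstraps: int = 1000
    eeg_emg_bootstraps: int = 1000
    onset_shuffles: int = 400
    # reproducibility
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = {f.name: _plain(getattr(self, f.name)) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        for f in fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def _plain(v):
    return list(v) if isinstance(v, tuple) else v
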