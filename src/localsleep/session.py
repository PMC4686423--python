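"""Session data model and the language-neutral on-disk directory format.

A session directory holds a JSON manifest plus raw little-endian float32
binaries for each trace and CSV tables for spikes, trials, and state
labels.  All times are seconds (float64), voltages microvolts, sample
indexing 0-based, and intervals half-open [start, end).  Traces are stored
(and held in memory) as float32, so write -> read round-trips are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MANIFEST = "manifest.json"


class SessionFormatError(ValueError):
    pass


@dataclass
class SpikeTrain:
    unit_id: str
    spike_times: np.ndarray  # s, strictly increasing
    peak_to_trough_us: float
    region: str = "cortex"  # cortex | subcortical
    quality: str = "single"  # single | multi

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise SessionFormatError(
                f"spike times of {self.unit_id} not strictly increasing"
            )
        if self.peak_to_trough_us <= 0:
            raise SessionFormatError("peak_to_trough_us must be positive")
        if self.region not in ("cortex", "subcortical"):
            raise SessionFormatError(f"unknown region {self.region!r}")
        if self.quality not in ("single", "multi"):
            raise SessionFormatError(f"unknown quality {self.quality!r}")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class TrialSet:
    onsets: np.ndarray  # s
    offsets: np.ndarray  # s
    power_mw: np.ndarray
    stim_duration: float  # s (30 or 5 in the study)

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.power_mw = np.asarray(self.power_mw, dtype=float)
        if not (self.onsets.size == self.offsets.size == self.power_mw.size):
            raise SessionFormatError("trial columns differ in length")
        if np.any(self.offsets <= self.onsets):
            raise SessionFormatError("trial offsets must exceed onsets")
        if self.onsets.size > 1:
            gaps = self.onsets[1:] - self.offsets[:-1]
            if np.any(gaps < self.stim_duration - 1e-9):
                raise SessionFormatError(
                    "inter-trial gap shorter than the stimulation duration"
                )

    @property
    def n_trials(self) -> int:
        return self.onsets.size


@dataclass
class Session:
    lfp: np.ndarray  # (channels, samples) uV
    fs_lfp: float
    eeg: np.ndarray  # (samples,) uV
    fs_eeg: float
    emg: np.ndarray  # (samples,) uV
    fs_emg: float
    spikes: list
    trials: TrialSet
    channel_meta: list  # per channel: {"tag": str, "x": float, "y": float}
    state_labels: np.ndarray = None  # per-second state strings
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lfp = np.atleast_2d(np.asarray(self.lfp, dtype=np.float32))
        self.eeg = np.asarray(self.eeg, dtype=np.float32)
        self.emg = np.asarray(self.emg, dtype=np.float32)
        if self.fs_lfp < 200.0:
            raise SessionFormatError(
                "fs_lfp must be >= 200 Hz for 70-100 Hz analyses"
            )
        if len(self.channel_meta) != self.lfp.shape[0]:
            raise SessionFormatError("channel_meta length != n_channels")
        dur = self.duration_s
        if self.trials.n_trials and self.trials.offsets.max() > dur + 1e-6:
            raise SessionFormatError("trials extend past the record")
        if self.state_labels is not None:
            self.state_labels = np.asarray(self.state_labels, dtype=str)

    @property
    def duration_s(self) -> float:
        return self.lfp.shape[1] / self.fs_lfp

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]


def write_session(session: Session, path) -> Path:
    """Write a Session to a directory (manifest + .bin traces + CSV tables)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "fs_lfp": session.fs_lfp,
        "fs_eeg": session.fs_eeg,
        "fs_emg": session.fs_emg,
        "n_channels": session.n_channels,
        "n_samples_lfp": int(session.lfp.shape[1]),
        "n_samples_eeg": int(session.eeg.size),
        "n_samples_emg": int(session.emg.size),
        "stim_duration": session.trials.stim_duration,
        "channel_meta": session.channel_meta,
        "has_states": session.state_labels is not None,
        "has_ground_truth": bool(session.ground_truth),
    }
    (path / MANIFEST).write_text(json.dumps(manifest, indent=1))
    session.lfp.astype("<f4").tofile(path / "lfp.bin")
    session.eeg.astype("<f4").tofile(path / "eeg.bin")
    session.emg.astype("<f4").tofile(path / "emg.bin")
    rows = []
    for tr in session.spikes:
        for t in tr.spike_times:
            rows.append((tr.unit_id, t, tr.peak_to_trough_us, tr.region,
                         tr.quality))
    pd.DataFrame(
        rows, columns=["unit_id", "time_s", "peak_to_trough_us", "region",
                       "quality"]
    ).to_csv(path / "spikes.csv", index=False, float_format="%.17g")
    pd.DataFrame(
        {"onset_s": session.trials.onsets, "offset_s": session.trials.offsets,
         "power_mw": session.trials.power_mw}
    ).to_csv(path / "trials.csv", index=False, float_format="%.17g")
    if session.state_labels is not None:
        pd.DataFrame(
            {"second": np.arange(session.state_labels.size),
             "state": session.state_labels}
        ).to_csv(path / "states.csv", index=False)
    if session.ground_truth:
        (path / "ground_truth.json").write_text(
            json.dumps(session.ground_truth, default=_jsonable)
        )
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _read_trace(path: Path, name: str, n_expected: int):
    f = path / name
    if not f.exists():
        raise SessionFormatError(f"missing component: {name}")
    data = np.fromfile(f, dtype="<f4")
    if data.size != n_expected:
        raise SessionFormatError(
            f"inconsistent manifest: {name} has {data.size} samples, "
            f"manifest says {n_expected}"
        )
    return data


def read_session(path) -> Session:
    """Read and validate a session directory written by write_session."""
    path = Path(path)
    mf = path / MANIFEST
    if not mf.exists():
        raise SessionFormatError("missing component: manifest.json")
    try:
        manifest = json.loads(mf.read_text())
    except json.JSONDecodeError as e:
        raise SessionFormatError(f"inconsistent manifest: bad JSON ({e})")
    for key in ("fs_lfp", "n_channels", "n_samples_lfp"):
        if key not in manifest:
            raise SessionFormatError(f"inconsistent manifest: missing {key}")
    n_ch = int(manifest["n_channels"])
    lfp = _read_trace(path, "lfp.bin", n_ch * int(manifest["n_samples_lfp"]))
    lfp = lfp.reshape(n_ch, -1)
    eeg = _read_trace(path, "eeg.bin", int(manifest["n_samples_eeg"]))
    emg = _read_trace(path, "emg.bin", int(manifest["n_samples_emg"]))
    sp_f = path / "spikes.csv"
    if not sp_f.exists():
        raise SessionFormatError("missing component: spikes.csv")
    sp = pd.read_csv(sp_f, float_precision="round_trip")
    spikes = []
    for uid, grp in sp.groupby("unit_id", sort=True):
        spikes.append(
            SpikeTrain(
                str(uid),
                grp["time_s"].to_numpy(),
                float(grp["peak_to_trough_us"].iloc[0]),
                str(grp["region"].iloc[0]),
                str(grp["quality"].iloc[0]),
            )
        )
    tr_f = path / "trials.csv"
    if not tr_f.exists():
        raise SessionFormatError("missing component: trials.csv")
    tr = pd.read_csv(tr_f, float_precision="round_trip")
    trials = TrialSet(
        tr["onset_s"].to_numpy(), tr["offset_s"].to_numpy(),
        tr["power_mw"].to_numpy(), float(manifest.get("stim_duration", 30.0)),
    )
    states = None
    if manifest.get("has_states") and (path / "states.csv").exists():
        states = pd.read_csv(path / "states.csv")["state"].to_numpy(dtype=str)
    gt = {}
    if manifest.get("has_ground_truth") and (path / "ground_truth.json").exists():
        gt = json.loads((path / "ground_truth.json").read_text())
    return Session(
        lfp=lfp, fs_lfp=float(manifest["fs_lfp"]),
        eeg=eeg, fs_eeg=float(manifest["fs_eeg"]),
        emg=emg, fs_emg=float(manifest["fs_emg"]),
        spikes=spikes, trials=trials,
        channel_meta=manifest["channel_meta"], state_labels=states,
        ground_truth=gt,
    )
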