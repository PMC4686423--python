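"""End-to-end orchestration of all analysis stages on one session.

Each stage derives its own seed from the config's global seed by stable
hashing of the stage name, so re-running with the same config and session
is bit-reproducible, and editing one stage leaves the others' draws
untouched.  Stage failures are logged and the remaining stages still run;
their outputs are preserved and a PipelineError listing the failures is
raised at the end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import behavior, light, offperiods, phase, slowwaves, spectral, units
from .config import AnalysisConfig
from .session import Session, _jsonable
from .stats import derive_seed, signed_rank_effect

log = logging.getLogger("localsleep")


class PipelineError(RuntimeError):
    pass


@dataclass
class ReportBundle:
    out_dir: Path
    stats: dict
    errors: list = field(default_factory=list)


def _summarize(diffs) -> dict:
    """Signed-rank summary when >= 6 pairs, plain median otherwise."""
    diffs = np.asarray(diffs, dtype=float)
    out = {"n": int(diffs.size), "per_trial": diffs.tolist()}
    if diffs.size >= 6:
        eff = signed_rank_effect(diffs)
        out.update(median=eff.median, ci=[eff.ci_lo, eff.ci_hi], p=eff.p)
    elif diffs.size:
        out.update(median=float(np.median(diffs)), ci=None, p=None)
    return out


def _stage_spectral(cfg: AnalysisConfig, s: Session, out: Path) -> dict:
    res = {"channels": []}
    onsets = s.trials.onsets
    dur = s.trials.stim_duration
    for ch in range(s.n_channels):
        x = s.lfp[ch].astype(float)
        entry = {"channel": ch, "tag": s.channel_meta[ch].get("tag", "")}
        for name, band in (("delta", cfg.delta_band),
                           ("spindle", cfg.spindle_band),
                           ("beta_gamma", cfg.beta_gamma_band)):
            pre, stim = spectral._paired_band_powers_db(
                x, s.fs_lfp, onsets, band, dur, cfg.spectrum_tapers
            )
            entry[name] = _summarize(stim - pre)
        res["channels"].append(entry)
    if len(onsets) >= 6:
        emap = spectral.delta_effect_map(
            s.lfp.astype(float), s.fs_lfp, onsets, cfg.delta_band,
            cfg.norm_broadband, window_s=dur, k=cfg.spectrum_tapers,
        )
        res["delta_effect_map"] = [vars(e) for e in emap]
        import pandas as pd

        pd.DataFrame(
            [(e.channel, e.change_db, e.significant_bonferroni,
              e.delta_effect_flag) for e in emap],
            columns=["channel", "change_db", "significant_a", "significant_b"],
        ).to_csv(out / "channel_map.csv", index=False)
    return res


def _stage_events(cfg: AnalysisConfig, s: Session, out: Path) -> dict:
    import pandas as pd

    res = {"channels": []}
    for ch in range(s.n_channels):
        evs = slowwaves.detect_slow_waves(
            s.lfp[ch].astype(float), s.fs_lfp, cfg.sw_band,
            cfg.sw_min_trough_uv, cfg.sw_top_pct, cfg.sw_artifact_sd_uv,
        )
        pd.DataFrame(
            [(e.trough_time, e.trough_amp, e.next_peak_time, e.peak_amp,
              e.peak_to_peak, e.session_percentile) for e in evs],
            columns=["trough_time_s", "trough_uv", "peak_time_s", "peak_uv",
                     "p2p_uv", "percentile"],
        ).to_csv(out / f"events_ch{ch}.csv", index=False)
        times = np.array([e.trough_time for e in evs])
        on_r, pre_r = slowwaves._per_trial_rates(
            times, s.trials.onsets, s.trials.stim_duration
        )
        res["channels"].append(
            {"channel": ch, "n_events": len(evs),
             "rate_change_per_s": _summarize(on_r - pre_r)}
        )
    return res


def _pooled_spikes(s: Session):
    if not s.spikes:
        return np.array([])
    return np.sort(np.concatenate([t.spike_times for t in s.spikes]))


def _stage_off(cfg: AnalysisConfig, s: Session, out: Path, seed: int) -> dict:
    import pandas as pd

    pooled = _pooled_spikes(s)
    if pooled.size < 2:
        return {"skipped": "no spikes"}
    t0, t1 = 0.0, s.duration_s
    offs = offperiods.detect_off_periods(
        pooled, t0, t1, cfg.off_kernel_sd_ms, cfg.off_min_dur_ms
    )
    dphase, _ = phase.delta_phase(s.lfp[0].astype(float), s.fs_lfp,
                                  cfg.delta_band)
    tgrid = np.arange(dphase.size) / s.fs_lfp
    rows, phases = [], []
    for p in offs:
        ph = phase.phases_at([p.midpoint], s.fs_lfp, dphase)[0]
        phases.append(ph)
        rows.append((p.start, p.end, p.duration_ms, ph))
    pd.DataFrame(
        rows, columns=["start_s", "end_s", "duration_ms", "phase_rad"]
    ).to_csv(out / "off_periods.csv", index=False)
    res = {
        "n_off": len(offs),
        "fraction_pct": offperiods.off_fraction(offs, t0, t1),
    }
    null = offperiods.off_fraction_null(
        pooled, t0, t1, cfg.off_null_sims, seed,
        cfg.off_kernel_sd_ms, cfg.off_min_dur_ms,
    )
    res["null"] = {
        "observed_pct": null.observed_pct,
        "null_mean_pct": null.null_mean_pct,
        "null_interval_pct": list(null.null_interval_pct),
        "exceeds_null": null.exceeds_null,
    }
    if len(offs) >= 20:
        stat, dof, p, _ = offperiods.off_phase_test(
            offs, tgrid, dphase, cfg.off_phase_bins
        )
        res["phase_uniformity"] = {"chi2": stat, "dof": dof, "p": p}
    # paired ON vs pre fraction change
    diffs = []
    for onset in s.trials.onsets:
        d = s.trials.stim_duration
        on_f = offperiods.off_fraction(
            [p for p in offs if p.midpoint >= onset and p.midpoint < onset + d],
            onset, onset + d)
        pre_f = offperiods.off_fraction(
            [p for p in offs if p.midpoint >= onset - d and p.midpoint < onset],
            onset - d, onset)
        diffs.append(on_f - pre_f)
    res["fraction_change_pct"] = _summarize(diffs)
    return res


def _stage_phase(cfg: AnalysisConfig, s: Session, out: Path, seed: int) -> dict:
    res = {"units": [], "plv": []}
    dphase, valid = phase.delta_phase(s.lfp[0].astype(float), s.fs_lfp,
                                      cfg.delta_band)
    onsets = s.trials.onsets
    dur = s.trials.stim_duration
    for tr in s.spikes:
        entry = {"unit_id": tr.unit_id}
        try:
            mc = phase.mi_change(tr.spike_times, s.fs_lfp, dphase, onsets,
                                 dur, cfg.mi_spike_bins)
            entry.update(
                mi_pre=mc.mi_pre, mi_on=mc.mi_on,
                delta_mi=mc.effect.median,
                ci=[mc.effect.ci_lo, mc.effect.ci_hi],
                fraction_change=mc.fraction_change,
            )
        except ValueError as e:
            sp = tr.spike_times
            ph = phase.phases_at(sp, s.fs_lfp, dphase)
            pre = np.concatenate([
                ph[(sp >= o - dur) & (sp < o)] for o in onsets])
            on = np.concatenate([
                ph[(sp >= o) & (sp < o + dur)] for o in onsets])
            if pre.size and on.size:
                mi_pre = phase.spike_phase_mi(pre, cfg.mi_spike_bins, 1).mi_bits
                mi_on = phase.spike_phase_mi(on, cfg.mi_spike_bins, 1).mi_bits
                entry.update(mi_pre=mi_pre, mi_on=mi_on,
                             delta_mi=mi_on - mi_pre, ci=None,
                             note=str(e))
            else:
                entry["note"] = str(e)
        res["units"].append(entry)
    if s.n_channels > 1 and len(onsets) >= 6:
        windows = [(int(o * s.fs_lfp), int((o + dur) * s.fs_lfp))
                   for o in onsets]
        for ch in range(1, s.n_channels):
            ph_b, _ = phase.delta_phase(s.lfp[ch].astype(float), s.fs_lfp,
                                        cfg.delta_band)
            r = phase.plv(dphase, ph_b, windows, cfg.plv_permutations,
                          cfg.plv_bootstraps, derive_seed(seed, f"plv{ch}"))
            res["plv"].append({"channel": ch, "plv": r.plv,
                               "offset_rad": r.offset, "p": r.p})
    gm = phase.gamma_power_mi(s.lfp[0].astype(float), s.fs_lfp,
                              cfg.high_gamma_band, cfg.delta_band,
                              cfg.mi_gamma_bins, phase=dphase)
    res["gamma_mi"] = {"mi_bits": gm.mi_bits,
                       "preferred_phase": gm.preferred_phase}
    (out / "phase_stats.json").write_text(
        json.dumps(res, sort_keys=True, default=_jsonable))
    return res


def _stage_units(cfg: AnalysisConfig, s: Session, out: Path, seed: int) -> dict:
    import pandas as pd

    res = {"units": []}
    onsets = s.trials.onsets
    dur = s.trials.stim_duration
    glm_rows = []
    for tr in s.spikes:
        entry = {
            "unit_id": tr.unit_id,
            "class": units.classify_unit(tr.peak_to_trough_us),
        }
        entry["rate_change_hz"] = _summarize([
            (np.sum((tr.spike_times >= o) & (tr.spike_times < o + dur))
             - np.sum((tr.spike_times >= o - dur) & (tr.spike_times < o)))
            / dur for o in onsets])
        base_w = [(o - dur, o) for o in onsets]
        stim_w = [(o, o + dur) for o in onsets]
        try:
            fb = units.fit_history_glm(tr.spike_times, base_w, "baseline",
                                       tr.unit_id)
            fs_ = units.fit_history_glm(tr.spike_times, stim_w, "stim",
                                        tr.unit_id)
            cmp_ = units.compare_history_2_4ms(fb, fs_)
            entry["history_2_4ms"] = cmp_
            for cond, f in (("baseline", fb), ("stim", fs_)):
                for i in range(units.N_LAGS):
                    glm_rows.append((tr.unit_id, cond, (i + 1) * 2.0,
                                     f.coef[i], f.ci_lo[i], f.ci_hi[i]))
        except ValueError as e:
            entry["history_2_4ms"] = {"note": str(e)}
        res["units"].append(entry)
    pd.DataFrame(
        glm_rows,
        columns=["unit_id", "condition", "lag_ms", "coef", "ci_lo", "ci_hi"],
    ).to_csv(out / "glm.csv", index=False)
    pd.DataFrame(
        [(u["unit_id"], u["class"], u["rate_change_hz"].get("median"))
         for u in res["units"]],
        columns=["unit_id", "class", "delta_rate"],
    ).to_csv(out / "units.csv", index=False)
    return res


def _stage_score(cfg: AnalysisConfig, s: Session, out: Path) -> dict:
    import pandas as pd

    labels = behavior.score_sleep(s.eeg.astype(float), s.emg.astype(float),
                                  s.fs_eeg, min_wake_s=cfg.min_wake_s)
    pd.DataFrame(
        {"second": np.arange(labels.states.size), "state": labels.states}
    ).to_csv(out / "states.csv", index=False)
    res = {
        "occupancy_pct": labels.occupancy(),
        "quality_ok": labels.quality_ok,
        "emg_threshold": labels.emg_threshold,
        "ratio_threshold": labels.ratio_threshold,
    }
    res["emg_power_change_db"] = _summarize([
        d for d in _emg_diffs(cfg, s)])
    occ = behavior.state_occupancy_change(labels, s.trials.onsets,
                                          s.trials.stim_duration) \
        if len(s.trials.onsets) >= 6 else None
    if occ:
        res["occupancy_change_pp"] = {
            st: {"median": e.median, "ci": [e.ci_lo, e.ci_hi]}
            for st, e in occ.items()
        }
    return res


def _emg_diffs(cfg, s):
    t, p = behavior.emg_band_power(s.emg.astype(float), s.fs_emg, cfg.emg_band)
    dur = s.trials.stim_duration
    for onset in s.trials.onsets:
        on = (t >= onset) & (t < onset + dur)
        pre = (t >= onset - dur) & (t < onset)
        yield 10 * np.log10(p[on].sum() / p[pre].sum())


def _stage_light(cfg: AnalysisConfig, s: Session, out: Path) -> dict:
    power = float(np.median(s.trials.power_mw)) if s.trials.n_trials else 1.0
    fiber = light.FiberSpec(power_mw=power)
    tissue = light.TISSUE_PRESETS["paper"]
    prof = light.irradiance_profile(fiber, tissue, z_max_mm=2.0)
    import pandas as pd

    pd.DataFrame({"depth_mm": prof.depth_mm,
                  "irradiance_mw_mm2": prof.irradiance_mw_mm2}
                 ).to_csv(out / "irradiance.csv", index=False)
    return {
        "power_mw": power,
        "depth_at_1mw_mm2": light.stimulated_depth(fiber, tissue, 1.0),
    }


def _stage_figures(cfg: AnalysisConfig, s: Session, out: Path) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    times, freqs, mat = spectral.normalized_spectrogram(
        s.lfp[0].astype(float), s.fs_lfp, s.trials.onsets,
        cfg.specgram_window_s, cfg.specgram_tapers, cfg.specgram_step_s,
        pre_s=s.trials.stim_duration, post_s=s.trials.stim_duration,
    )
    fig, ax = plt.subplots(figsize=(6, 3))
    sel = freqs <= 50
    im = ax.pcolormesh(times, freqs[sel], mat[sel], shading="auto",
                       cmap="RdBu_r", vmin=-5, vmax=5)
    fig.colorbar(im, ax=ax, label="dB re: pre")
    ax.set(xlabel="time from laser onset (s)", ylabel="frequency (Hz)")
    fig.savefig(out / "spectrogram.png", dpi=110)
    plt.close(fig)
    return {"figures": ["spectrogram.png"]}


def run_pipeline(config: AnalysisConfig, session: Session, out_dir) -> ReportBundle:
    """Run every analysis stage on a session and write outputs to out_dir.

    Raises ValueError("no trials") for a session without laser trials and
    PipelineError at the end if any stage failed (partial outputs remain).
    """
    if session.trials.n_trials == 0:
        raise ValueError("no trials")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stats: dict = {}
    errors = []
    stages = [
        ("spectral", lambda: _stage_spectral(config, session, out)),
        ("events", lambda: _stage_events(config, session, out)),
        ("off", lambda: _stage_off(config, session, out,
                                   derive_seed(config.seed, "off"))),
        ("phase", lambda: _stage_phase(config, session, out,
                                       derive_seed(config.seed, "phase"))),
        ("units", lambda: _stage_units(config, session, out,
                                       derive_seed(config.seed, "units"))),
        ("score", lambda: _stage_score(config, session, out)),
        ("light", lambda: _stage_light(config, session, out)),
        ("figures", lambda: _stage_figures(config, session, out)),
    ]
    for name, fn in stages:
        try:
            stats[name] = fn()
        except Exception as e:  # noqa: BLE001 - stage isolation is the point
            log.exception("stage %s failed", name)
            errors.append((name, repr(e)))
            stats[name] = {"error": repr(e)}
    (out / "statistics.json").write_text(
        json.dumps(stats, sort_keys=True, indent=1, default=_jsonable)
    )
    if errors:
        raise PipelineError(
            "; ".join(f"{n}: {m}" for n, m in errors)
        )
    return ReportBundle(out, stats, errors)
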