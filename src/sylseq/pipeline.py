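"""End-to-end orchestration, flat-file configuration, and logging.

Three modes:

* ``synthetic-audio`` — schedule → synthetic trial audio → segmentation →
  ISI extraction → length/practice models, with a ground-truth comparison
  appendix (landmark deviations per trial);
* ``synthetic-chronometric`` — group presets → ISI/error simulation →
  mixed models and the two-group interaction model (a parameter-recovery
  report);
* ``external-audio`` — user WAV files + manifest → F1 calibration →
  segmentation → ISI tables and models.

Every random draw derives from the single config seed.  Exclusion
bookkeeping mirrors the study design: error trials are dropped from ISI
tables; ambiguous-release (double-release) trials are dropped from both
the chronometric and the error tabulations, with counts reported.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import chron_sim, error_coding, landmarks, stats, stimuli, synth_audio
from .landmarks import DEFAULT_CONFIG, F1Range, LandmarkConfig

log = logging.getLogger("sylseq")


@dataclass
class RunConfig:
    """Flat, serialisable run configuration (key = value text format)."""

    seed: int = 1
    sample_rate: int = 22050
    n_speakers: int = 1
    trials_per_speaker: int = 30          # synthetic-audio mode subset
    noise_snr_db: float | None = None
    f1_min: float | None = None           # None -> calibrate from audio
    f1_max: float | None = None
    landmark: LandmarkConfig = field(default_factory=LandmarkConfig)
    wav_dir: str = ""
    manifest: str = ""
    out_dir: str = "sylseq_out"
    verbose: bool = False

    def to_text(self) -> str:
        lines = []
        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            if f_.name == "landmark":
                for lf in dataclasses.fields(LandmarkConfig):
                    lv = getattr(v, lf.name)
                    if isinstance(lv, dict):
                        for k, val in lv.items():
                            lines.append(f"landmark.{lf.name}.{k} = {val}")
                    elif isinstance(lv, tuple):
                        lines.append(f"landmark.{lf.name} = {','.join(map(str, lv))}")
                    else:
                        lines.append(f"landmark.{lf.name} = {lv}")
            else:
                lines.append(f"{f_.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        cfg = cls()
        lm: dict = {f_.name: getattr(cfg.landmark, f_.name)
                    for f_ in dataclasses.fields(LandmarkConfig)}
        lm["hop_ms"] = dict(lm["hop_ms"])
        lm["sigma_ms"] = dict(lm["sigma_ms"])
        for raw in text.splitlines():
            raw = raw.split("#")[0].strip()
            if not raw or "=" not in raw:
                continue
            key, val = (s.strip() for s in raw.split("=", 1))
            if key.startswith("landmark."):
                parts = key.split(".")
                if len(parts) == 3:
                    lm[parts[1]][parts[2]] = float(val)
                elif parts[1] == "nasal_band":
                    lm[parts[1]] = tuple(float(x) for x in val.split(","))
                elif parts[1] == "filter_order":
                    lm[parts[1]] = int(val)
                else:
                    lm[parts[1]] = float(val)
            elif key in ("seed", "sample_rate", "n_speakers", "trials_per_speaker"):
                setattr(cfg, key, int(val))
            elif key in ("noise_snr_db", "f1_min", "f1_max"):
                setattr(cfg, key, None if val == "None" else float(val))
            elif key == "verbose":
                cfg.verbose = val in ("True", "true", "1")
            elif key in ("wav_dir", "manifest", "out_dir"):
                setattr(cfg, key, val)
        cfg.landmark = LandmarkConfig(**lm)
        return cfg


class PipelineError(RuntimeError):
    pass


def _segment_trials(trial_audio, config: RunConfig, f1: F1Range):
    """Segment a list of (trial, TrialAudio); returns landmark rows, ISI rows
    and exclusion counts."""
    lm_rows, isi_rows = [], []
    n_flagged = 0
    deviations = []
    for t, ta in trial_audio:
        ref = f"r{t.run}t{t.trial}"
        ls = landmarks.segment_trial(ta.waveform, t.stimulus, f1, config.landmark)
        if config.verbose or ls.qc_flags:
            log.info("trial %s flags=%s audit=%s", ref, ls.qc_flags, ls.audit)
        if ls.qc_flags:
            n_flagged += 1
            lm_rows.append({"trial": ref, "syllable": "",
                            "flags": ";".join(f"{fl[0]}({fl[1]})" for fl in ls.qc_flags)})
            continue
        isis = landmarks.compute_isis(ls, ref)
        for k in range(ls.n):
            lm_rows.append({
                "trial": ref, "syllable": k + 1,
                "cOn_ms": round(ls.c_on[k], 3), "vOn_ms": round(ls.v_on[k], 3),
                "vOff_ms": round(ls.v_off[k], 3),
                "isi_ms": round(isis[k].isi_ms, 3) if k < len(isis) else "",
                "flags": "",
            })
        if ta.truth is not None:
            dev = np.abs(np.array(ls.c_on) - np.array(ta.truth.c_on))
            deviations.extend(dev.tolist())
        for rec in isis:
            isi_rows.append({"speaker": "spk", "run": t.run, "length": t.stimulus.n,
                             "trial": t.trial, "position": rec.position,
                             "isi_ms": rec.isi_ms})
    return lm_rows, isi_rows, n_flagged, deviations


def run_pipeline(config: RunConfig, mode: str) -> dict:
    """Run one of the three pipeline modes; returns the report bundle and
    writes tables under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO if config.verbose else logging.WARNING)
    if mode == "synthetic-chronometric":
        return _run_chronometric(config, out)
    if mode == "synthetic-audio":
        return _run_synthetic_audio(config, out)
    if mode == "external-audio":
        return _run_external_audio(config, out)
    raise PipelineError(f"unknown mode {mode!r}")


def _run_chronometric(config: RunConfig, out: Path) -> dict:
    presets = chron_sim.default_presets()
    sched = stimuli.build_schedule(config.seed)
    report: dict = {"mode": "synthetic-chronometric", "seed": config.seed, "fits": {}}
    frames_isi, frames_err = {}, {}
    rng = np.random.default_rng(config.seed)
    for name, preset in presets.items():
        s1, s2 = rng.integers(2**31, size=2)
        frames_isi[name] = chron_sim.simulate_isis(preset, sched, int(s1))
        frames_err[name] = chron_sim.simulate_errors(preset, sched, int(s2))
        isi_len = stats.fit_length_model(
            chron_sim.speaker_means(frames_isi[name], "length", "isi_ms"), "isi")
        isi_run = stats.fit_practice_model(
            chron_sim.speaker_means(frames_isi[name], "run", "isi_ms"), "isi")
        err_len = stats.fit_length_model(
            chron_sim.speaker_error_rates(frames_err[name], "length"), "pctErr")
        err_run = stats.fit_practice_model(
            chron_sim.speaker_error_rates(frames_err[name], "run"), "pctErr")
        report["fits"][name] = {
            "isi_length_slope": isi_len.slope, "isi_run_slope": isi_run.slope,
            "err_length_slope": err_len.slope, "err_run_slope": err_run.slope,
            "generative": {"isi_length": preset.length_slope_isi,
                           "isi_run": preset.run_slope_isi,
                           "err_length": preset.length_slope_err * 100,
                           "err_run": preset.run_slope_err * 100},
        }
        chron_sim.write_long_table(frames_isi[name], out / f"isi_{name}.tsv")
        chron_sim.write_long_table(frames_err[name], out / f"errors_{name}.tsv")
    both = pd.concat([chron_sim.speaker_means(frames_isi["healthy"], "length", "isi_ms"),
                      chron_sim.speaker_means(frames_isi["hypokinetic"], "length", "isi_ms")])
    inter = stats.fit_interaction_model(both, "length")
    report["fits"]["interaction_healthy_hypokinetic"] = {
        "length_slope_difference": inter.interaction,
        "p": inter.p_interaction,
    }
    gm = chron_sim.simulate_group_means_isi(presets, int(rng.integers(2**31)))
    gc = stats.compare_groups(gm, "isi")
    report["group_comparison"] = {
        "test": gc.used_test, "post_hoc": gc.post_hoc,
        "bonferroni_alpha": gc.bonferroni_alpha,
    }
    (out / "report.txt").write_text(_format_report(report))
    return report


def _make_session_audio(config: RunConfig, sched, profile, n_trials: int):
    pairs = []
    rng = np.random.default_rng(config.seed + 17)
    for t in sched.trials[:n_trials]:
        ta = synth_audio.synth_sequence(t.stimulus, profile,
                                        sample_rate=config.sample_rate,
                                        seed=int(rng.integers(2**31)))
        if config.noise_snr_db is not None:
            ta = synth_audio.add_noise(ta, config.noise_snr_db,
                                       int(rng.integers(2**31)))
        pairs.append((t, ta))
    return pairs


def _run_synthetic_audio(config: RunConfig, out: Path) -> dict:
    sched = stimuli.build_schedule(config.seed)
    stimuli.write_manifest(sched, out / "manifest.tsv")
    profile = synth_audio.SpeakerProfile(seed=config.seed)
    pairs = _make_session_audio(config, sched, profile, config.trials_per_speaker)
    if config.f1_min is not None and config.f1_max is not None:
        f1 = F1Range(config.f1_min, config.f1_max, 0)
    else:
        calib = [(ta.waveform, t.stimulus) for t, ta in pairs[:10]]
        f1 = landmarks.estimate_f1_range(calib, config.landmark)
    lm_rows, isi_rows, n_flagged, deviations = _segment_trials(pairs, config, f1)
    landmarks.write_landmark_table(out / "landmarks.tsv", lm_rows)
    isi_df = pd.DataFrame(isi_rows)
    if not isi_df.empty:
        isi_df.to_csv(out / "isis.tsv", sep="\t", index=False)
    report = {
        "mode": "synthetic-audio", "seed": config.seed,
        "n_trials": len(pairs), "n_flagged": n_flagged,
        "f1_range": (round(f1.f1_min, 1), round(f1.f1_max, 1)),
        "mean_onset_deviation_ms": float(np.mean(deviations)) if deviations else None,
        "max_onset_deviation_ms": float(np.max(deviations)) if deviations else None,
        "n_isis": len(isi_rows),
    }
    (out / "report.txt").write_text(_format_report(report))
    return report


def _run_external_audio(config: RunConfig, out: Path) -> dict:
    if not config.manifest:
        raise PipelineError("external-audio mode needs a manifest path")
    sched = stimuli.read_manifest(config.manifest)
    wav_dir = Path(config.wav_dir)
    pairs = []
    for t in sched.trials:
        path = wav_dir / f"r{t.run}t{t.trial}.wav"
        if not path.exists():
            raise PipelineError(f"missing WAV for run {t.run} trial {t.trial}: {path}")
        w = synth_audio.read_wav(path)
        pairs.append((t, synth_audio.TrialAudio(w, None, t.stimulus, None)))
    if config.f1_min is not None and config.f1_max is not None:
        f1 = F1Range(config.f1_min, config.f1_max, 0)
    else:
        calib_trials = landmarks.select_calibration_trials(sched)
        by_key = {(t.run, t.trial): ta for t, ta in pairs}
        calib = [(by_key[(t.run, t.trial)].waveform, t.stimulus)
                 for t in calib_trials if (t.run, t.trial) in by_key]
        f1 = landmarks.estimate_f1_range(calib, config.landmark)
    lm_rows, isi_rows, n_flagged, _ = _segment_trials(pairs, config, f1)
    landmarks.write_landmark_table(out / "landmarks.tsv", lm_rows)
    report = {"mode": "external-audio", "n_trials": len(pairs),
              "n_flagged": n_flagged, "n_isis": len(isi_rows),
              "f1_range": (round(f1.f1_min, 1), round(f1.f1_max, 1))}
    if isi_rows:
        pd.DataFrame(isi_rows).to_csv(out / "isis.tsv", sep="\t", index=False)
    (out / "report.txt").write_text(_format_report(report))
    return report


def _format_report(report: dict, indent: int = 0) -> str:
    lines = []
    pad = "  " * indent
    for k, v in report.items():
        if isinstance(v, dict):
            lines.append(f"{pad}{k}:")
            lines.append(_format_report(v, indent + 1))
        else:
            lines.append(f"{pad}{k}: {v}")
    return "\n".join(lines)
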