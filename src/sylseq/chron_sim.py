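"""Chronometric simulator: trial-level ISIs and Bernoulli error outcomes.

Generates data with exactly the statistical structure the analysis stage
assumes — speaker random intercepts, a fixed sequence-length slope, and a
fixed run (practice) slope — under presets for three speaker groups:

* healthy controls: ISI slope 4.9 ms/syllable, practice −3.2 ms/run,
  error slopes +5.0 %/syllable and −1.1 %/run, 14 speakers;
* hypokinetic dysarthria (Parkinson's disease): 12 ms/syllable,
  −3.5 ms/run, +8.2 %/syllable, −1.9 %/run, 8 speakers;
* ataxic dysarthria: no length or practice effects on ISIs or practice
  effect on errors, +6.3 %/syllable on errors, 5 speakers.

The ISI model is linear in ms with the intercept anchored at sequence
length 2 (the shortest length yielding an interval) and the run predictor
centred at run 3, so the baseline is the run-averaged value.  The error
model is additive on the probability scale, anchored at length 1, with
speaker heterogeneity as a mean-one multiplicative severity factor
(log-normal), which leaves every generative slope unbiased in expectation
while keeping probabilities valid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .stimuli import Schedule

P_CLIP = (0.001, 0.999)


@dataclass(frozen=True)
class GroupPreset:
    """Generative parameters for one speaker group.

    Slopes are stored signed: practice reduces ISIs and error rates, so
    ``run_slope_isi`` and ``run_slope_err`` are negative for the groups
    that show practice effects.  ``isi_group_offset`` is the group's mean
    ISI elevation over healthy controls, used for group-comparison
    simulations.
    """

    name: str
    n_speakers: int
    isi_baseline: float          # ms, mean ISI at length 2, run-averaged
    length_slope_isi: float      # ms per syllable
    run_slope_isi: float         # ms per run (signed)
    err_baseline: float          # proportion at length 1, run-averaged
    length_slope_err: float      # proportion per syllable
    run_slope_err: float         # proportion per run (signed)
    speaker_sd_isi: float = 25.0     # ms
    resid_sd_isi: float = 30.0       # ms, trial-level
    speaker_sd_err_log: float = 0.3  # SD of log speaker severity
    isi_group_offset: float = 0.0    # ms vs healthy

    def __post_init__(self) -> None:
        if self.n_speakers < 2:
            raise ValueError("need at least 2 speakers")
        if min(self.speaker_sd_isi, self.resid_sd_isi, self.speaker_sd_err_log) < 0:
            raise ValueError("SDs must be non-negative")


def default_presets() -> dict[str, GroupPreset]:
    """The three group presets with documented generative effect sizes.

    Baseline fields (isi_baseline, err_baseline, SDs) are package defaults:
    group mean ISIs 230/306/318 ms reproduce the 76 and 88 ms group
    offsets, and the 8% error baseline keeps the additive error model's
    linear predictor inside (0, 1) over the whole 5-length x 5-run design
    for every preset, so no clipping distorts the generative slopes.
    """
    return {
        "healthy": GroupPreset("healthy", 14, 230.0, 4.9, -3.2,
                               0.08, 0.050, -0.011, isi_group_offset=0.0),
        "hypokinetic": GroupPreset("hypokinetic", 8, 306.0, 12.0, -3.5,
                                   0.08, 0.082, -0.019, isi_group_offset=76.0),
        "ataxic": GroupPreset("ataxic", 5, 318.0, 0.0, 0.0,
                              0.08, 0.063, 0.0, isi_group_offset=88.0),
    }


def _schedule_frame(schedule: Schedule) -> pd.DataFrame:
    rows = [(t.run, t.trial, t.stimulus.n) for t in schedule.trials if t.run != 0]
    return pd.DataFrame(rows, columns=["run", "trial", "length"])


def simulate_isis(preset: GroupPreset, schedule: Schedule, seed: int) -> pd.DataFrame:
    """Trial-level mean ISIs for one group over a session schedule.

    Per speaker s: intercept b_s ~ N(0, speaker_sd_isi); for each trial of
    length n >= 2 in run r, the trial-mean ISI is

        isi_baseline + b_s + length_slope_isi*(n-2) + run_slope_isi*(r-3)
        + N(0, resid_sd_isi).

    The run predictor is centred at run 3 so isi_baseline is the
    run-averaged mean at length 2.  Length-1 trials produce no interval
    and are omitted.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    sched = _schedule_frame(schedule)
    sched = sched[sched["length"] >= 2].reset_index(drop=True)
    frames = []
    for s in range(preset.n_speakers):
        b = rng.normal(0.0, preset.speaker_sd_isi)
        mu = (preset.isi_baseline + b
              + preset.length_slope_isi * (sched["length"] - 2)
              + preset.run_slope_isi * (sched["run"] - 3))
        isi = mu + rng.normal(0.0, preset.resid_sd_isi, len(sched))
        frames.append(pd.DataFrame({
            "speaker": f"{preset.name}-{s + 1:02d}", "group": preset.name,
            "run": sched["run"], "length": sched["length"],
            "trial": sched["trial"], "isi_ms": isi,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_errors(preset: GroupPreset, schedule: Schedule, seed: int) -> pd.DataFrame:
    """Bernoulli error outcomes for one group over a session schedule.

    Trial error probability: the additive linear predictor
    err_baseline + length_slope_err*(n-1) + run_slope_err*(r-3), scaled by
    the speaker's severity gamma_s = exp(b_s - sd^2/2) with
    b_s ~ N(0, speaker_sd_err_log^2), then clipped to [0.001, 0.999].
    E[gamma_s] = 1, so expected cell rates — and therefore the slopes the
    analysis stage recovers — equal the generative values.
    """
    rng = np.random.default_rng(seed)
    sched = _schedule_frame(schedule)
    sd = preset.speaker_sd_err_log
    frames = []
    for s in range(preset.n_speakers):
        gamma = np.exp(rng.normal(0.0, sd) - sd**2 / 2.0) if sd > 0 else 1.0
        p_lin = (preset.err_baseline
                 + preset.length_slope_err * (sched["length"] - 1)
                 + preset.run_slope_err * (sched["run"] - 3))
        p = np.clip(p_lin * gamma, *P_CLIP)
        frames.append(pd.DataFrame({
            "speaker": f"{preset.name}-{s + 1:02d}", "group": preset.name,
            "run": sched["run"], "length": sched["length"],
            "trial": sched["trial"],
            "is_error": rng.random(len(sched)) < p,
        }))
    return pd.concat(frames, ignore_index=True)


def speaker_means(df: pd.DataFrame, by: str, value: str) -> pd.DataFrame:
    """Per-speaker cell means (the unit of analysis for the mixed models)."""
    out = (df.groupby(["speaker", by], sort=True)[value]
             .mean().rename("value").reset_index())
    out["group"] = df.groupby(["speaker", by])["group"].first().values
    return out


def speaker_error_rates(df: pd.DataFrame, by: str, percent: bool = True) -> pd.DataFrame:
    """Per-speaker error rates by cell, on the percentage scale by default."""
    out = speaker_means(df.assign(is_error=df["is_error"].astype(float)),
                        by, "is_error")
    if percent:
        out["value"] = out["value"] * 100.0
    return out


def simulate_group_means_isi(presets: dict[str, GroupPreset], seed: int) -> pd.DataFrame:
    """Per-speaker overall mean ISIs for a group comparison.

    Speaker means are drawn N(healthy baseline + group offset, speaker SD);
    the configured offsets are 0 / 76 / 88 ms.
    """
    rng = np.random.default_rng(seed)
    base = presets["healthy"].isi_baseline
    rows = []
    for preset in presets.values():
        mu = base + preset.isi_group_offset
        for s in range(preset.n_speakers):
            rows.append({"speaker": f"{preset.name}-{s + 1:02d}",
                         "group": preset.name,
                         "value": rng.normal(mu, preset.speaker_sd_isi)})
    return pd.DataFrame(rows)


def write_long_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_long_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ----------------------------------------------------- recovery harness


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds below 2**31."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31, size=n)]


def recover_isi_effects(presets: dict[str, GroupPreset], schedule: Schedule,
                        n_reps: int, seed: int) -> dict[str, np.ndarray]:
    """Replicate-wise recovered ISI effects for healthy + hypokinetic data.

    Each replicate simulates both groups, fits the per-group length and
    practice models and the combined two-group length-interaction model,
    and records the fitted coefficients.  Returns arrays keyed
    ``<group>_length``, ``<group>_run`` and ``interaction``.
    """
    from . import stats  # local import: stats also imports nothing from here

    seeds = _child_seeds(seed, n_reps)
    out: dict[str, list[float]] = {
        "healthy_length": [], "hypokinetic_length": [],
        "healthy_run": [], "hypokinetic_run": [], "interaction": [],
    }
    for s in seeds:
        tables = {}
        for i, name in enumerate(("healthy", "hypokinetic")):
            df = simulate_isis(presets[name], schedule, s + i)
            tables[name] = df
            out[f"{name}_length"].append(
                stats.fit_length_model(speaker_means(df, "length", "isi_ms"), "isi").slope)
            out[f"{name}_run"].append(
                stats.fit_practice_model(speaker_means(df, "run", "isi_ms"), "isi").slope)
        both = pd.concat([speaker_means(tables["healthy"], "length", "isi_ms"),
                          speaker_means(tables["hypokinetic"], "length", "isi_ms")])
        out["interaction"].append(
            stats.fit_interaction_model(both, "length").interaction)
    return {k: np.asarray(v) for k, v in out.items()}


def recover_error_effects(preset: GroupPreset, schedule: Schedule,
                          n_reps: int, seed: int) -> dict[str, np.ndarray]:
    """Replicate-wise recovered error-rate slopes (percentage scale)."""
    from . import stats

    seeds = _child_seeds(seed, n_reps)
    out: dict[str, list[float]] = {"length": [], "run": []}
    for s in seeds:
        df = simulate_errors(preset, schedule, s)
        out["length"].append(
            stats.fit_length_model(speaker_error_rates(df, "length"), "pctErr").slope)
        out["run"].append(
            stats.fit_practice_model(speaker_error_rates(df, "run"), "pctErr").slope)
    return {k: np.asarray(v) for k, v in out.items()}


def recover_group_difference(presets: dict[str, GroupPreset],
                             n_reps: int, seed: int) -> np.ndarray:
    """Replicate-wise healthy-vs-hypokinetic post-hoc mean ISI differences."""
    from . import stats

    diffs = []
    for s in _child_seeds(seed, n_reps):
        gm = simulate_group_means_isi(presets, s)
        gc = stats.compare_groups(gm, "isi")
        d = next(d for pair, d, _p in gc.post_hoc if pair == "healthy-hypokinetic")
        diffs.append(abs(d))
    return np.asarray(diffs)
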